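"""Tests of median division, the early decay ratio, and mean-delay inference."""

import math
import warnings

import numpy as np
import pytest

from decaylab import cohort as chm
from decaylab import group as grp


def _series(values, n_training=300):
    n_ret = len(values) - n_training
    return chm.TrialSeries("s", chm.trial_index(n_training, n_ret), values)


# --------------------------------------------------------------------------
# median division
# --------------------------------------------------------------------------

def test_median_divide_separates_decayers_exactly():
    t = chm.trial_index(300, 325)
    flat = np.ones(625)
    step = np.where(t <= 0, 1.0, 0.0)
    cohort = [chm.TrialSeries(f"d{i}", t, step.copy()) for i in range(20)] \
        + [chm.TrialSeries(f"n{i}", t, flat.copy()) for i in range(20)]
    high, low = grp.median_divide(cohort)
    assert len(high) == len(low) == 20
    assert {s.subject_id[0] for s in high} == {"d"}
    assert {s.subject_id[0] for s in low} == {"n"}


def test_median_divide_odd_n_assigns_median_to_high():
    t = chm.trial_index(300, 325)
    cohort = []
    for i, drop in enumerate([0.9, 0.7, 0.5, 0.3, 0.1]):
        v = np.where(t <= 0, 1.0, 1.0 - drop)
        cohort.append(chm.TrialSeries(f"s{i}", t, v))
    high, low = grp.median_divide(cohort)
    assert len(high) == 3 and len(low) == 2
    assert {s.subject_id for s in high} == {"s0", "s1", "s2"}


def test_median_divide_excludes_near_zero_learning():
    t = chm.trial_index(300, 325)
    good = chm.TrialSeries("g", t, np.where(t <= 0, 1.0, 0.5))
    bad = chm.TrialSeries("z", t, np.zeros(625))
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        high, low = grp.median_divide([good, good, bad])
    assert any("near-zero learning" in str(w.message) for w in rec)
    assert len(high) + len(low) == 2


# --------------------------------------------------------------------------
# early decay ratio
# --------------------------------------------------------------------------

def test_ed_step_decay_is_one():
    t = chm.trial_index(300, 325)
    assert grp.early_decay_ratio(_series(np.where(t <= 0, 1.0, 0.0))) == pytest.approx(1.0)


def test_ed_zero_when_decay_starts_after_decision_window():
    p = chm.DelayedExponentialParams(0.9, 0.2, 30.0, 60.0)
    t = chm.trial_index(300, 325)
    s = _series(chm.eval_delayed_exponential(p, t))
    assert grp.early_decay_ratio(s) == pytest.approx(0.0, abs=1e-9)


def test_ed_undefined_without_decay():
    with pytest.raises(ValueError):
        grp.early_decay_ratio(_series(np.ones(625)))


def test_ed_closed_form_oracle():
    """Noiseless immediate-decay ED equals the discrete geometric-sum value."""
    a, b, tau = 0.875, 0.360, 40.0
    # independent oracle: plain-Python window sums of the decay curve
    E = b + (a - b) * sum(math.exp(-t / tau) for t in range(1, 51)) / 50
    T = b + (a - b) * sum(math.exp(-t / tau) for t in range(251, 326)) / 75
    expected = (a - E) / (a - T)

    p = chm.DelayedExponentialParams(a, b, tau, 0.0)
    t = chm.trial_index(300, 325)
    s = _series(chm.eval_delayed_exponential(p, t))
    assert grp.early_decay_ratio(s) == pytest.approx(expected, abs=1e-12)

    # the vectorised simulator reproduces it exactly when noise is off
    pop = chm.PopulationSpec(a_sd=0, b_sd=0, tau_sd=0, noise_sd=0.0,
                             mu_lambda=0.0, n_subjects=8)
    pairs = grp.simulate_ed_distribution(0.0, pop, 25, np.random.default_rng(0))
    np.testing.assert_allclose(pairs, expected, atol=1e-12)

    # and the full-trace cohort pipeline agrees
    cohort = chm.simulate_cohort(pop, np.random.default_rng(1))
    pair = grp.cohort_ed_pair(cohort)
    assert pair.ed_high == pytest.approx(expected, abs=1e-12)
    assert pair.ed_low == pytest.approx(expected, abs=1e-12)


def test_selection_bias_elevates_low_group_at_long_delay(rng):
    """With a 90-trial mean delay the low-decay subgroup's mean ED is slightly
    negative: pure selection on noise among non-decayers."""
    pairs = grp.simulate_ed_distribution(90.0, chm.PopulationSpec(), 400, rng)
    assert pairs[:, 1].mean() < 0.0
    assert pairs[:, 0].mean() > pairs[:, 1].mean()


def test_monotonic_separation_in_mean_delay(rng):
    """Mean simulated ED of the low-decay subgroup decreases with mean delay."""
    means = []
    for mu in (0.0, 30.0, 60.0, 90.0):
        pairs = grp.simulate_ed_distribution(mu, chm.PopulationSpec(), 400, rng)
        means.append(pairs[:, 1].mean())
    assert all(x > y for x, y in zip(means, means[1:]))


# --------------------------------------------------------------------------
# MVN likelihood
# --------------------------------------------------------------------------

def test_fit_mvn_handles_degenerate_pairs():
    pairs = np.tile([0.4, 0.2], (50, 1))
    f = grp.fit_mvn(pairs)
    assert np.isfinite(f.pdf([0.4, 0.2]))
    np.testing.assert_allclose(f.mean, [0.4, 0.2])


def test_fit_mvn_recovers_known_parameters(rng):
    mean = np.array([0.5, 0.3])
    cov = np.array([[0.04, 0.01], [0.01, 0.02]])
    pairs = rng.multivariate_normal(mean, cov, size=10_000)
    f = grp.fit_mvn(pairs)
    np.testing.assert_allclose(f.mean, mean, atol=0.01)
    np.testing.assert_allclose(f.cov, cov, atol=0.005)


def test_fit_mvn_density_integrates_to_one(rng):
    pairs = rng.multivariate_normal([0.0, 0.0], np.eye(2) * 0.01, size=2000)
    f = grp.fit_mvn(pairs)
    g = np.linspace(-1, 1, 301)
    xx, yy = np.meshgrid(g, g)
    from scipy.stats import multivariate_normal
    dens = multivariate_normal(f.mean, f.cov).pdf(np.dstack([xx, yy]))
    total = np.trapezoid(np.trapezoid(dens, g, axis=1), g)
    assert total == pytest.approx(1.0, abs=1e-3)


def test_fit_mvn_needs_enough_pairs():
    with pytest.raises(ValueError):
        grp.fit_mvn(np.zeros((5, 2)))


# --------------------------------------------------------------------------
# posterior
# --------------------------------------------------------------------------

def test_posterior_normalisation_and_map(rng):
    post = grp.posterior_mean_delay(grp.EarlyDecayPair(0.50, 0.35),
                                    chm.PopulationSpec(), n_sims=150, rng=rng)
    assert post.prob.sum() == pytest.approx(1.0, abs=1e-12)
    assert post.map in post.grid
    assert post.grid[np.argmax(post.prob)] == post.map
    lo95, hi95 = post.hpd95
    lo99, hi99 = post.hpd99
    assert lo99 <= lo95 <= hi95 <= hi99
    mask = (post.grid >= lo95) & (post.grid <= hi95)
    assert post.prob[mask].sum() >= 0.95 - 1e-12


def test_posterior_recovers_zero_delay_truth(rng):
    """Observed pairs generated under immediate decay lead the posterior MAP
    to (near) zero mean delay."""
    pop = chm.PopulationSpec()
    maps = []
    for _ in range(4):
        obs_pair = grp.simulate_ed_distribution(0.0, pop, 1, rng)[0]
        post = grp.posterior_mean_delay(
            grp.EarlyDecayPair(*obs_pair), pop, n_sims=300, rng=rng)
        maps.append(post.map)
    assert sum(m <= 5 for m in maps) >= 3


def test_posterior_rejects_nonfinite_observation(rng):
    with pytest.raises(ValueError):
        grp.posterior_mean_delay(grp.EarlyDecayPair(float("nan"), 0.3), rng=rng)


# --------------------------------------------------------------------------
# exponential-delay facts
# --------------------------------------------------------------------------

def test_exponential_delay_facts():
    f = grp.exp_delay_facts(90.0)
    assert f.fraction_above(50) == pytest.approx(math.exp(-50 / 90), abs=1e-12)
    assert round(100 * f.fraction_above(50)) == 57
    assert round(100 * f.fraction_below(10)) == 11
    assert f.median == pytest.approx(90 * math.log(2), abs=1e-12)


def test_exponential_facts_point_mass_convention():
    f = grp.exp_delay_facts(0.0)
    assert f.fraction_below(1.0) == 1.0
    assert f.fraction_above(1.0) == 0.0
    assert f.median == 0.0
    with pytest.raises(ValueError):
        grp.exp_delay_facts(-1.0)
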