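"""Tests of the synthetic-cohort generators and the decay-curve primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from decaylab import cohort as chm
from decaylab.noise import autocorrelation, partial_autocorrelation


# --------------------------------------------------------------------------
# delayed exponential
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "params, t, expected",
    [
        ((0.85, 0.40, 40.0, 0.0), 0, 0.85),            # t <= lam branch
        ((0.85, 0.40, 40.0, 0.0), 1e9, 0.40),          # asymptote
        # hand computation: b + (a-b)*exp(-1) = 0.40 + 0.45*0.36787944117144233
        ((0.85, 0.40, 40.0, 0.0), 40, 0.5655457485271490),
        ((0.85, 0.40, 40.0, 25.0), 25, 0.85),          # value at the onset itself
    ],
)
def test_eval_delayed_exponential_values(params, t, expected):
    p = chm.DelayedExponentialParams(*params)
    assert chm.eval_delayed_exponential(p, t) == pytest.approx(expected, abs=1e-9)


def test_invalid_tau_rejected():
    with pytest.raises(ValueError):
        chm.DelayedExponentialParams(0.8, 0.4, 0.0, 0.0)


@given(
    a=st.floats(-1.5, 1.5),
    b=st.floats(-1.0, 1.0),
    tau=st.floats(2.0, 200.0),
    lam=st.floats(-100.0, 325.0),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_continuity_at_onset(a, b, tau, lam):
    """The curve is continuous at the decay onset: f(lam) == f(lam+)."""
    p = chm.DelayedExponentialParams(a, b, tau, lam)
    left = chm.eval_delayed_exponential(p, lam)
    right = chm.eval_delayed_exponential(p, lam + 1e-9)
    assert abs(left - right) < 1e-6
    assert left == pytest.approx(a)


@given(
    a=st.floats(0.5, 1.5), b=st.floats(-0.3, 0.3),
    tau=st.floats(2.0, 200.0), lam=st.floats(0.0, 100.0),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_strictly_decreasing_after_onset(a, b, tau, lam):
    # restrict to within a few time constants of onset: further out the
    # decrements fall below float resolution against b
    p = chm.DelayedExponentialParams(a, b, tau, lam)
    t = np.linspace(lam + 0.5, lam + 8 * tau, 200)
    f = chm.eval_delayed_exponential(p, t)
    assert np.all(np.diff(f) < 0)


# --------------------------------------------------------------------------
# population draws
# --------------------------------------------------------------------------

def test_degenerate_population_draws(rng):
    pop = chm.PopulationSpec(a_sd=0, b_sd=0, tau_sd=0, mu_lambda=0.0)
    p = chm.draw_subject(pop, rng)
    assert (p.a, p.b, p.tau, p.lam) == (pop.a_mean, pop.b_mean, pop.tau_mean, 0.0)


def test_zero_mean_delay_is_point_mass(rng):
    pop = chm.PopulationSpec(mu_lambda=0.0)
    assert all(chm.draw_subject(pop, rng).lam == 0.0 for _ in range(100))


def test_tau_sample_mean_matches_population(rng):
    """Law of large numbers: 1e5 draws of tau average to 40 within 3 SE."""
    pop = chm.PopulationSpec()
    taus = np.array([chm.draw_subject(pop, rng).tau for _ in range(100_000)])
    se = pop.tau_sd / np.sqrt(len(taus))
    assert abs(taus.mean() - pop.tau_mean) < 3 * se


# --------------------------------------------------------------------------
# subject / cohort simulation
# --------------------------------------------------------------------------

def test_noiseless_subject_equals_curve(rng):
    p = chm.DelayedExponentialParams(0.9, 0.3, 30.0, 10.0)
    s = chm.simulate_subject(p, 0.0, rng)
    np.testing.assert_allclose(s.value, chm.eval_delayed_exponential(p, s.t))
    assert s.t[0] == -299 and s.t[-1] == 325


def test_residual_sd_matches_noise(rng):
    p = chm.DelayedExponentialParams(0.9, 0.3, 30.0, 0.0)
    s = chm.simulate_subject(p, 0.25, rng, n_training=5000, n_retention=5000)
    resid = s.value - chm.eval_delayed_exponential(p, s.t)
    assert np.std(resid) == pytest.approx(0.25, rel=0.02)


def test_zero_delay_training_at_asymptote(rng):
    p = chm.DelayedExponentialParams(0.85, 0.40, 40.0, 0.0)
    s = chm.simulate_subject(p, 0.0, rng)
    np.testing.assert_allclose(s.value[s.t <= 0], p.a)


def test_cohort_shape_and_truth(rng):
    pop = chm.PopulationSpec(n_subjects=40)
    cohort = chm.simulate_cohort(pop, rng)
    assert len(cohort) == 40
    assert all(len(s.t) == pop.n_training + pop.n_retention for s in cohort)
    assert all(s.truth is not None for s in cohort)


def test_cohort_determinism_and_prefix_stability():
    pop = chm.PopulationSpec(n_subjects=6)
    c1 = chm.simulate_cohort(pop, np.random.default_rng(42))
    c2 = chm.simulate_cohort(pop, np.random.default_rng(42))
    for s1, s2 in zip(c1, c2):
        np.testing.assert_array_equal(s1.value, s2.value)
    # growing the cohort must not reshuffle earlier subjects
    big = chm.simulate_cohort(pop.replace(n_subjects=10), np.random.default_rng(42))
    for s1, s2 in zip(c1, big[:6]):
        np.testing.assert_array_equal(s1.value, s2.value)


def test_degenerate_cohort_all_identical(rng):
    pop = chm.PopulationSpec(a_sd=0, b_sd=0, tau_sd=0, noise_sd=0.0,
                             mu_lambda=0.0, n_subjects=5)
    cohort = chm.simulate_cohort(pop, rng)
    for s in cohort[1:]:
        np.testing.assert_array_equal(s.value, cohort[0].value)


# --------------------------------------------------------------------------
# ARMA noise
# --------------------------------------------------------------------------

def test_arma_reduces_to_white_noise(rng):
    x = chm.simulate_arma(chm.ArmaSpec(0.0, 0.0, 0.5), 50_000, rng)
    assert np.std(x) == pytest.approx(0.5, rel=0.02)
    acf = autocorrelation(x, 5)
    assert np.all(np.abs(acf[1:]) < 3 / np.sqrt(len(x)))


def test_ar1_lag1_autocorrelation(rng):
    x = chm.simulate_arma(chm.ArmaSpec(0.9, 0.0, 1.0), 100_000, rng, burn_in=200)
    assert autocorrelation(x, 1)[1] == pytest.approx(0.9, abs=0.02)


def test_arma11_stationary_variance(rng):
    spec = chm.ArmaSpec(0.8, -0.4, 0.7)
    x = chm.simulate_arma(spec, 400_000, rng, burn_in=500)
    assert np.std(x) == pytest.approx(spec.stationary_sd, rel=0.02)


def test_nonstationary_ar_rejected():
    with pytest.raises(ValueError):
        chm.ArmaSpec(1.0, 0.0, 1.0)


def test_white_noise_retention_acf_pacf_near_zero(rng):
    """Without drift, retention residual ACF/PACF at lags 1-10 are null."""
    n = 10_000
    x = rng.normal(0, 0.25, n)
    bound = 3 / np.sqrt(n)
    assert np.all(np.abs(autocorrelation(x, 10)[1:]) < bound)
    assert np.all(np.abs(partial_autocorrelation(x, 10)) < bound)


# --------------------------------------------------------------------------
# drift generative model
# --------------------------------------------------------------------------

def test_drift_subject_deterministic_backbone(rng):
    spec = chm.DriftGenerativeSpec(D_sd=0.0, train_noise_sd=0.0,
                                   ar_sd=0.0, ma_sd=0.0,
                                   eps_sd_mean=0.0, eps_sd_sd=0.0)
    s = chm.simulate_drift_subject(spec, rng)
    assert s.value[s.t == 0][0] == pytest.approx(0.56)
    # one time constant into retention the trace is at D/e
    t36 = s.value[s.t == 36][0]
    assert t36 == pytest.approx(0.56 * np.exp(-36 / 35.8), abs=1e-12)
    assert 0.56 / np.e == pytest.approx(t36, rel=0.01)


def test_drift_retention_noise_positively_correlated(rng):
    """ARMA(1,1) with AR 0.93, MA -0.55 has positive lag-1 autocorrelation."""
    spec = chm.DRIFT_ADJUSTED
    arma = chm.ArmaSpec(spec.ar_mean, spec.ma_mean, spec.eps_sd_mean)
    # closed-form lag-1 ACF of ARMA(1,1)
    ar, ma = arma.ar, arma.ma
    rho1 = (1 + ar * ma) * (ar + ma) / (1 + 2 * ar * ma + ma ** 2)
    assert rho1 > 0
    x = chm.simulate_arma(arma, 200_000, rng, burn_in=500)
    assert autocorrelation(x, 1)[1] == pytest.approx(rho1, abs=0.02)


def test_drift_cohort_sizes(rng):
    cohort = chm.simulate_drift_cohort(chm.DRIFT_ADJUSTED, 7, rng)
    assert len(cohort) == 7
    assert all(s.truth.lam == 0.0 for s in cohort)


# --------------------------------------------------------------------------
# tidy CSV round trip
# --------------------------------------------------------------------------

def test_cohort_frame_round_trip(rng):
    cohort = chm.simulate_cohort(chm.PopulationSpec(n_subjects=3), rng)
    df = chm.cohort_to_frame(cohort)
    assert list(df.columns) == ["subject_id", "t", "phase", "probe", "value"]
    assert set(df["phase"]) == {"training", "retention"}
    back = chm.frame_to_cohort(df)
    for a, b in zip(cohort, back):
        assert a.subject_id == b.subject_id
        np.testing.assert_allclose(a.value, b.value)
        np.testing.assert_array_equal(a.t, b.t)


def test_spec_yaml_round_trip(tmp_path):
    for spec in (chm.PopulationSpec(mu_lambda=30.0), chm.ArmaSpec(0.9, -0.5, 0.2),
                 chm.DRIFT_ADJUSTED):
        p = tmp_path / "spec.yaml"
        chm.spec_to_yaml(spec, p)
        assert chm.spec_from_yaml(p) == spec
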