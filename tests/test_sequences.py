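"""Tests of vEC sequence generation, rejection rules, and balancing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from decaylab import cohort as chm
from decaylab import sequences as seq
from decaylab import group as grp


CRIT = seq.RejectionCriteria()


# --------------------------------------------------------------------------
# ternary pattern
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "angle, expected",
    [
        (0.0, 0),
        (10.0, 1),      # 100*sin(10 deg) = 17.4 mm > 6 mm
        (-10.0, -1),
        (3.0, 0),       # 100*sin(3 deg) = 5.234 mm <= 6 mm
        (-3.0, 0),
        (3.45, 1),      # 100*sin(3.45 deg) = 6.018 mm > 6 mm
    ],
)
def test_binary_error_pattern(angle, expected):
    assert seq.binary_error_pattern([angle], CRIT)[0] == expected


# --------------------------------------------------------------------------
# rejection rules
# --------------------------------------------------------------------------

def test_all_zero_pattern_rejected_by_gap_rule():
    ok, rule = seq.passes_criteria(np.zeros(325), CRIT)
    assert not ok and rule == "gap"


def test_consecutive_run_rejected_by_smoothing():
    pattern = np.zeros(325)
    pattern[100:106] = 1  # six consecutive rightward misses: 5-trial mean hits 1.0
    ok, rule = seq.passes_criteria(pattern, CRIT)
    assert not ok and rule == "smooth5"


def test_strict_alternation_passes():
    pattern = np.tile([1, -1], 200)[:325]
    ok, rule = seq.passes_criteria(pattern, CRIT)
    assert ok and rule is None


def test_short_pattern_raises():
    with pytest.raises(ValueError):
        seq.passes_criteria(np.ones(5), CRIT)


@given(st.lists(st.sampled_from([-1, 0, 1]), min_size=30, max_size=120))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_criteria_symmetric_under_sign_flip(pattern):
    p = np.array(pattern)
    assert seq.passes_criteria(p, CRIT)[0] == seq.passes_criteria(-p, CRIT)[0]


@given(st.integers(0, 2**32 - 1), st.integers(30, 120))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_batch_screen_agrees_with_scalar_rules(seed, n):
    """The vectorised candidate screen matches the per-sequence rule check."""
    r = np.random.default_rng(seed)
    pats = r.choice([-1, 0, 1], size=(8, n), p=[0.1, 0.8, 0.1])
    batch = seq._passes_batch(pats, CRIT)
    scalar = np.array([seq.passes_criteria(p, CRIT)[0] for p in pats])
    np.testing.assert_array_equal(batch, scalar)


# --------------------------------------------------------------------------
# generation and mirroring
# --------------------------------------------------------------------------

def test_generate_sequence_accepted_and_plausible(rng):
    s = seq.generate_sequence(rng=rng)
    assert s.accepted and len(s) == 325
    assert seq.passes_criteria(s.pattern, CRIT)[0]
    # nominal directional spread of the clamp angles
    assert np.std(s.angles, ddof=1) == pytest.approx(2.6, abs=0.3)
    # mirror of an accepted sequence is itself acceptable
    m = seq.mirror(s)
    assert seq.passes_criteria(seq.binary_error_pattern(m.angles, CRIT), CRIT)[0]


def test_generation_exhaustion_raises(rng):
    with pytest.raises(seq.SequenceGenerationError) as err:
        seq.generate_sequence(rng=rng, max_attempts=10)
    assert err.value.attempts == 10


def test_mirror_involution_and_pattern(rng):
    s = seq.generate_sequence(rng=rng)
    m = seq.mirror(s)
    np.testing.assert_array_equal(m.angles, -s.angles)
    np.testing.assert_array_equal(m.pattern, -s.pattern)
    back = seq.mirror(m)
    np.testing.assert_array_equal(back.angles, s.angles)
    np.testing.assert_array_equal(
        seq.binary_error_pattern(m.angles, CRIT), -seq.binary_error_pattern(s.angles, CRIT))


def test_mirror_of_zero_angles_is_zero():
    s = seq.VecSequence(angles=np.zeros(20))
    np.testing.assert_array_equal(seq.mirror(s).angles, np.zeros(20))


# --------------------------------------------------------------------------
# linear response model and balancing
# --------------------------------------------------------------------------

def test_stiffness_gain_example():
    s = seq.VecSequence(angles=np.ones(10))
    dev = seq.sequence_response(s, seq.LinearResponseModel(k_stiff=-0.03, k_learn=0.0))
    np.testing.assert_allclose(dev, -0.03)


def test_zero_angles_zero_response():
    s = seq.VecSequence(angles=np.zeros(10))
    model = seq.LinearResponseModel(k_stiff=-0.03, k_learn=0.02)
    np.testing.assert_allclose(seq.sequence_response(s, model), 0.0)


def test_response_linearity_under_mirror(rng):
    s = seq.VecSequence(angles=rng.normal(0, 2.6, 50))
    model = seq.LinearResponseModel(k_stiff=-0.03, k_learn=0.015)
    np.testing.assert_allclose(seq.sequence_response(seq.mirror(s), model),
                               -seq.sequence_response(s, model))


def test_balancing_theorem(rng):
    """Averaging the responses to a sequence and its mirror cancels exactly:
    decay + mean(response(s), response(mirror(s))) == decay."""
    s = seq.VecSequence(angles=rng.normal(0, 2.6, 325))
    model = seq.LinearResponseModel(k_stiff=-0.04, k_learn=0.03)
    decay = 0.5 * np.exp(-np.arange(325) / 40.0)
    mean_resp = 0.5 * (seq.sequence_response(s, model)
                       + seq.sequence_response(seq.mirror(s), model))
    np.testing.assert_allclose(decay + mean_resp, decay, atol=1e-15)


def test_estimate_effect_exact_algebra():
    d = np.linspace(1, 0, 50)
    r = np.sin(np.arange(50))
    np.testing.assert_allclose(seq.estimate_sequence_effect(d + r, d - r), r)
    np.testing.assert_allclose(seq.estimate_sequence_effect(d, d), 0.0)
    with pytest.raises(ValueError):
        seq.estimate_sequence_effect(d, d[:-1])


def test_remove_effect_recovers_pure_decay(rng):
    vec = seq.VecSequence(angles=rng.normal(0, 2.6, 325))
    model = seq.LinearResponseModel(k_stiff=-0.03, k_learn=0.01)
    p = chm.DelayedExponentialParams(0.85, 0.4, 40.0, 0.0)
    base = chm.simulate_subject(p, 0.0, rng)
    resp = seq.sequence_response(vec, model)
    v = base.value.copy()
    v[base.t >= 1] += resp
    subject = chm.TrialSeries("x", base.t, v)
    corrected = seq.remove_sequence_effect(subject, resp, "1a")
    np.testing.assert_allclose(corrected.value, base.value, atol=1e-12)
    # zero effect is the identity
    same = seq.remove_sequence_effect(subject, np.zeros(325), "1a")
    np.testing.assert_allclose(same.value, subject.value)
    with pytest.raises(ValueError):
        seq.remove_sequence_effect(subject, resp, "2c")


def test_effect_recovery_on_noisy_mirrored_cohort(rng):
    """With 20 subjects per arm and trial noise 0.25, the half-difference
    estimate correlates strongly with the true sequence response."""
    vec = seq.generate_sequence(rng=rng)
    model = seq.LinearResponseModel(k_stiff=-0.03, k_learn=0.01)
    resp_a = seq.sequence_response(vec, model)
    resp_b = seq.sequence_response(seq.mirror(vec), model)
    pop = chm.PopulationSpec(n_subjects=20)

    def arm(resp):
        out = []
        for s in chm.simulate_cohort(pop, rng):
            v = s.value.copy()
            v[s.t >= 1] += resp
            out.append(chm.TrialSeries(s.subject_id, s.t, v))
        return out

    arm_a, arm_b = arm(resp_a), arm(resp_b)
    ret = arm_a[0].t >= 1
    mean_a = grp.subgroup_mean_series(arm_a).value[ret]
    mean_b = grp.subgroup_mean_series(arm_b).value[ret]
    effect = seq.estimate_sequence_effect(mean_a, mean_b)
    assert np.corrcoef(effect, resp_a)[0, 1] > 0.8
    # removal reduces mean trial-to-trial variance of individuals
    raw = np.mean([seq.trial_to_trial_variance(s.value[ret]) for s in arm_a + arm_b])
    cor = np.mean([seq.trial_to_trial_variance(
        seq.remove_sequence_effect(s, effect, g).value[ret])
        for s, g in [(s, "1a") for s in arm_a] + [(s, "1b") for s in arm_b]])
    assert cor < raw


# --------------------------------------------------------------------------
# trial-to-trial variance
# --------------------------------------------------------------------------

def test_trial_to_trial_variance_values(rng):
    assert seq.trial_to_trial_variance(np.full(100, 3.3)) == 0.0
    c = 0.4
    alt = np.tile([c, -c], 5000)
    # differences are +-2c with zero mean: population variance 4c^2
    assert seq.trial_to_trial_variance(alt) == pytest.approx(4 * c ** 2, rel=1e-3)
    x = rng.normal(0, 0.7, 200_000)
    assert seq.trial_to_trial_variance(x) == pytest.approx(2 * 0.49, rel=0.02)
    with pytest.raises(ValueError):
        seq.trial_to_trial_variance([1.0])
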