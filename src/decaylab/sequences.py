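"""Variable-error-clamp (vEC) direction sequences.

A vEC retention block imposes a small directional error on every error-clamp
trial, drawn from N(0 deg, 2.6 deg^2), to preserve the kinematic variability of
the training period and thereby mask the training-to-retention context change.
Because subjects both resist the imposed error within a trial (stiffness) and
learn from it across trials (adaptation), an arbitrary random sequence can
drive large systematic oscillations in the measured retention curve.  The
sequence generator here rejects candidate sequences whose *binary error
pattern* (-1 left miss / 0 hit / +1 right miss) is locally unbalanced:

* the 5-trial moving average of the pattern must never exceed 0.5 in
  magnitude (net 3 same-direction misses within 5 trials),
* no 9-trial window may accumulate a net count of 3 same-direction misses
  (the count form of the nominal 0.2 mean bound; see RejectionCriteria),
* neither rightward nor leftward misses may be separated by a gap of more
  than 25 trials (counting the gaps from the sequence boundaries).

These rules jointly reject all but roughly 1 in 10^5 candidates.  The accepted
sequence and its mirror (sign-flipped) copy are assigned to two experiment
arms; averaging the arms cancels the sequence-driven response exactly for any
linear response model (the balancing theorem tested in this package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .cohort import TrialSeries

__all__ = [
    "VecSequence",
    "RejectionCriteria",
    "LinearResponseModel",
    "SequenceGenerationError",
    "binary_error_pattern",
    "passes_criteria",
    "generate_sequence",
    "mirror",
    "sequence_response",
    "estimate_sequence_effect",
    "remove_sequence_effect",
    "trial_to_trial_variance",
    "acceptance_rate",
]


@dataclass(frozen=True)
class RejectionCriteria:
    """Rejection rules for candidate vEC sequences.

    The smoothing rules bound the moving averages of the ternary miss
    pattern: a candidate is rejected when the magnitude of its 5-trial mean
    exceeds ``smooth5_max`` (with ±1 entries that is a net count of 3 misses
    in one direction within 5 trials) or when any 9-trial window reaches a
    net count of ``smooth9_min_count`` same-direction misses.  The 9-trial
    bound is deliberately expressed as a count: its nominal mean bound of 0.2
    taken literally (net count 2, mean 2/9) rejects every candidate at the
    nominal miss rate, so the operative threshold is the smallest count above
    it that leaves the sampler a ~1e-5 acceptance rate.

    ``hit_lateral_max`` (mm) and ``movement_length`` (mm) define the hit rule
    used to ternarise angles: a trial counts as a hit when the lateral
    endpoint displacement ``movement_length * sin(angle)`` is within the
    reward radius.
    """

    smooth5_max: float = 0.5
    smooth9_max: float = 0.2
    smooth9_min_count: int = 3
    max_gap: int = 25
    hit_lateral_max: float = 6.0
    movement_length: float = 100.0

    def __post_init__(self):
        for name in ("smooth5_max", "smooth9_max", "smooth9_min_count",
                     "max_gap", "hit_lateral_max", "movement_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class VecSequence:
    """A vEC direction sequence (degrees) with its derived ternary pattern."""

    angles: np.ndarray
    sd_target: float = 2.6
    pattern: Optional[np.ndarray] = None
    accepted: bool = False
    attempts: int = 0

    def __post_init__(self):
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        if self.pattern is not None:
            pat = np.asarray(self.pattern, dtype=int)
            if pat.shape != self.angles.shape:
                raise ValueError("pattern and angles must have the same length")
            object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class LinearResponseModel:
    """Linear per-trial behavioural response to imposed clamp errors.

    ``k_stiff`` is the same-trial gain (adaptation units per degree; negative:
    the subject pushes back toward the target) and ``k_learn`` the next-trial
    learning gain.
    """

    k_stiff: float = -0.03
    k_learn: float = 0.0


class SequenceGenerationError(RuntimeError):
    """Raised when no acceptable sequence is found within max_attempts."""

    def __init__(self, attempts: int):
        self.attempts = attempts
        super().__init__(f"no acceptable vEC sequence found in {attempts} candidates")


# --------------------------------------------------------------------------
# pattern and criteria
# --------------------------------------------------------------------------

def binary_error_pattern(angles, criteria: RejectionCriteria = RejectionCriteria()) -> np.ndarray:
    """Ternary miss pattern of an angle sequence: -1 left, 0 hit, +1 right.

    A trial is a hit when |movement_length * sin(angle)| <= hit_lateral_max.
    """
    angles = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    lateral = criteria.movement_length * np.sin(np.deg2rad(angles))
    pattern = np.where(np.abs(lateral) <= criteria.hit_lateral_max, 0, np.sign(angles))
    return pattern.astype(int)


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    # valid windows only: a length-n input yields n-w+1 means
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    return (c[w:] - c[:-w]) / w


def _max_spacing(positions: np.ndarray, n: int) -> int:
    """Largest gap between successive occurrences, including boundary gaps.

    Occurrence positions are 0-based; the gap from the start to the first
    occurrence is ``pos[0] + 1`` spacing units, matching the spacing
    ``pos[i+1] - pos[i]`` between interior occurrences, and the end gap is
    ``n - pos[-1]``.  No occurrences at all counts as a gap of n + 1.
    """
    if len(positions) == 0:
        return n + 1
    gaps = np.diff(np.concatenate([[-1], positions, [n]]))
    return int(gaps.max())


def passes_criteria(pattern, criteria: RejectionCriteria = RejectionCriteria()
                    ) -> Tuple[bool, Optional[str]]:
    """Apply the rejection rules to a ternary pattern.

    Returns ``(True, None)`` on acceptance, else ``(False, rule)`` where rule
    is the first failed rule among ``smooth5``, ``smooth9``, ``gap``.
    """
    pattern = np.asarray(pattern, dtype=float)
    if len(pattern) < 9:
        raise ValueError("pattern must have at least 9 trials")
    if np.max(np.abs(_moving_mean(pattern, 5))) > criteria.smooth5_max:
        return False, "smooth5"
    if np.max(np.abs(_moving_mean(pattern, 9))) * 9 >= criteria.smooth9_min_count:
        return False, "smooth9"
    n = len(pattern)
    for direction in (1, -1):
        if _max_spacing(np.flatnonzero(pattern == direction), n) > criteria.max_gap:
            return False, "gap"
    return True, None


def _passes_batch(patterns: np.ndarray, criteria: RejectionCriteria) -> np.ndarray:
    """Vectorised acceptance over a (n_candidates, length) pattern batch."""
    pat = patterns.astype(float)
    n_cand, n = pat.shape
    ok = np.ones(n_cand, dtype=bool)

    c = np.concatenate([np.zeros((n_cand, 1)), np.cumsum(pat, axis=1)], axis=1)
    m5 = (c[:, 5:] - c[:, :-5]) / 5
    ok &= np.max(np.abs(m5), axis=1) <= criteria.smooth5_max
    s9 = c[:, 9:] - c[:, :-9]
    ok &= np.max(np.abs(s9), axis=1) < criteria.smooth9_min_count

    # gap rule: max spacing > g  <=>  some run of >= g trials without a miss
    # (boundary gaps included: a first occurrence later than position g-1
    #  means the initial g trials are all non-misses).
    g = criteria.max_gap
    if n <= g:
        # any direction absent entirely -> gap n+1 > g only if n+1 > g
        for direction in (1, -1):
            present = np.any(pat == direction, axis=1)
            if n + 1 > g:
                ok &= present
        return ok
    for direction in (1, -1):
        ind = (pat == direction).astype(float)
        ci = np.concatenate([np.zeros((n_cand, 1)), np.cumsum(ind, axis=1)], axis=1)
        wsum = ci[:, g:] - ci[:, :-g]  # counts in every length-g window
        ok &= np.min(wsum, axis=1) > 0
    return ok


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_sequence(
    criteria: RejectionCriteria = RejectionCriteria(),
    sd: float = 2.6,
    length: int = 325,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 2_000_000,
    batch: int = 20_000,
) -> VecSequence:
    """Rejection-sample a vEC sequence of i.i.d. N(0, sd^2) angles.

    Candidates are drawn in batches and screened with the vectorised criteria;
    the first accepted candidate (in draw order) is returned together with the
    number of candidates drawn before acceptance.  Raises
    :class:`SequenceGenerationError` when ``max_attempts`` is exhausted —
    expect on the order of 10^5 attempts at the default criteria.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    attempts = 0
    while attempts < max_attempts:
        m = min(batch, max_attempts - attempts)
        angles = rng.normal(0.0, sd, size=(m, length))
        lateral = criteria.movement_length * np.sin(np.deg2rad(angles))
        patterns = np.where(np.abs(lateral) <= criteria.hit_lateral_max,
                            0, np.sign(angles)).astype(int)
        ok = _passes_batch(patterns, criteria)
        hits = np.flatnonzero(ok)
        if len(hits):
            i = int(hits[0])
            return VecSequence(
                angles=angles[i], sd_target=sd, pattern=patterns[i],
                accepted=True, attempts=attempts + i + 1,
            )
        attempts += m
    raise SequenceGenerationError(attempts)


def acceptance_rate(
    criteria: RejectionCriteria = RejectionCriteria(),
    sd: float = 2.6,
    length: int = 325,
    n_candidates: int = 1_000_000,
    rng: Optional[np.random.Generator] = None,
    batch: int = 50_000,
) -> Tuple[float, int]:
    """Monte-Carlo estimate of the sampler's acceptance rate.

    Returns ``(rate, n_accepted)`` over ``n_candidates`` i.i.d. candidates.
    """
    if rng is None:
        rng = np.random.default_rng()
    accepted = 0
    done = 0
    while done < n_candidates:
        m = min(batch, n_candidates - done)
        angles = rng.normal(0.0, sd, size=(m, length))
        lateral = criteria.movement_length * np.sin(np.deg2rad(angles))
        patterns = np.where(np.abs(lateral) <= criteria.hit_lateral_max,
                            0, np.sign(angles)).astype(int)
        accepted += int(_passes_batch(patterns, criteria).sum())
        done += m
    return accepted / n_candidates, accepted


def mirror(seq: VecSequence) -> VecSequence:
    """Sign-flip a sequence; acceptance is preserved (criteria are symmetric)."""
    pattern = None if seq.pattern is None else -seq.pattern
    return replace(seq, angles=-seq.angles, pattern=pattern)


# --------------------------------------------------------------------------
# behavioural response and its removal
# --------------------------------------------------------------------------

def sequence_response(seq: VecSequence, model: LinearResponseModel) -> np.ndarray:
    """Per-trial adaptation deviation driven by the clamp-angle sequence.

    deviation(t) = k_stiff * angle(t) + k_learn * angle(t-1); the first trial
    has no lagged term.
    """
    a = seq.angles
    dev = model.k_stiff * a
    dev[1:] = dev[1:] + model.k_learn * a[:-1]
    return dev


def estimate_sequence_effect(mean_1a: np.ndarray, mean_1b: np.ndarray) -> np.ndarray:
    """Sequence-driven effect trace from the two mirrored experiment arms.

    With arm 1a seeing sequence s and arm 1b its mirror, shared decay cancels
    in the half-difference and the arm-1a sequence response remains:
    effect = (mean_1a - mean_1b) / 2.
    """
    mean_1a = np.asarray(mean_1a, dtype=float)
    mean_1b = np.asarray(mean_1b, dtype=float)
    if mean_1a.shape != mean_1b.shape:
        raise ValueError("arm means must have equal length")
    return (mean_1a - mean_1b) / 2.0


def remove_sequence_effect(series: TrialSeries, effect: np.ndarray,
                           group: str) -> TrialSeries:
    """Subtract the estimated sequence effect from a subject's retention trials.

    Group "1a" subjects saw the original sequence (subtract the effect);
    group "1b" subjects saw the mirror (subtract the negated effect).
    """
    if group not in ("1a", "1b"):
        raise ValueError(f"unknown group {group!r}; expected '1a' or '1b'")
    effect = np.asarray(effect, dtype=float)
    ret_mask = series.t >= 1
    if effect.shape[0] != int(ret_mask.sum()):
        raise ValueError("effect length must equal the retention length")
    value = series.value.copy()
    value[ret_mask] = value[ret_mask] - (effect if group == "1a" else -effect)
    return TrialSeries(subject_id=series.subject_id, t=series.t.copy(),
                       value=value, probe=series.probe, truth=series.truth)


def trial_to_trial_variance(trace) -> float:
    """Variance (unbiased) of the trial-to-trial changes d(t) = x(t) - x(t-1)."""
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 2:
        raise ValueError("need at least 2 trials")
    return float(np.var(np.diff(trace), ddof=1))
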