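"""Adaptation measures computed from within-trial force/velocity profiles.

During an error-clamp trial the channel constrains the hand to a straight
path and records the lateral force the subject pushes into the channel wall.
For a curl force field F = B @ v with B = [[0, b], [-b, 0]] (gain b in
N s/m), the ideal compensatory lateral force is proportional to the forward
velocity, F_lat(t) = b * v_forward(t).  Two scalar per-trial adaptation
measures are supported:

* ``adaptation_coefficient`` — through-origin regression slope of the measured
  lateral force on the ideal +FF force (sensitive to force-profile shape), and
* ``integrated_lateral_force`` — ratio of time-integrals (shape-agnostic).

Both score +1 for perfect compensation of the +FF field and -1 for perfect
-FF compensation.  The module also provides control-referencing against a
null-field cohort, window-level movement characteristics, the balanced
overall-decay statistic with a subject-level bootstrap, and a synthetic
kinematics generator (minimum-jerk trials) so the force measures are testable
without robot data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KinematicTrial",
    "ForceFieldSpec",
    "DecaySummary",
    "ideal_force_profile",
    "adaptation_coefficient",
    "integrated_lateral_force",
    "control_reference",
    "movement_characteristics",
    "overall_decay",
    "synth_kinematics",
    "analysis_window",
]

SAMPLE_HZ = 200.0
MOVEMENT_LENGTH_M = 0.10
ONSET_SPEED_M_S = 0.05  # movement onset: forward speed crosses 5 cm/s
REWARD_RADIUS_M = 0.006
REWARD_WINDOW_S = (0.150, 0.250)


@dataclass(frozen=True)
class ForceFieldSpec:
    """Velocity-dependent curl field F = B @ v with B = [[0, b], [-b, 0]]."""

    gain_b: float = 15.0

    @property
    def matrix(self) -> np.ndarray:
        b = self.gain_b
        return np.array([[0.0, b], [-b, 0.0]])

    def force(self, vel_xy: np.ndarray) -> np.ndarray:
        """Field force for velocity rows (n, 2); orthogonal to v for all v."""
        return np.asarray(vel_xy, dtype=float) @ self.matrix.T


@dataclass
class KinematicTrial:
    """Within-trial kinematics and measured clamp force on a 200 Hz grid."""

    time: np.ndarray
    pos_xy: np.ndarray
    vel_xy: np.ndarray
    lateral_force: np.ndarray
    angle: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pos_xy = np.asarray(self.pos_xy, dtype=float)
        self.vel_xy = np.asarray(self.vel_xy, dtype=float)
        self.lateral_force = np.asarray(self.lateral_force, dtype=float)
        n = len(self.time)
        if not (len(self.pos_xy) == len(self.vel_xy) == len(self.lateral_force) == n):
            raise ValueError("all per-sample arrays must share length")

    @property
    def v_forward(self) -> np.ndarray:
        return self.vel_xy[:, 1]


@dataclass(frozen=True)
class DecaySummary:
    """Balanced overall-decay quantification across +FF / -FF subgroups."""

    LP: float
    LN: float
    RP: float
    RN: float
    overall_decay: float
    boot_se: float
    n_boot: int
    windows: dict


def ideal_force_profile(vel_forward, ff: ForceFieldSpec) -> np.ndarray:
    """Ideal compensatory lateral force b * v_forward for the given field."""
    v = np.asarray(vel_forward, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocities must be finite")
    return ff.gain_b * v


def adaptation_coefficient(measured, ideal_pos) -> float:
    """Through-origin regression slope of measured force on the ideal +FF force."""
    m = np.asarray(measured, dtype=float)
    i = np.asarray(ideal_pos, dtype=float)
    if m.shape != i.shape:
        raise ValueError("measured and ideal must have equal length")
    denom = float(i @ i)
    if denom == 0.0:
        raise ValueError("ideal force profile is identically zero")
    return float(m @ i) / denom


def integrated_lateral_force(measured, ideal_pos, dt: float = 1.0 / SAMPLE_HZ) -> float:
    """Ratio of trapezoidal time-integrals, insensitive to within-trial timing."""
    m = np.asarray(measured, dtype=float)
    i = np.asarray(ideal_pos, dtype=float)
    if m.shape != i.shape:
        raise ValueError("measured and ideal must have equal length")
    denom = float(np.trapezoid(i, dx=dt))
    if denom == 0.0:
        raise ValueError("ideal force integral is zero")
    return float(np.trapezoid(m, dx=dt)) / denom


def control_reference(traces: np.ndarray, control_mean: np.ndarray) -> np.ndarray:
    """Subtract the trial-aligned control (0-FF cohort) mean from measures.

    ``traces`` may be a 1-D per-trial measure vector or a (trials, samples)
    force-profile matrix; ``control_mean`` must match along the trailing axes.
    """
    traces = np.asarray(traces, dtype=float)
    control_mean = np.asarray(control_mean, dtype=float)
    if traces.shape[-control_mean.ndim:] != control_mean.shape:
        raise ValueError("control mean does not align with traces")
    return traces - control_mean


def analysis_window(trial: KinematicTrial,
                    to_target: bool = True) -> slice:
    """Sample window from movement onset to target arrival (or trace end).

    Onset is the first sample whose forward speed reaches 5 cm/s; arrival the
    first sample at or beyond 10 cm forward travel.
    """
    v = trial.v_forward
    onset_idx = np.flatnonzero(np.abs(v) >= ONSET_SPEED_M_S)
    start = int(onset_idx[0]) if len(onset_idx) else 0
    if not to_target:
        return slice(start, len(v))
    forward = trial.pos_xy[:, 1] - trial.pos_xy[0, 1]
    arr = np.flatnonzero(forward >= MOVEMENT_LENGTH_M)
    stop = int(arr[0]) + 1 if len(arr) else len(v)
    return slice(start, stop)


def _movement_angle(trial: KinematicTrial) -> float:
    """Movement direction (deg) of the position at target distance."""
    rel = trial.pos_xy - trial.pos_xy[0]
    forward = rel[:, 1]
    idx = np.flatnonzero(forward >= MOVEMENT_LENGTH_M)
    i = int(idx[0]) if len(idx) else int(np.argmax(forward))
    return math.degrees(math.atan2(rel[i, 0], rel[i, 1]))


def _rewarded(trial: KinematicTrial) -> bool:
    """Passes within 6 mm of target center 150-250 ms after movement onset."""
    v = trial.v_forward
    onset_idx = np.flatnonzero(np.abs(v) >= ONSET_SPEED_M_S)
    if not len(onset_idx):
        return False
    t0 = trial.time[int(onset_idx[0])]
    target = trial.pos_xy[0] + np.array([0.0, MOVEMENT_LENGTH_M])
    in_window = (trial.time >= t0 + REWARD_WINDOW_S[0]) & (trial.time <= t0 + REWARD_WINDOW_S[1])
    if not in_window.any():
        return False
    d = np.linalg.norm(trial.pos_xy[in_window] - target, axis=1)
    return bool(np.min(d) <= REWARD_RADIUS_M)


def _duration(trial: KinematicTrial) -> float:
    v = trial.v_forward
    onset_idx = np.flatnonzero(np.abs(v) >= ONSET_SPEED_M_S)
    start = int(onset_idx[0]) if len(onset_idx) else 0
    forward = trial.pos_xy[:, 1] - trial.pos_xy[0, 1]
    arr = np.flatnonzero(forward >= MOVEMENT_LENGTH_M)
    stop = int(arr[0]) if len(arr) else len(forward) - 1
    return float(trial.time[stop] - trial.time[start])


def _curvature(trial: KinematicTrial) -> float:
    """Sum of squared lateral deviations from the start-to-end straight line."""
    rel = trial.pos_xy - trial.pos_xy[0]
    end = rel[-1]
    norm = np.linalg.norm(end)
    if norm == 0.0:
        return 0.0
    u = end / norm
    lateral = rel[:, 0] * u[1] - rel[:, 1] * u[0]  # signed distance to the chord
    return float(np.sum(lateral ** 2))


def movement_characteristics(trials: Sequence[KinematicTrial]) -> dict:
    """Window-level movement statistics over a set of trials.

    Returns directional variability (sd of per-trial movement angle, deg),
    probability of reward, mean movement duration (s), mean trajectory
    curvature (sum of squared lateral deviations, m^2), and intermovement
    consistency (reported as NaN; not computed by this package).
    """
    if len(trials) == 0:
        raise ValueError("empty trial window")
    angles = np.array([_movement_angle(tr) for tr in trials])
    return {
        "directional_variability": float(np.std(angles, ddof=1)) if len(trials) > 1 else 0.0,
        "p_reward": float(np.mean([_rewarded(tr) for tr in trials])),
        "duration": float(np.mean([_duration(tr) for tr in trials])),
        "curvature": float(np.mean([_curvature(tr) for tr in trials])),
        "intermovement_consistency": float("nan"),
    }


# --------------------------------------------------------------------------
# overall decay
# --------------------------------------------------------------------------

def overall_decay(
    learning: np.ndarray,
    retention: np.ndarray,
    subgroup: Sequence[str],
    rng: Optional[np.random.Generator] = None,
    n_boot: int = 10_000,
    windows: Optional[dict] = None,
) -> DecaySummary:
    """Balanced fractional decay ((LP-LN) - (RP-RN)) / (LP-LN).

    ``learning`` and ``retention`` hold one asymptotic value per subject
    (mean of the last 150 training trials and of the retention trials after
    the first 150, respectively); ``subgroup`` labels each subject "P" (+FF)
    or "N" (-FF).  The standard error is a subject-level bootstrap (resampling
    within each subgroup).  Adding any constant to all subjects' values leaves
    the statistic unchanged.
    """
    learning = np.asarray(learning, dtype=float)
    retention = np.asarray(retention, dtype=float)
    labels = np.asarray(subgroup)
    pos = labels == "P"
    neg = labels == "N"
    if not pos.any() or not neg.any():
        raise ValueError("both +FF and -FF subgroups must be non-empty")

    def stat(lp_idx, ln_idx):
        LP = learning[lp_idx].mean()
        LN = learning[ln_idx].mean()
        RP = retention[lp_idx].mean()
        RN = retention[ln_idx].mean()
        denom = LP - LN
        if denom == 0.0:
            raise ZeroDivisionError("no learning separation between subgroups (LP = LN)")
        return LP, LN, RP, RN, (denom - (RP - RN)) / denom

    pos_idx = np.flatnonzero(pos)
    neg_idx = np.flatnonzero(neg)
    LP, LN, RP, RN, value = stat(pos_idx, neg_idx)

    if rng is None:
        rng = np.random.default_rng()
    boots = np.empty(n_boot)
    for k in range(n_boot):
        bp = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        bn = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        try:
            boots[k] = stat(bp, bn)[4]
        except ZeroDivisionError:
            boots[k] = np.nan
    boot_se = float(np.nanstd(boots, ddof=1))
    return DecaySummary(LP=LP, LN=LN, RP=RP, RN=RN, overall_decay=value,
                        boot_se=boot_se, n_boot=n_boot,
                        windows=windows or {"learning": "last 150 training",
                                            "retention": "after first 150 retention"})


# --------------------------------------------------------------------------
# synthetic kinematics fixture generator
# --------------------------------------------------------------------------

def _min_jerk(duration: float, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk position/velocity profiles for a 10 cm movement."""
    t = np.arange(n) / SAMPLE_HZ
    s = np.clip(t / duration, 0.0, 1.0)
    pos = MOVEMENT_LENGTH_M * (10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5)
    vel = MOVEMENT_LENGTH_M * (30 * s ** 2 - 60 * s ** 3 + 30 * s ** 4) / duration
    vel[t > duration] = 0.0
    return t, pos, vel


def synth_kinematics(
    angle: float = 0.0,
    duration: float = 0.2,
    adaptation_level: float = 1.0,
    ff: ForceFieldSpec = ForceFieldSpec(+15.0),
    shape_shift_s: float = 0.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    tail_s: float = 0.25,
) -> KinematicTrial:
    """Generate one synthetic error-clamp trial.

    The hand follows a minimum-jerk 10 cm trajectory in direction ``angle``
    (degrees from straight ahead); the measured lateral force equals
    ``adaptation_level`` times the ideal +FF compensatory force, optionally
    time-shifted by ``shape_shift_s`` (equal area, later timing — a profile
    distortion that leaves the integrated measure unchanged but lowers the
    regression measure) plus white sensor noise.  The trace extends ``tail_s``
    seconds past movement end so shifted profiles stay fully sampled.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round((duration + tail_s) * SAMPLE_HZ)) + 1
    t, s_pos, s_vel = _min_jerk(duration, n)
    rad = math.radians(angle)
    u = np.array([math.sin(rad), math.cos(rad)])
    pos_xy = np.outer(s_pos, u)
    vel_xy = np.outer(s_vel, u)
    ideal = ideal_force_profile(vel_xy[:, 1], ff)
    if shape_shift_s:
        measured = adaptation_level * np.interp(t - shape_shift_s, t, ideal,
                                                left=0.0, right=0.0)
    else:
        measured = adaptation_level * ideal
    if noise_sd:
        if rng is None:
            rng = np.random.default_rng()
        measured = measured + rng.normal(0.0, noise_sd, size=n)
    return KinematicTrial(time=t, pos_xy=pos_xy, vel_xy=vel_xy,
                          lateral_force=measured, angle=angle)
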