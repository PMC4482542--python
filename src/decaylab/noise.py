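"""Correlated-noise (drift) characterisation of retention traces.

Individual retention curves carry slowly varying correlated noise — drift —
on top of the mean decay.  Drift is characterised by the autocorrelation
function (Pearson correlation between a series and its lag-tau shift) and the
partial autocorrelation function (the coefficient on the lag-tau term when
regressing x(t) jointly on x(t-1)..x(t-tau)), computed on per-subject
residuals after removing the across-subject mean from retention trial 76
onward.  Drift is modelled as ARMA(1,1),

    x(t) = AR * x(t-1) + eps(t) + MA * eps(t-1),

estimated by conditional least squares with eps(0) = 0 (a state-space
maximum-likelihood mode is available as a cross-check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz
from scipy.optimize import minimize
from scipy.signal import lfilter

from .cohort import ArmaSpec, TrialSeries
from .fitting import FitConstraints, fit_delayed_exponential

__all__ = [
    "CorrelationProfile",
    "demean_across_subjects",
    "autocorrelation",
    "partial_autocorrelation",
    "correlation_profile",
    "fit_arma11",
    "drift_population_stats",
    "population_comparison",
]


@dataclass(frozen=True)
class CorrelationProfile:
    """ACF (lags 0..L) and PACF (lags 1..L) of one series of length n."""

    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    n: int


def demean_across_subjects(
    traces: Sequence[TrialSeries], start_trial: int = 76
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-subject residuals after removing the across-subject mean per trial.

    Keeps retention trials >= ``start_trial`` so the correlation analysis sees
    the drift rather than the mean decay.  Returns ``(t, residuals)`` with
    residuals shaped (n_subjects, n_trials); each residual column sums to zero.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 subjects")
    t0 = traces[0].t
    mask = t0 >= start_trial
    t = t0[mask]
    rows = []
    for s in traces:
        if not np.array_equal(s.t, t0):
            raise ValueError("traces are not trial-aligned")
        rows.append(s.value[mask])
    X = np.vstack(rows)
    return t, X - X.mean(axis=0, keepdims=True)


# --------------------------------------------------------------------------
# ACF / PACF
# --------------------------------------------------------------------------

def autocorrelation(trace, max_lag: int) -> np.ndarray:
    """ACF by the full-overlap Pearson convention, lags 0..max_lag.

    Each lag correlates x[tau:] with x[:-tau], demeaning both segments
    separately.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    if np.std(x) == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = np.corrcoef(x[k:], x[:-k])[0, 1]
    return out


def _sample_acov(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/n) sample autocovariances about the common mean."""
    x = x - x.mean()
    n = len(x)
    return np.array([x[k:] @ x[: n - k] / n for k in range(max_lag + 1)])


def _pacf_ols(x: np.ndarray, max_lag: int) -> np.ndarray:
    """PACF by the regression definition: for each lag tau, the coefficient on
    x(t-tau) when regressing x(t) on x(t-1)..x(t-tau) (with intercept)."""
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        y = x[k:]
        X = np.column_stack([x[k - j: len(x) - j] for j in range(1, k + 1)])
        X = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[k - 1] = beta[-1]
    return out


def _pacf_yule_walker(x: np.ndarray, max_lag: int) -> np.ndarray:
    """PACF from the sample ACF by directly solving the Toeplitz
    Yule-Walker system at each order."""
    r = _sample_acov(x, max_lag)
    r = r / r[0]
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        phi = solve_toeplitz(r[:k], r[1: k + 1])
        out[k - 1] = phi[-1]
    return out


def _pacf_durbin_levinson(acf: np.ndarray) -> np.ndarray:
    """PACF via the Durbin-Levinson recursion on a (normalised) ACF.

    Algebraically identical to solving each Yule-Walker system directly; kept
    as the independent route for the dual-implementation check.
    """
    max_lag = len(acf) - 1
    pacf = np.empty(max_lag)
    phi_prev = np.array([acf[1]])
    pacf[0] = acf[1]
    for k in range(2, max_lag + 1):
        num = acf[k] - phi_prev @ acf[k - 1:0:-1]
        den = 1.0 - phi_prev @ acf[1:k]
        phi_kk = num / den
        phi = np.empty(k)
        phi[:-1] = phi_prev - phi_kk * phi_prev[::-1]
        phi[-1] = phi_kk
        pacf[k - 1] = phi_kk
        phi_prev = phi
    return pacf


def partial_autocorrelation(trace, max_lag: int, method: str = "ols") -> np.ndarray:
    """PACF at lags 1..max_lag.

    ``method="ols"`` (default) is the definitional lag-regression estimator;
    ``"yule-walker"`` and ``"durbin-levinson"`` are the ACF-based routes,
    which agree with each other to machine precision.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    if np.std(x) == 0:
        raise ValueError("partial autocorrelation undefined for a constant series")
    if method == "ols":
        return _pacf_ols(x, max_lag)
    if method == "yule-walker":
        return _pacf_yule_walker(x, max_lag)
    if method == "durbin-levinson":
        r = _sample_acov(x, max_lag)
        return _pacf_durbin_levinson(r / r[0])
    raise ValueError(f"unknown method {method!r}")


def correlation_profile(trace, max_lag: int = 10) -> CorrelationProfile:
    x = np.asarray(trace, dtype=float)
    return CorrelationProfile(
        lags=np.arange(max_lag + 1),
        acf=autocorrelation(x, max_lag),
        pacf=partial_autocorrelation(x, max_lag),
        n=len(x),
    )


# --------------------------------------------------------------------------
# ARMA(1,1) estimation
# --------------------------------------------------------------------------

def _cls_sse(x: np.ndarray, ar: float, ma: float) -> float:
    # conditional residuals with eps(0) = 0: e(t) = x(t) - ar x(t-1) - ma e(t-1)
    d = x[1:] - ar * x[:-1]
    e = lfilter([1.0], [1.0, ma], d)
    return float(e @ e)


def fit_arma11(trace, demean: bool = True, method: str = "cls") -> ArmaSpec:
    """Estimate (AR, MA, eps_sd) of an ARMA(1,1) model.

    The default is conditional least squares: residuals are computed
    recursively with the initial innovation fixed at zero, and the summed
    squared residuals are minimised over |AR| < 1, |MA| < 1 from several
    starts.  ``method="mle"`` delegates to statsmodels' state-space maximum
    likelihood as an alternative mode.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) < 50:
        raise ValueError("series must have at least 50 points for ARMA fitting")
    if demean:
        x = x - x.mean()
    if method == "mle":
        from statsmodels.tsa.arima.model import ARIMA
        res = ARIMA(x, order=(1, 0, 1), trend="n").fit()
        ar = float(res.arparams[0])
        ma = float(res.maparams[0])
        return ArmaSpec(ar=np.clip(ar, -0.999, 0.999), ma=ma,
                        eps_sd=float(np.sqrt(res.params[-1])))
    if method != "cls":
        raise ValueError(f"unknown method {method!r}")

    bounds = [(-0.995, 0.995), (-0.995, 0.995)]
    best = None
    for x0 in ((0.0, 0.0), (0.5, -0.3), (0.9, -0.5), (-0.5, 0.3)):
        res = minimize(lambda p: _cls_sse(x, p[0], p[1]), x0,
                       method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        warnings.warn("ARMA(1,1) conditional least squares did not converge")
    ar, ma = best.x
    n_eff = len(x) - 1
    eps_sd = float(np.sqrt(best.fun / max(n_eff - 2, 1)))
    return ArmaSpec(ar=float(np.clip(ar, -0.999, 0.999)), ma=float(ma), eps_sd=eps_sd)


# --------------------------------------------------------------------------
# population comparisons (data vs simulation)
# --------------------------------------------------------------------------

def drift_population_stats(
    cohort: Sequence[TrialSeries],
    start_trial: int = 76,
    min_len: int = 50,
) -> pd.DataFrame:
    """Per-subject decay/noise descriptors for population comparison.

    For each subject: decay depth and rate from a zero-delay delayed
    exponential fit (lam fixed at 0), the retention-residual noise sd, the
    ARMA(1,1) estimate, and PACF lags 1-3 of the demeaned late-retention
    residual.  Subjects with residual series shorter than ``min_len`` are
    excluded with a warning.
    """
    t, resid = demean_across_subjects(cohort, start_trial=start_trial)
    rows = []
    zero_lam = FitConstraints(lam_bounds=(-1e-6, 1e-6))
    for i, s in enumerate(cohort):
        r = resid[i]
        if len(r) < min_len:
            warnings.warn(f"excluding subject {s.subject_id}: residual series too short")
            continue
        fit = fit_delayed_exponential(s, constraints=zero_lam, lam_step=1e-6)
        arma = fit_arma11(r)
        pac = partial_autocorrelation(r, 3)
        rows.append({
            "subject_id": s.subject_id,
            "decay_depth": fit.params.a - fit.params.b,
            "decay_rate": fit.params.tau,
            "retention_noise_sd": float(np.std(r, ddof=1)),
            "ar": arma.ar, "ma": arma.ma, "eps_sd": arma.eps_sd,
            "pac1": pac[0], "pac2": pac[1], "pac3": pac[2],
        })
    return pd.DataFrame(rows)


def population_comparison(
    data_fits: pd.DataFrame,
    sim_fits: pd.DataFrame,
    quantities: Sequence[str] = ("decay_depth", "decay_rate",
                                 "retention_noise_sd", "pac1", "pac2", "pac3"),
    n_bins: int = 20,
) -> dict:
    """Aligned summary statistics and histograms for two fitted populations."""
    if len(data_fits) == 0 or len(sim_fits) == 0:
        raise ValueError("both fit collections must be non-empty")
    summary_rows, hists = [], {}
    for q in quantities:
        a = data_fits[q].to_numpy(dtype=float)
        b = sim_fits[q].to_numpy(dtype=float)
        summary_rows.append({
            "quantity": q,
            "data_mean": a.mean(), "data_sd": a.std(ddof=1),
            "sim_mean": b.mean(), "sim_sd": b.std(ddof=1),
            "data_median": float(np.median(a)), "sim_median": float(np.median(b)),
        })
        edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=n_bins)
        hists[q] = {
            "edges": edges,
            "data_counts": np.histogram(a, bins=edges)[0],
            "sim_counts": np.histogram(b, bins=edges)[0],
        }
    return {"summary": pd.DataFrame(summary_rows).set_index("quantity"), "histograms": hists}
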