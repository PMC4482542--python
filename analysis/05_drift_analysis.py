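"""Drift characterisation and its effect on individual delay estimates.

Simulates 60-subject cohorts from the zero-delay generative model with and
without ARMA(1,1) retention drift, then (a) characterises the noise structure
(ACF/PACF of demeaned late-retention residuals, per-subject ARMA fits) and
(b) fits every subject with an unconstrained delayed exponential to measure
how drift broadens the distribution of best-fit onset delays even though
every simulated subject decays immediately.

Writes results/drift_population_stats.csv, results/drift_correlograms.csv
and results/drift_delay_iqr.json.  Runtime ~1 minute.
"""

import json
import pathlib

import numpy as np
import pandas as pd

from decaylab import cohort as chm
from decaylab import fitting as fit
from decaylab import noise

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 0
N_SUBJECTS = 60

rng = np.random.default_rng(SEED)
cohorts = {
    "drift": chm.simulate_drift_cohort(chm.DRIFT_ADJUSTED, N_SUBJECTS, rng, drift=True),
    "no_drift": chm.simulate_drift_cohort(chm.DRIFT_ADJUSTED, N_SUBJECTS, rng, drift=False),
}

stats, correlos, iqr = [], [], {}
for label, cohort in cohorts.items():
    df = noise.drift_population_stats(cohort)
    df.insert(0, "condition", label)
    stats.append(df)

    t, resid = noise.demean_across_subjects(cohort)
    for s, r in zip(cohort, resid):
        prof = noise.correlation_profile(r, max_lag=10)
        correlos.append(pd.DataFrame({
            "condition": label, "subject_id": s.subject_id,
            "lag": prof.lags[1:], "acf": prof.acf[1:], "pacf": prof.pacf,
        }))

    table, summary = fit.fit_cohort(cohort)
    iqr[label] = summary
    print(f"{label:9s}: delay IQR {summary['lam_iqr']:5.1f} trials, "
          f"median {summary['median_lam']:+5.1f}, "
          f"{100*summary['frac_r2_above_0.5']:.0f}% well-fit (R^2 > 0.5)")

pd.concat(stats, ignore_index=True).to_csv(
    OUT / "drift_population_stats.csv", index=False, float_format="%.4f")
pd.concat(correlos, ignore_index=True).to_csv(
    OUT / "drift_correlograms.csv", index=False, float_format="%.4f")
(OUT / "drift_delay_iqr.json").write_text(json.dumps(iqr, indent=2))

ratio = iqr["drift"]["lam_iqr"] / max(iqr["no_drift"]["lam_iqr"], 1e-9)
print(f"-> drift widens the spread of best-fit delays {ratio:.1f}-fold even "
      "though every simulated subject decays with zero true delay: broad "
      "individual delay estimates are not evidence of delayed decay.")
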