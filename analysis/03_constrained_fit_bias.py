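"""Demonstrate the estimation bias caused by constraining the decay onset.

Simulates subjects whose adaptation starts decaying exactly at retention
onset (true delay 0) with realistic white noise, then fits each trace twice:
once with the onset free within the data window and once constrained
non-negative.  The unconstrained estimates distribute symmetrically around
zero; the constraint folds the negative half onto zero and drags the mean
upward — apparent delays manufactured by the fitting procedure alone.

The full-scale demonstration uses 10,000 subjects; this driver runs 1,000 by
default (set N_SUBJECTS below), which reproduces the same picture in a couple
of minutes.  Writes results/bias_delays.csv and prints the summary.
"""

import pathlib

import numpy as np
import pandas as pd

from decaylab import fitting as fit

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 0
N_SUBJECTS = 1000

out = fit.bias_experiment(n=N_SUBJECTS, rng=np.random.default_rng(SEED))
s = out["summary"]

pd.DataFrame({"unconstrained": out["unconstrained"],
              "constrained": out["constrained"]}).to_csv(
    OUT / "bias_delays.csv", index=False, float_format="%.4f")

print(f"n = {s['n']} zero-delay subjects (noise sd 0.2)")
print(f"unconstrained delay estimates: mean {s['unconstrained_mean']:+.2f}, "
      f"median {s['unconstrained_median']:+.2f} trials; "
      f"{100*s['unconstrained_frac_below_zero']:.0f}% negative")
print(f"constrained (lam >= 0):        mean {s['constrained_mean']:+.2f}, "
      f"median {s['constrained_median']:+.2f} trials; "
      f"{100*s['constrained_frac_at_zero']:.0f}% pinned at exactly 0")
print("-> the constraint turns a symmetric zero-centred distribution into an "
      "exclusively non-negative one with a strictly positive mean.")
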