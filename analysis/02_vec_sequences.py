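"""Generate a balanced vEC sequence pair and demonstrate sequence removal.

Rejection-samples an acceptable 325-trial variable-error-clamp direction
sequence, mirrors it, and simulates two mirrored experiment arms whose
subjects respond linearly to the imposed errors (same-trial stiffness gain
-0.03 per degree plus a next-trial learning gain).  Averaging the arms
cancels the sequence-driven oscillations; the half-difference of the arm
means recovers the sequence response, which is then removed from individual
subjects.

Writes results/vec_sequence_a.csv, results/vec_sequence_b.csv and
results/vec_balancing.json.  Runtime well under a minute.
"""

import json
import pathlib

import numpy as np
import pandas as pd

from decaylab.pipeline import RunConfig, run_reproduction
from decaylab import sequences as seq

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 0

s = seq.generate_sequence(rng=np.random.default_rng(SEED))
m = seq.mirror(s)
pd.DataFrame({"angle_deg": s.angles}).to_csv(OUT / "vec_sequence_a.csv",
                                             index=False, float_format="%.6f")
pd.DataFrame({"angle_deg": m.angles}).to_csv(OUT / "vec_sequence_b.csv",
                                             index=False, float_format="%.6f")
print(f"accepted sequence after {s.attempts} candidates "
      f"(sd {np.std(s.angles, ddof=1):.2f} deg); mirror written alongside")

report = run_reproduction("balancing", RunConfig(seed=SEED))
v = report["values"]
(OUT / "vec_balancing.json").write_text(json.dumps(v, indent=2))
print(f"trial-to-trial variance of the arm-mean retention curve: "
      f"{v['raw_trial_to_trial_variance']:.5f} raw vs "
      f"{v['balanced_trial_to_trial_variance']:.5f} after balancing "
      f"({100*v['variance_reduction']:.0f}% reduction)")
print(f"half-difference estimate vs true sequence response: "
      f"r = {v['effect_vs_true_response_corr']:.2f}")
print("-> the sequence-specific oscillations cancel under mirror balancing, "
      "revealing the underlying decay.")
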