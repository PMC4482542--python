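# decaylab

Simulation and inference tools for a core question in motor learning: when a
trained motor adaptation stops being reinforced (the perturbing force field is
replaced by error-clamp trials), does the learned behaviour decay
*immediately*, trial by trial — or does it hold steady until the subject
*detects* that the context has changed, predicting a decay-onset **delay**?

The package implements the full computational apparatus needed to answer this
with synthetic data:

* **Cohort simulation** (`decaylab.cohort`) — per-subject adaptation traces
  over a 300-trial training block and a 325-trial retention block, following a
  delayed exponential

  `f(t) = a` for `t ≤ λ`, `f(t) = (a − b)·exp(−(t − λ)/τ) + b` for `t > λ`,

  with white measurement noise, optional ARMA(1,1) correlated noise
  ("drift"), exponentially distributed onset delays `λ ~ Expo(μ_λ)`, and the
  20%-probe measurement structure of the experimental design.
* **vEC sequence design** (`decaylab.sequences`) — rejection sampling of
  variable-error-clamp direction sequences (N(0°, 2.6°²)) whose ternary miss
  patterns are locally balanced, mirror-pair balancing, and removal of the
  sequence-driven motor response from retention traces.
* **Force-based adaptation measures** (`decaylab.measures`) — adaptation
  coefficient (through-origin regression on the ideal curl-field compensation
  `b·v_forward`), integrated lateral force, control referencing, movement
  characteristics, and the balanced overall-decay statistic with a
  subject-level bootstrap.
* **Delay fitting** (`decaylab.fitting`) — bounded variable-projection
  least squares for the delayed exponential, with the onset either free
  within the data window or constrained non-negative, plus the demonstration
  that the non-negativity constraint manufactures apparent delays on
  zero-delay noisy data.
* **Group-level Bayesian inference** (`decaylab.group`) — median division
  into high/low-decay subgroups, the early decay ratio
  `ED = (learning − early retention)/(learning − late retention)`, and a
  simulation-based posterior `P(μ_λ | ED_high, ED_low)` over the mean delay
  on the integer grid 0..90 trials with a uniform prior.
* **Drift characterisation** (`decaylab.noise`) — ACF, regression-defined
  PACF, conditional-least-squares ARMA(1,1) estimation, and data-vs-model
  population comparisons.

The scientific model, parameter values and estimator conventions are
documented in [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the main analyses at reduced
problem sizes and write their tables under `results/`. For example, the
constrained-fitting bias demonstration:

```bash
$ python analysis/03_constrained_fit_bias.py
n = 1000 zero-delay subjects (noise sd 0.2)
unconstrained delay estimates: mean -0.00, median +0.00 trials; 48% negative
constrained (lam >= 0):        mean +3.11, median +0.75 trials; 47% pinned at exactly 0
```

Every simulated subject here truly starts decaying at retention onset
(delay 0). With the onset free, estimates centre on zero; forcing the onset
to be non-negative folds the negative half of the distribution onto zero and
drags the mean up by three trials — apparent delay created entirely by the
fitting constraint.

The group-level inference script reads the two observed early-decay pairs
through the simulated likelihood:

```bash
$ python analysis/04_group_inference.py
...
exp1 (n=40, observed ED high/low 0.67/0.31): MAP = 0 trials, 95% HPD (0, 1), 99% HPD (0, 4)
exp2 (n=20, observed ED high/low 0.69/0.4): MAP = 0 trials, 95% HPD (0, 2), 99% HPD (0, 5)
```

Both posteriors concentrate at a mean onset delay of zero trials: decay
begins immediately whether or not the context change is masked. (This driver
uses 300 simulations per grid point; the acceptance script below runs the
full 1000.)

A thin CLI exposes the same operations
(`decaylab simulate|vecgen|fit|group-infer|drift|reproduce|fixtures`); try
`decaylab reproduce --target exp_facts`.

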