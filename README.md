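# fibrosim

Stochastic simulation and estimation of liver fibrosis progression in
NAFLD/NASH, built for clinical-trial design questions: how big is the
placebo response for a given baseline cohort, which disease transitions move
the average fibrosis score the most, and how many patients per arm does a
trial need?

## Who this is for

Quantitative clinical pharmacologists, biostatisticians and modellers
working on NASH trials who need a transparent, reproducible patient-level
disease-progression simulator that can be fitted to the kind of data the
field actually publishes: paired-biopsy transition tables and arm-level
stage distributions.

## The model

A patient's fibrosis stage F0–F4 evolves as a birth–death continuous-time
Markov chain. Adjacent stages are linked by forward rates p1, p3, p5, p7 and
reverse rates p2, p4, p6, p8 (per month); 1/rate is the mean transition time
τ in months. A patient starting at F0 is a *progressor* with probability p0
(the progressor fraction) and otherwise never leaves F0. Trajectories are
simulated by competing exponential clocks: a waiting time τ = (1/λ) ln(1/u)
is drawn for each enabled transition and the shortest fires. The matrix
exponential of the generator provides the exact stage-occupancy
probabilities and is used both as a test oracle and as the deterministic
objective in fitting.

Interventions enter as scale factors: α (four multipliers on the forward
rates) captures the placebo effect of trial participation, and β (eight
multipliers on all rates) captures a drug effect on top of it. Estimation is
staged — natural-history rates first, then α per study, then β — and an
evolutionary optimizer (differential evolution, ≤200 individuals ×
≤100 generations) searches mean transition times on a log scale.

The package ships the printed parameter sets (`fitted`, `placebo`,
`pioglitazone`), the 18-month placebo-controlled pioglitazone trial tables,
and reference cohort mixes, plus a generator of synthetic paired-biopsy
studies with known ground truth for testing every fitting stage.

## Worked example

```python
import numpy as np
import fibrosim as fs
from fibrosim.trial import stage_outcome_fractions, placebo_response, power_analysis

fx = fs.builtin_fixtures()
placebo = fx["placebo"]

rng = np.random.default_rng(42)
f1 = stage_outcome_fractions(placebo, stage=1, n_patients=100,
                             horizon=12.0, n_reps=500, rng=rng)
print(f"F1 starters improved: {f1.improved:.1%} +/- {f1.improved_se:.1%}")

resp = placebo_response(placebo, fx["typical_mix"], n_patients=100,
                        horizon=12.0, n_reps=500, rng=rng)
print(f"typical cohort improved: {resp.mean:.1%} "
      f"(90% band {resp.lower_5:.1%}-{resp.upper_95:.1%})")

curve = power_analysis(placebo, fx["pioglitazone"], fx["cusi_pooled_mix"],
                       n_grid=[65], n_distributions=90,
                       sims_per_distribution=200, rng=np.random.default_rng(42))
print(f"power at n=65 per arm: {curve.power_mean[0]:.1%}")
```

prints

```
F1 starters improved: 40.7% +/- 0.2%
typical cohort improved: 20.2% (90% band 14.0%-27.0%)
power at n=65 per arm: 98.0%
```

Read: over 12 months under placebo-arm dynamics, about 41% of patients who
start at stage F1 regress to F0 — a large, purely baseline-dependent placebo
response — while a typical mixed cohort (35% F0, 44% F1, 10% F2, 12% F3)
shows about 20% improvement, with wide trial-to-trial spread at n = 100.
A two-arm trial with 65 patients per arm, baseline drawn like the reference
trial and a pioglitazone-like drug effect, has ~98% analytic power to detect
a 0.5-stage difference in mean score change at α = 0.05.

The same analyses are available from the shell:

```sh
fibrosim trial placebo-response --mix typical --seed 42 --out resp.json
fibrosim sensitivity --param p2 --folds 0.001:100:25log --seed 1 --out curve.csv
fibrosim synth --params fitted --per-stage 500 --times 6,24,72,156 --seed 1 --out study.csv
fibrosim fit observational --data study.csv --seed 1 --out fit.json
```

Every command takes `--seed` and writes a `.meta.json` sidecar sufficient to
re-run it exactly.

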