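# Methods

## The model

Liver fibrosis in NAFLD/NASH is staged ordinally from F0 (no fibrosis) to F4
(cirrhosis). `fibrosim` models a patient's stage as a birth–death
continuous-time Markov chain (CTMC) on these five states. Adjacent stages are
connected by forward (progression) rates p1, p3, p5, p7 and reverse
(regression) rates p2, p4, p6, p8, all in units of 1/month. The reciprocal of
a rate is the mean transition time τ in months, which is the convention used
in printed parameter tables and in the JSON parameter files.

A ninth parameter, the progressor fraction p0, captures the observation that
a large share of patients scored F0 never develop fibrosis: each patient
starting at F0 is designated a progressor with probability p0, once, at time
zero. Non-progressors stay at F0 forever. Patients starting at F1–F4 always
evolve. Because the chain is memoryless we do not re-draw the designation
when a progressor regresses to F0; such a patient may progress again. (The
alternative — re-drawing on each return to F0 — would raise the fraction of
F1 starters found improved at a fixed horizon; under the parameter sets
shipped with the package the no-re-draw rule reproduces the published
placebo-response percentages, so it is the one implemented.)

Assumptions worth stating explicitly:

* transition hazards are constant in time and across patients (heterogeneity
  enters only through the progressor split and the stochasticity of the
  chain, which is also intended to absorb biopsy sampling and scoring
  variability);
* only one-stage moves occur; an observed two-stage change over a follow-up
  interval is the composition of one-stage moves;
* F4 is not absorbing (a regression rate p8 exists); F0 is absorbing only
  for non-progressors.

## Simulation

Patient trajectories are generated by the next-reaction scheme: in each
state, a candidate exponential waiting time is drawn by inversion,
τ = (1/λ) ln(1/u) with u uniform on the open interval (0,1), for every
enabled transition (forward and/or reverse), and the transition with the
shortest time fires. Discarding the losing clock is exact by memorylessness.
Ties (a zero-probability event) resolve forward, for reproducibility. The
jump that would overshoot the observation horizon is discarded and the
patient is read at the stage occupied at the horizon.

A vectorized engine (`simulate_final_stages`) runs the identical scheme for
whole patient batches and is used wherever only endpoint stages matter
(cohort tables, sensitivity sweeps, virtual trials). The scalar
`simulate_patient` retains full event lists.

The deterministic counterpart, `transition_probability_matrix`, is the
matrix exponential of the generator built from the eight rates, with the F0
row mixed as (1−p0)·e0 + p0·expm(Qt)[0]. It serves as the oracle that the
stochastic engine is validated against (agreement within four binomial
standard errors at 10⁴ patients per initial stage) and as the variance-free
prediction mode in fitting.

## Data model and fixtures

Paired-biopsy data come in two shapes, and both are supported: full
initial×final transition tables (one row per starting stage), and
distribution-only arm summaries (baseline and follow-up marginals, the shape
in which placebo-controlled trial data are typically published). Dropout is
represented — baseline and follow-up totals may differ — and never imputed;
objectives compare completer proportions.

The package ships three parameter sets as printed in the source material:
`fitted` (natural history: forward τ 5.7/86/97/116 months, backward τ
10/51/208/526 months, p0 = 0.64), `placebo` (the fitted set with the
placebo-arm forward scale factors already composed: forward τ 9.3/68/52/374),
and `pioglitazone` (forward τ 139/1750/1570/374000, backward τ
3.8/7.6/171/2140). It also ships the 18-month placebo-controlled
pioglitazone trial tables (placebo arm 20/22/4/5/0 → 18/16/3/5/0;
drug arm 15/22/6/7/0 → 22/13/2/3/0) and two reference cohort mixes: the
"typical" mix 35/44/10/12/0 percent (the printed percentages sum to 1.01 and
are renormalized proportionally on load, with a logged warning) and a 50%
F2 / 50% F3 advanced-disease mix.

## Estimation

Fitting is staged. First the nine natural-history parameters are fitted to
observational tables spanning several follow-up times. Then, with those
frozen, a per-study placebo effect is fitted as four multipliers α on the
forward rates only (trial participation — diet and exercise advice — is
assumed to slow progression, not reverse fibrosis). Finally a drug effect is
fitted as eight multipliers β on all rates on top of α (the drug may also
accelerate regression). Scale factors multiply rates; reported fold changes
are τ ratios to match the printed convention.

The objective is a sum of squared differences between predicted and observed
final-stage proportions. For transition tables the comparison is per initial
stage and each row's errors are weighted by that row's completer count; for
arm summaries the predicted marginal (baseline proportions propagated
through the model) is compared to the observed follow-up marginal, weighted
by the completer total. Two prediction modes exist:

* `expected` (default) — matrix-exponential probabilities; deterministic,
  which keeps the optimizer's landscape noise-free;
* `simulated` — the mean of `n_reps` (default 100) stochastic cohort
  replicates, the literal trial-simulation procedure; used for final
  reporting and available for fitting.

The optimizer is differential evolution (an evolutionary algorithm) with a
budget of at most 200 individuals and 100 generations, searching log10 τ in
[1, 10⁵] months, log10 scale factors in [10⁻³, 10³] and p0 in [0, 1]
linearly, followed by a local polish. The log scale covers the printed
parameter range (3.8 to 374 000 months) with margin and makes the search
scale-free. Selection/crossover/mutation specifics are scipy's defaults,
fixed by `OptimizerConfig` and recorded in the fit report. Data spanning a
single follow-up time trigger a non-identifiability warning.

With only marginal arm summaries, four α (let alone eight β) parameters are
not all identifiable from four observed degrees of freedom dominated by the
F0/F1 stages; tests therefore assert *prediction closure* (the fitted model
reproduces the generating final distribution within sampling error) and
parameter recovery only for the well-populated early-stage multipliers.

## Sensitivity analysis

One rate at a time is multiplied by a fold change on a log-spaced grid (25
points spanning 0.001–100 by default), the trial cohort (by default the
51-patient placebo-arm baseline 20/22/4/5/0) is simulated 500 times over 24
months, and the change of the mean final average fibrosis score relative to
the unperturbed (fold = 1) simulation is recorded with its standard error.
The progressor fraction is held fixed. A deterministic oracle-mode
counterpart (`expected_score_delta`) backs the monotonicity tests: the
expected score is non-decreasing in every forward rate and non-increasing in
every reverse rate.

## Virtual trials and power

Stage-wise placebo response simulates 100 patients per starting stage for 12
months under the `placebo` parameter set and reports the fractions improved,
worsened and unchanged. Cohort-level placebo response draws each
replicate's baseline stages multinomially from a reference mix and reports
the mean fraction improving by ≥1 stage with a 5th–95th percentile band.
"Improved" always means a final stage strictly below the initial stage at
the horizon.

The power analysis compares a placebo-like and a drug-like arm over an
18-month horizon (the endpoint of the trial whose baseline proportions seed
the cohorts). For each per-arm size n (5–125 in steps of 5) and each of 90
baseline distributions drawn multinomially from the pooled trial
proportions, both arms are simulated 200 times. The per-patient score-change
SD, pooled across arms, feeds an analytic two-sample t-test power
computation (noncentral t) for detecting a 0.5-stage difference in mean
score change at α = 0.05, two-sided; the curve averages power across
distributions. An empirical mode — the rejection fraction of per-replicate
two-sample t-tests between the arms — is provided as a cross-check and is
what calibrates to the significance level under a null effect. Note the
analytic mode answers "power to detect a 0.5 difference given the observed
variability", independent of the simulated mean difference; with the shipped
parameter sets the simulated arm difference (≈0.6 stages) exceeds 0.5, so
the minimal n clearing 80% power in this mode is smaller than a design that
anchors on the simulated effect would give.

## Synthetic studies

`synthetic.generate_virtual_study` emulates the panel-study shape the
fitting code consumes: a configurable number of patients per starting stage
(default 500), independent cohorts per biopsy time (default 6, 24, 72 and
156 months, matching the span of published follow-ups), simulation under
known ground-truth rates, and observation at the biopsy time.
Missing-completely-at-random dropout removes patients from the final tallies
only. An optional symmetric ±1-stage misread probability exists but is off
by default, since the CTMC's own stochasticity is meant to absorb scoring
variability. What the generator does not emulate: informative dropout,
covariate-dependent rates, inter-study scoring drift, and correlated
sampling error within a biopsy — so passing recovery tests demonstrate
identifiability under the model's own assumptions, not robustness to
real-world biopsy artefacts.

`recovery_experiment` generates a study, refits it, and reports relative τ
errors and the p0 error. At the default design, fits recover all eight τ
within ±30% and p0 within ±0.08 in ≥90% of 20 seeded runs; the binding
constraint is the slow late-stage transitions (τ up to 526 months), which
the 156-month horizon identifies only just.

## Numerical choices

* Uniform variates are drawn from the open interval (0,1); the probability-
  zero draw u = 0 is rejected in the scalar path and yields an inert
  infinite waiting time in the vectorized path.
* `transition_probability_matrix` clips sub-machine-epsilon negative entries
  of the matrix exponential and renormalizes rows.
* Oracle-agreement tests use a 4-binomial-SE band plus one count (1/n) of
  discreteness allowance.
* The noncentral-t lower tail can underflow to NaN at large degrees of
  freedom; it is negligible there and treated as zero.
* A zero-horizon cohort simulation returns the identity table; because the
  transition-table schema requires a positive follow-up time, it is recorded
  at the smallest positive float.
* Monte-Carlo test and acceptance sizes (500 replicates, 10⁴–10⁵ draws, 20
  recovery seeds, 90 distributions × 200 simulations) follow the replicate
  counts the analyses themselves prescribe.

## Known limitations

* Rates carry no covariates (age, diabetes, BMI) and no secular trend.
* The placebo response percentages depend on the progressor-designation
  rule discussed above; the package implements one rule and documents it.
* Point estimates only: the fitting stages provide no confidence intervals
  or profile likelihoods.
* Trial utilities model no within-trial dropout and use the mean score
  difference as the endpoint; ordinal endpoint tests are out of scope.
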