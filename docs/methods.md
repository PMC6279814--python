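# Methods

This note documents the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical and design decisions that were
genuinely open.

## Estimation engine

Every model in the package is a Cox proportional-hazards fit obtained by
Newton–Raphson maximization of the **Breslow-ties partial likelihood**
over risk sets R(t) = {j : entry_j < t ≤ time_j}. Delayed entry (left
truncation) is first-class because the landmark supermodel is fitted on
stacked records that enter at their landmark time; using one engine for
ordinary and stacked fits guarantees identical tie and risk-set
conventions throughout. Breslow ties were chosen over Efron because the
stacked landmark dataset replicates each subject's event time across many
landmarks, making ties ubiquitous; the Breslow form keeps the pooled
likelihood simple and is the convention the baseline-hazard estimator
matches exactly.

Risk-set sums are computed with suffix cumulative sums over the exit- and
entry-sorted records, giving O((n + E)p²) per iteration, so stacks with
tens of thousands of records fit in milliseconds. Convergence is declared
at gradient max-norm < 1e-8; monotone likelihoods (separation) are
detected as |β_j|·sd(x_j) > 36 and reported as an estimation error naming
the covariate. The covariance is the inverse observed information. The
baseline cumulative hazard is the Breslow estimator
H₀(t) = Σ_{t_k ≤ t} d_k / Σ_{R(t_k)} w_j exp(η_j); with all coefficients
zero it reduces exactly to Nelson–Aalen (a tested identity).

## Penalized gene selection

The LASSO-Cox objective is −pl(β)/n + λ‖β‖₁ on internally standardized
covariates, solved by iteratively reweighted least squares with cyclic
coordinate descent, soft thresholding, an active-set strategy with
vectorized KKT screening, and warm starts down a geometric grid from the
data-derived λ_max (smallest penalty that zeroes every coefficient) to
0.05·λ_max (50 points by default). Coefficients are reported on the
original scale. The path is truncated once a model carries more nonzero
coefficients than observed events (configurable via `max_nonzero`):
larger models are not estimable in any meaningful sense and dominate
runtime.

λ is chosen by **repeated stratified K-fold cross-validation** of the
Verweij–van Houwelingen partial-likelihood deviance,
−2·[pl_all(β̂_train) − pl_train(β̂_train)], minimizing the mean curve.
The default of 10 folds × 50 repeats (500 fold-fits) reflects the
intended production setting; tests and the bundled pipeline configs use
fewer repeats to stay fast, which only adds Monte-Carlo noise to the CV
curve. Stratifying folds by event status keeps events in every training
fold; if the event count is below the fold count the call fails loudly.
No one-standard-error rule is applied: the minimizer is used. The
absolute value of λ is parameterization-specific (per-observation scaling,
standardized covariates) and is not comparable across software.

## Cross-validated prognostic indices and stacking

A prognostic index evaluated in-sample is optimistic; feeding it into a
second-stage model would inflate the stacking weights. The package
therefore uses **leave-one-out** indices: subject i's CVPI is the linear
predictor at x_i of the model fitted on everyone else. Within each
leave-one-out fold the *gene set is frozen* at the full-data LASSO
selection and only the unpenalized coefficients are refitted; re-running
the LASSO inside folds is available (pass a custom fitter) but is not the
default, because the selection step is treated as part of model
specification rather than estimation. CVPIs are centered to mean zero — a
pure convention (Cox fits are location-invariant, a tested identity) that
stabilizes baseline-hazard estimation.

Stacking is a two-covariate Cox fit of (CVPI_clin, CVPI_gene); its
coefficients (α₁, α₂) weight the sources and define
CVPI_comb = α₁·CVPI_clin + α₂·CVPI_gene. Indices correlated above 0.999
are rejected as collinear. Up to 10% of leave-one-out fit failures are
tolerated (recorded as missing and dropped downstream); more aborts,
since an unstable model cannot support honest indices.

Four representative risk profiles are built from the upper and lower
quartiles of each index: A (low, low), B (high clinical, low genetic),
C (low, high), D (high, high), each with its combined index
α₁·q_clin + α₂·q_gene. Note that quartile combinations are linear-formula
constructs; their combined values need not coincide with any observed
subject's index.

## Landmark dynamic prediction

For landmark grid s ∈ {0, 0.1, …, 7} years (71 landmarks), window
w = 5 years and scaling horizon τ = 7 years, each subject alive at s
contributes one record (entry = s, exit = min(T, s+w), event iff the
death occurred by s+w). The supermodel is a single delayed-entry Cox fit
on this stack with covariates (s/τ, (s/τ)², x, x·s/τ) and risk sets
pooled across landmarks under one common baseline — the pooled (ipl*)
formulation rather than a per-landmark stratified fit, which matches the
"one smooth supermodel" intent and keeps H₀ estimable for prediction.
The landmark basis is quadratic in s for the baseline terms but only
linear in s for the covariate interaction; the quadratic-interaction
variant was deliberately not added, keeping the effect function
β(s) = β₀ + β₁·s/τ interpretable as a drift in prognostic strength.

Model-based standard errors are invalid on stacked data (each subject
appears in up to 71 records), so a cluster-sandwich covariance by subject
is computed from score residuals; point estimates alone drive all
predictions. The fixed-width mortality is
F_w(s|x) = 1 − exp(−[H₀(s+w) − H₀(s)]·exp(γ₁ s/τ + γ₂ (s/τ)² + (β₀+β₁ s/τ)x)).
Beyond the last event time H₀ is extended by constant-hazard
carry-forward at the average fitted hazard, with a warning — predictions
that far out are extrapolations and are labelled as such rather than
silently truncated.

## Evaluation battery

Discrimination is Harrell's concordance of the prognostic index: among
pairs whose shorter observed time is an event, the fraction where the
higher index failed first, index ties counting 1/2. It is computed on the
*cross-validated* indices, so the reported values are honest rather than
apparent.

Prediction error is the **inverse-probability-of-censoring-weighted
Kullback–Leibler (log-loss) score**: at grid time t, subjects observed
beyond t contribute −log Ŝ_i(t) weighted by 1/Ĝ(t), subjects with an
event by t contribute −log(1−Ŝ_i(t)) weighted by 1/Ĝ(T_i⁻), censored-by-t
subjects contribute nothing; Ĝ is the Kaplan–Meier estimator of the
censoring distribution (left limits at event times avoid zero weights at
censoring ties). Predictions are clipped to [1e-6, 1−1e-6] before logs to
keep the score finite; the clip bound is a documented constant, not a
tuning parameter. The covariate-free reference predicts the pooled
Kaplan–Meier curve for everyone, and the reduction curve is
1 − err_model/err_null; a model identical to the pooled KM has reduction
identically zero (a tested identity).

## Synthetic cohorts

The generator draws event times from a Weibull baseline (shape 1.2, scale
8 years) modulated by exp(linear predictor). Defaults emulate a desk-scale
renal-cancer-like cohort: 127 subjects; 1000 candidate genes of which 15
are causal (10 hazard-increasing, 5 hazard-decreasing, |log-HR| = 0.35 per
unit log-expression); clinical covariates consisting of one dominant
continuous composite risk score (log-HR 0.8, standing in for a clinical
staging score), a binary metastasis indicator (0.5), a three-level grade
factor (0.2, 0.5), and null gender/age covariates so screening tests have
true negatives. Censoring is independent exponential with its rate solved
numerically (Brent) on the cohort's own latent event times to hit a target
censoring fraction (default 0.5), plus administrative censoring at 10
years. With `tv_slope = 0` event times come from exact Weibull inversion,
so proportional hazards holds exactly; with `tv_slope ≠ 0` the hazard is
h₀(t)·exp((1 + tv_slope·t)·z_i) and sampling uses a piecewise-constant
hazard on a 0.01-year grid with inversion, since no closed form exists.
Expression marginals are log-normal (standard normal on the log scale)
and causal genes act linearly on the log scale.

What the generator does **not** emulate: raw RNA-seq counts and their
overdispersion, batch effects, library-size normalization, informative
censoring, correlated gene modules, or covariate measurement error.
Passing tests therefore demonstrate correctness of the estimation and
prediction machinery under the model's own assumptions — not robustness
to the ways real cohort data violate them.

## Problem sizes and numerical choices

Simulation-based checks use n = 400 with 100–200 replicates for
coefficient-recovery and null-interaction means, 20 cohorts of n = 200
for the ordering properties, and n = 1000 for closed-form baseline
checks; these sizes put Monte-Carlo error comfortably inside the
tolerances asserted while keeping the full suite around a minute.
Brute-force oracles (1-d likelihood grids at 1e-4 resolution, Nelder–Mead
on an independently coded stacked partial likelihood, explicit
leave-one-out loops) are deliberately written in the tests, independent
of the library code paths they check. Ties in the concordance index count
1/2; grid endpoints of the landmark grid are inclusive (0–7 by 0.1 gives
71 landmarks); all randomness flows from explicit integer seeds through
`numpy.random.default_rng`, and the pipeline expands one master seed into
per-stage seeds recorded in the run manifest.

## Known limitations

- The univariate gene screen is applied to the log-normalized matrix;
  if the upstream differential-expression filter used a different
  normalization the retained gene sets can differ.
- The stepwise clinical search uses AIC with factors as units; a
  per-coefficient p-value mode exists (`criterion="p_value"`) but the two
  can select different models on small cohorts.
- The landmark supermodel freezes the combined index at baseline;
  biomarker updating over follow-up is out of scope.
- The penalty parameter of the LASSO is not comparable across software
  parameterizations; only the selected gene sets and their refitted
  coefficients are transportable.
- The cluster-sandwich variance for the supermodel assumes independent
  subjects; it corrects for record reuse across landmarks, not for the
  estimation of the combined index in earlier stages.
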