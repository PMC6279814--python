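# dynapred

Dynamic prognostic modelling for right-censored survival data that
combines two information sources — a clinical Cox model and a
gene-expression Cox model — and turns the combined risk score into
real-time, landmark-based predictions of fixed-width mortality.

The package is aimed at biostatisticians building prognostic models for
cancer cohorts of the TCGA type: a few hundred subjects with survival
follow-up, a handful of clinical indicators (stage, grade, composite
scores such as SSIGN or UISS), and a pre-filtered expression matrix with
many more genes than subjects.

## The method

1. **Clinical model.** Candidate clinical variables are screened
   marginally with Kaplan–Meier curves and log-rank tests, then reduced by
   backward stepwise Cox regression (whole factors enter and leave as
   units). The selected model's linear predictor is the clinical
   prognostic index *PI*<sub>clin</sub>.
2. **Genetic model.** Genes are pre-filtered by univariate Cox
   significance on the log2(x+1) scale, then selected jointly by
   LASSO-penalized Cox regression, min<sub>β</sub> −pl(β)/n + λ‖β‖₁, with
   λ chosen by repeated stratified K-fold cross-validation of the
   partial-likelihood deviance. The selected genes are refitted
   unpenalized, giving *PI*<sub>gene</sub>.
3. **Cross-validated prognostic indices.** Each index is recomputed
   honestly by leave-one-out cross-validation: subject *i*'s CVPI is the
   linear predictor of the model fitted without subject *i*. This removes
   the optimism that in-sample indices carry into the next stage.
4. **Stacking ("super learner").** A two-covariate Cox fit
   h(t | CVPI) = h₀(t) exp(α₁ CVPI<sub>clin</sub> + α₂ CVPI<sub>gene</sub>)
   weights the two sources; its linear predictor is the combined index
   CVPI<sub>comb</sub>.
5. **Landmark dynamic prediction.** For each landmark time *s* on a grid
   (default 0–7 years by 0.1), the subjects still alive at *s* form a
   landmark dataset administratively censored at *s + w* (window *w* = 5
   years). Stacking these datasets and fitting one delayed-entry Cox model
   with a common baseline (the pooled, "ipl*" formulation) gives the
   supermodel

   h(t | x, s) = h₀(t) exp(γ₁ s/τ + γ₂ (s/τ)² + (β₀ + β₁ s/τ) x),

   with x = CVPI<sub>comb</sub>, from which the fixed-width conditional
   mortality F<sub>w</sub>(s | x) = 1 − exp(−[H₀(s+w) − H₀(s)] e^{lp})
   is read off for any patient profile at any landmark.
6. **Evaluation.** Likelihood-ratio model χ², Harrell's concordance of the
   cross-validated indices, and Kullback–Leibler (IPCW log-loss)
   prediction-error and error-reduction curves against the covariate-free
   Kaplan–Meier reference.

All Cox fitting runs through one engine (`dynapred.coxph`) that maximizes
the Breslow-ties partial likelihood with delayed entry, so the landmark
supermodel and ordinary fits share identical conventions. A synthetic
cohort generator (`dynapred.simulate`) produces cohorts with known
proportional-hazards truth — sparse causal genes, a dominant clinical risk
score, calibrated independent censoring, optional time-varying effects —
so every stage is testable without external data.

## Worked example

```python
from dynapred import SimConfig, simulate_cohort, write_fixture, \
    PipelineConfig, run_full_pipeline, dynamic_window_mortality

ds = simulate_cohort(SimConfig(seed=42))       # 127 subjects, 1000 genes
write_fixture(ds, "cohort")
cfg = PipelineConfig(
    clinical_path="cohort/clinical.tsv",
    expression_path="cohort/expression.tsv",
    out_dir="run",
    lasso_k_folds=5, lasso_repeats=2, lasso_n_lambdas=20, lasso_max_nonzero=40,
    split_variable="metastasis", seed=1,
)
state = run_full_pipeline(cfg)
sl = state["super_learner"]
print(sl.alpha_clin, sl.alpha_gene)
```

On this cohort the run prints stacking weights `alpha_clin = 0.823`,
`alpha_gene = 0.347` — the genetic index carries most of the signal here
because the 15 causal genes jointly contribute more log-hazard variance
than the single clinical score — and the full-cohort comparison table

```
        model  chi_square  concordance
     clinical       5.800        0.594
      genetic      85.418        0.828
super_learner      90.090        0.835
```

shows the stacked model dominating both single sources in model χ² and
concordance. The fitted landmark supermodel is

```
gamma1=-0.461  gamma2=0.696  beta0=0.910  beta1=0.554
```

so the combined-index effect at landmark *s* is 0.910 + 0.554·s/7: the
index coefficient at s = 5 years is 1.305. Evaluating the fixed-width
mortality for the quartile profiles (A = low clinical/low genetic risk,
D = high/high):

```
profile A: 5-year mortality at s=0: 0.278, at s=2: 0.265
profile D: 5-year mortality at s=0: 0.928, at s=2: 0.972
```

i.e. a patient at both upper risk quartiles who is alive at 2 years still
faces a 97% five-year conditional mortality in this (deliberately
high-signal) synthetic cohort, against 27% for the low-low profile.

The same workflow is available from the shell:

```bash
dynapred simulate --out cohort --seed 42
dynapred run-all --config pipeline.yaml --seed 1
dynapred predict --model run/supermodel.json --cvpi 0.8 -s 2.0
```

All artifacts (screen reports, selected genes, CVPI vectors, comparison
tables, error curves, the landmark stack, the serialized supermodel and a
manifest with SHA-256 hashes of everything) are tab-separated or JSON
text under the output directory; identical config and seed reproduce
identical hashes.

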