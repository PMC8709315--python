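# misurv

Multiple-imputation benchmarking for survival analysis with incomplete
covariates.

## The problem

Real-world clinical datasets — for example oncology cohorts with genomic
biomarker panels (ALK, BRAF, EGFR, KRAS, PDL1) — are riddled with missing
covariate values, and the missingness is rarely completely at random: whether
a biomarker was tested depends on other observed characteristics and on the
patient's course. Analysing only complete cases wastes most of the cohort and
can bias the hazard-ratio estimates clinicians care about. Multiple
imputation (MI) replaces each missing cell with M stochastic draws, analyses
each completed dataset, and pools the results — but *which* imputation engine
to trust, and how an engine distorts downstream survival inference, is an
empirical question. `misurv` is a toolkit for answering it.

It provides, behind one protocol:

* **Six MI engines** — predictive mean matching within chained equations
  (PMM/MICE), bootstrap expectation–maximisation under a joint multivariate
  normal, iterative random forests (missForest-style), regularised iterative
  PCA with bootstrap multiple imputations, a generative adversarial imputer
  (generator vs. mask-predicting discriminator), and a chained-equations
  imputer built on an attentive tabular network (sequential decision steps
  with soft feature masks). The two neural engines are compact NumPy
  implementations with hand-rolled backpropagation, sized for CPU-scale
  tabular data.
* **Amputation simulators** — Bernoulli mask bootstrap of an observed
  missingness pattern (`p_flip = 0.25` keeps the new mask correlated with the
  original; 0.5 degenerates to MCAR), weighted multivariate MAR amputation
  via a scaled softmax of observed-predictor scores, and Little's chi-square
  test of the MCAR hypothesis.
* **A synthetic survival generator** — a two-latent structural causal model
  (A → B, manifests A1–A3, B1–B3) whose single loading parameter is
  calibrated by bisection to a target mean pairwise correlation (ρ ≈ 0.8
  "type I" vs. ρ ≈ 0.2 "type II"), plus proportional-hazards event times by
  inverse-transform sampling and a binary-biomarker cohort fixture with a
  realistic MAR pattern.
* **Survival pooling** — Cox proportional-hazards fits (Efron ties),
  Nelson–Aalen cumulative-hazard augmentation of the imputation predictors,
  and Rubin's rules.
* **Benchmark harnesses** — metrics (masked RMSE, percentage bias, CI
  coverage and width, Gelman–Rubin R-hat on chain traces) and the
  home/visiting concept-drift design: each "home" engine completes the
  original data once; every "visiting" engine re-imputes S bootstrap-amputated
  copies of that completed reference.

## The model

The analysis model is the multivariate Cox proportional-hazards model

    h_i(t) = h0(t) · exp(μ_i),      μ_i = Σ_p β_p x_ip ,

fitted to each of the M completed datasets by Efron partial likelihood.
Estimates are pooled with Rubin's rules

    β̄  = (1/M) Σ_m β_m
    σ_w = (1/M) Σ_m Var(β_m)                     (within-imputation)
    σ_b = Σ_m (β_m − β̄)² / (M − 1)               (between-imputation)
    σ   = σ_w + (1 + 1/M) σ_b                    (total variance)

with t-based confidence intervals β̄ ± t_{df,1−α/2} √σ, where
df = (M−1)(1 + σ_w/((1+1/M)σ_b))² (infinite when σ_b = 0). Imputation models
additionally see the Nelson–Aalen cumulative hazard H(t) and the event
indicator as fully observed predictors; these never enter the Cox model.

## Worked example

```python
import misurv as ms
from misurv.scm import MANIFESTS
from misurv.survival import AUGMENT_COLUMNS

# 1. calibrate the SCM to high correlation and simulate a survival cohort
spec = ms.calibrate_scm(0.8, n_probe=6000, seed=1)
ds = ms.make_scm_survival_dataset(spec, 2500, seed=2)

# 2. hide 30% of every manifest under weighted MAR (hazard-dependent)
aug = ms.augment_imputation_predictors(ds)
w = {c: 1.0 for c in MANIFESTS}; w[AUGMENT_COLUMNS[0]] = 1.0
amputed, mask = ms.ampute_mar_weighted(
    aug, ms.AmputationSpec(p_m=0.3, weights=w, targets=list(MANIFESTS), seed=3))

# 3. multiply-impute with PMM, Cox-fit each copy, pool with Rubin's rules
model = ms.MICoxPH(amputed, features=list(MANIFESTS), imputer="pmm",
                   augment=False)   # predictors already augmented above
res = model.fit(M=5, seed=4)
print(res.summary())
```

prints

```
Cox PH via multiple imputation (Rubin's rules)
==============================================================
imputer: pmm   M: 5   n: 2500   events: 1748
--------------------------------------------------------------
      coef      beta       se       df           [95% CI]
        A1    0.5565   0.0616     29.7 [ 0.4306,  0.6824]
        A2   -0.5370   0.0619     29.3 [-0.6634, -0.4105]
        A3    0.5374   0.0632     37.4 [ 0.4094,  0.6654]
        B1   -0.5839   0.0798     19.4 [-0.7507, -0.4171]
        B2    0.4709   0.0627     36.8 [ 0.3438,  0.5980]
        B3   -0.3946   0.0588    221.1 [-0.5105, -0.2787]
--------------------------------------------------------------
R-hat: B3=0.909, A2=1.150, A3=1.066, B2=1.204, A1=1.076, B1=1.080
```

The generating log-hazards were ±0.5; despite 30% hazard-dependent
missingness in every covariate the pooled estimates sit close to the
complete-data fit (percentage bias 8.5 on this draw), and the per-coefficient
degrees of freedom show how much information the missing data cost (B3, with
the least damaged donor pool here, approaches the no-missing-information
limit). R-hat values near 1 indicate the chained-equation sampler mixed.

A command-line interface mirrors the library
(`misurv simulate | ampute | impute | pool | mcar-test | bench | report`);
see `misurv --help`.

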