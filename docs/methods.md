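# Methods

This note records the models, algorithms, numerical choices and known
limitations of `misurv`, in the package's own words.

## Data model

A `TabularDataset` couples an n × p float feature matrix (NaN = missing)
with a per-row survival outcome (`time_at_risk` in days, `event` ∈ {0, 1})
that is always fully observed. Binary and categorical columns are stored as
numeric codes with the label lists held in the schema; imputation engines
operate on the numeric grid and project imputations back onto the observed
category set where the column kind requires it. A `MissingnessMask` is the
indicator grid R with R[i,j] = 1 meaning *hidden*; masks are positional
(row order is significant and preserved by every operation) because the
benchmark correlates masks across datasets. On disk, datasets are RFC-4180
CSV with `NA` written at missing cells; `NA`, `n.a.` and the empty string
are accepted on read (case-insensitively), matching common statistical
exports. Schemas travel in a YAML sidecar.

## Synthetic data: structural causal model and survival times

Features come from a two-latent linear-Gaussian SCM: A ~ N(0,1),
B = A + ε_B with ε_B ~ N(0, 0.5²); manifests A_k = c·A + ε and
B_k = c·B + ε with ε ~ N(0,1), plus a direct path 0.3·A into B1. The
latent-B noise keeps B from being collinear with A (with a noiseless B the
attainable mean manifest correlation saturates near 0.82, leaving no
headroom to calibrate a ρ = 0.8 regime). All six manifests share the single
loading c, which `calibrate_scm` finds by bisection against the *sampled*
mean absolute pairwise correlation on a fixed probe draw (default
n = 10,000), making calibration one-dimensional, monotone and reproducible;
the achieved correlation on fresh draws stays within a few hundredths of the
target. Manifests are scaled by their model-implied standard deviation so
that hazard coefficients are comparable across correlation regimes
(correlations are unaffected).

Survival times use a proportional-hazards model on all manifests with
inverse-transform sampling: T = H0⁻¹(−log U / exp(μ)), U ~ Uniform(0,1).
The baseline is exponential by default with rate log 2 / 365 (baseline
median ≈ one year; a Weibull shape parameter is available), chosen for its
closed-form inverse and testability. Censoring is an independent
exponential whose default rate (3/7 of the baseline rate) yields ≈ 30%
censoring when covariate effects vanish — a standard, documented knob.
Default log-hazards for benchmarks alternate ±0.5 across the six manifests
so the truth is nonzero for bias and coverage.

The binary-biomarker fixture (`generate_flatiron_like`) is a synthetic
stand-in for an NSCLC biomarker cohort: five 0/1 columns drawn through an
equicorrelated Gaussian copula (ρ = 0.12) thresholded at realistic positive
rates, proportional-hazards survival, and a missing-at-random pattern in
which each biomarker's missingness probability depends on the other
*observed* biomarkers and on the standardised Nelson–Aalen cumulative
hazard. At the full cohort size the per-column unknown rates land within a
binomial tolerance of their targets and an MCAR test rejects decisively.

## Amputation

* **Mask bootstrap.** Given an existing pattern, each originally-observed
  cell is hidden with probability p_flip and each originally-hidden cell
  with probability 1 − p_flip, via independent Bernoulli draws (maximum
  entropy for binary events; no exact-count sampling). p_flip = 0.25 keeps
  the new mask positively associated with the original; 0.5 is exactly MCAR.
* **Weighted MAR.** For target column i, row n gets score
  s(n) = Σ_{j≠i} w_j·m_j(n)·x_j(n) over currently-observed predictors
  (m_j(n) read as "predictor j observed for row n"; targets are processed
  sequentially so later targets condition on earlier amputation). Hide
  probabilities are the scaled softmax p_m · N · softmax(−s), computed
  max-shifted, clipped at 1 with the clipped mass reported. Raw scores make
  the softmax so heavy-tailed that clipping destroys the target missingness
  proportion, so by default scores are rescaled to standard deviation 0.5
  (`score_sd`; `None` restores raw scores). With the default, realized
  column missingness stays within three binomial standard errors of p_m.
* **Little's MCAR test** computes EM maximum-likelihood moments of the
  incomplete feature matrix and the pattern-wise statistic
  d² = Σ_j n_j (ȳ_j − μ̂_j)' Σ̂_j⁻¹ (ȳ_j − μ̂_j) with df = Σ_j p_j − p,
  referred to a chi-square distribution. No small-sample correction is
  applied; under MCAR the empirical size at α = 0.05 is within ±0.04 of
  nominal in our calibration runs.

## Imputation engines

All engines share the contract: observed cells are restored verbatim in
every completed copy; fixed seed ⇒ identical output (network weight
initialisation and batch order included); a complete input short-circuits to
M identical copies; M defaults to 5. Chained-equation engines visit
incomplete columns in order of increasing missing fraction (conditionals
are trained on the most data first) and record per-sweep means of the
imputed cells for the R-hat diagnostic.

* **PMM (chained equations).** Missing cells start as random draws from the
  column's observed values. Per sweep and column, a linear model is fitted
  on observed rows with a Bayesian-style perturbation (σ² from a scaled
  inverse chi-square draw, coefficients from the normal approximation);
  predicted means use the point estimate for observed rows and the
  perturbed draw for missing rows; each missing cell receives the observed
  value of one of the 5 nearest-predicted-mean donors, chosen uniformly.
  Donor search uses a sorted window rather than the full distance matrix
  (O(n log n) per column). Imputations therefore always lie in the observed
  support — binary columns need no rounding rules.
* **Bootstrap EM.** Each of the M imputations row-bootstraps the data, runs
  EM (pattern-vectorised E-step with conditional covariance accumulation;
  convergence on relative observed-data log-likelihood change < 1e−6,
  ridge-bumped near-singular blocks) and draws the original missing cells
  from the conditional normal under that resample's (μ, Σ). Binaries are
  snapped to the nearest observed category afterwards.
* **Iterative random forest.** missForest scheme (scikit-learn forests,
  50 trees by default): mean/mode start, per-iteration refitting, stop at
  the first increase of the difference statistic (normalised squared change
  for continuous, disagreement rate for categorical), returning the
  imputation from before the increase; M runs with distinct seeds.
* **Iterative PCA.** Columns are centred and scaled by their observed
  standard deviation; the algorithm alternates a truncated SVD with
  shrunken singular values and re-prediction of missing cells. The column
  center is re-estimated from the completed matrix every sweep — a fixed
  observed-cell center leaves a rank-breaking offset that blocks exact
  completion of noise-free low-rank data. The shrinkage noise level is
  estimated from observed-cell residuals of the plain rank-k fit, so it
  vanishes on noise-free data (exact completion to 1e−6 in tests). The
  rank is chosen by cell-wise K-fold cross-validation over a component
  grid; multiple imputations re-estimate the model on nonparametric row
  bootstraps and add Gaussian residual noise to imputed cells.
* **GAIN-style adversarial imputer.** Data are min-max normalised; the
  generator receives the noise-filled matrix plus the observedness matrix,
  the discriminator receives the completed matrix plus a hint matrix
  (hint rate 0.9) and predicts observedness cell-wise. The discriminator
  minimises cross-entropy; the generator minimises the fooling loss plus
  α = 10 times the observed-cell reconstruction loss. Networks are
  two-hidden-layer MLPs of width p trained with Adam (default 5e−3,
  200 epochs — sized so the ~2–4k gradient steps match the reference
  design's training length at desk-scale n). M imputations use M
  independent noise draws. Non-finite losses raise with advice to lower
  the learning rate.
* **Attentive tabular network (chained equations).** Per chain: random
  initial fills from observed values; per sweep and column, rows with the
  target observed are split 80:20 into train/validation and a small
  attentive tabular network is trained to predict the column from all other
  columns. Each of 3 sequential decision steps runs feature-transformer →
  attentive soft feature mask (softmax over inputs, entropy sparsity
  penalty 1e−3) → feature-transformer; step outputs are summed into a
  linear head. Loss is MSE (continuous) or cross-entropy (binary /
  categorical); optimisation is Adam with step-decay learning rate
  (initial 0.02, step 10, γ = 0.9) and early stopping (patience 10, best
  weights restored). Trained predictions overwrite the missing cells —
  *plain* predictions, no residual-noise perturbation; multiplicity comes
  from the M chains' distinct random initial fills. Width 8, ≤ 100 epochs,
  batch 256 by default; all gradients are validated against finite
  differences in the test suite. A constant observed column is imputed
  with that constant (warning, no training); columns with fewer than 25
  observed rows are rejected (the 80:20 split needs data).

### A calibration caveat that matters

Plain-prediction overwrite makes the attentive-network imputer (and, to a
lesser degree, the forest and adversarial engines) *deterministic*
conditional-mean imputers. These achieve the best masked-RMSE in our
experiments, but Var(imputed) < Var(truth), and in the pooled Cox fit this
attenuates coefficients and collapses the between-imputation variance. In
our synthetic benchmarks the proper-imputation engines (PMM, bootstrap EM)
therefore show markedly lower percentage bias and better CI coverage than
the deterministic ones, even where the latter win on RMSE — a concrete
illustration of why accuracy alone is the wrong yardstick for inference
after imputation. An optional residual-noise perturbation for the network
imputer is a natural extension; it is deliberately not the default because
the algorithm specifies plain prediction.

## Pooling and metrics

Cox fits delegate to lifelines (Efron ties); an independent brute-force
partial-likelihood maximiser cross-checks the estimates on untied toy data.
Rubin's rules are applied per coefficient (diagonal treatment). The
confidence interval multiplies the t quantile by √σ — the total variance
enters under a square root so the interval has the units of β. Degrees of
freedom use the classic adjusted formula; σ_b = 0 gives the normal-quantile
limit. Percentage bias is 100·Σ_p |β̄_p − β̂_p| / Σ_p |β̂_p| (absolute-value
convention; the statistic is reported as a positive magnitude). Coverage
averages per-coefficient CI-cover indicators within a replicate, then
across replicates. R-hat is the classic potential scale reduction factor
√(((n−1)/n·W + B/n)/W) on per-sweep means of imputed cells, first half of
each chain discarded; all-constant chains define R-hat = 1 with a warning.

## Benchmark designs and problem sizes

`run_synthetic_experiment` draws a fresh SCM survival dataset per
replicate, Cox-fits the complete data for the reference β̂, amputes 30% of
every manifest under weighted MAR (unit weights on the other manifests and
the cumulative hazard), multiply-imputes, pools, and scores bias, coverage,
width and RMSE. `run_benchmark` implements the home/visiting design: each
home engine completes the original data once (M = 1) and defines the
reference; S Bernoulli mask bootstraps (p_flip = 0.25) of the original
pattern are applied to that reference and every visiting engine re-imputes
them. On-diagonal cells isolate the impact of missingness; off-diagonal
cells add the concept drift of the home imputer. Matrices report
mean ± standard error over S; replicate records carry the seeds to re-run
any single cell; a pseudo-visitor `"oracle"` restores the reference exactly
(plumbing check: zero bias/RMSE, full coverage). Failed cells (e.g. Cox
separation) are dropped with a reported count rather than aborting.

Problem sizes: the acceptance script uses n = 2,500 with 30 replicates per
experiment and the prescribed sampler settings (PMM: 5 donors, 10 sweeps,
M = 5; convergence run: 5 chains × 20 sweeps). The test suite runs the
six-method comparison at n = 1,250 with 4 replicates and reduced network
epochs, the end-to-end CI-calibration check at n = 1,000 with 200
replicates, and the MCAR-test calibration at n = 200 with 200 seeds —
sizes chosen so the full suite completes in minutes on one CPU while
keeping the Monte-Carlo error of each assertion well inside its tolerance.

## What the synthetic generator does and does not emulate

It reproduces: controlled feature correlation, proportional-hazards
outcomes with realistic event/censoring mix, hazard-dependent (hence
testably non-MCAR) missingness, and a binary biomarker panel with realistic
prevalence and unknown rates. It does not emulate: non-linear or
interaction effects in the hazard, time-varying covariates, competing
risks, informative censoring, MNAR mechanisms, longitudinal biomarker
measurement, or the mixed continuous/categorical messiness of real
electronic records. Passing benchmarks here therefore certify correct
mechanics and calibration under linear-Gaussian MAR conditions — not
performance on any particular real cohort.

## Known limitations

* The multivariate-normal EM engine treats binaries as Gaussian and snaps
  afterwards; with very skewed binaries this distorts imputation
  probabilities.
* Rubin pooling is per-coefficient; no joint (matrix) pooling or
  Barnard–Rubin small-sample df refinement (available design hook, off by
  default).
* The MAR amputation softmax clips at 1 for extreme weights; the clipped
  mass is warned about but not redistributed.
* Network engines are CPU-sized; no GPU path, no hyperparameter search
  beyond the PCA rank CV.
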