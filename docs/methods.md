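# Methods

This note records the models, conventions and design choices behind
`bilemark`, in the order the pipeline applies them.

## Scope and data model

The pipeline targets two-group discrimination problems (a benign
reference group vs one malignant group) on sample × feature abundance
tables. The universal currency is `FeatureTable` — a pandas-backed
matrix with NaN as the missing mask and a `kind` flag separating
continuous ("decimal", metabolomics-like) from count ("integer",
proteomics-like) data. Three-group cohorts are handled by the
statistics and DAPC modules (pairwise contrasts against the reference
group); classifier training is strictly binary, as the clinical question
is benign vs one malignancy at a time.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions
every downstream claim is demonstrated under.

* **Marginals.** Feature abundances are log-normal:
  `x = exp(m + s·z)`, `z ~ N(0,1)`, with defaults m = 2.0, s = 0.6 for
  the lipidomics-like fixture and m = 4.0, s = 0.8 (then rounded to
  counts) for the proteomics-like fixture. Log-normal marginals are
  positive and right-skewed, the shape MS abundance data typically has;
  the specific location/scale values are fixture conventions, not claims
  about bile chemistry, since no distributional description of the real
  tables exists to copy.
* **Cohort shapes.** The lipidomics fixture uses 162 features over
  groups of 36 benign / 36 CCA / 57 PDAC; the proteomics fixture uses
  ~2000 integer features over 5 vs 5 samples. These mirror the study
  cohort the package emulates.
* **Planted effects.** An effect of size e shifts the latent mean of the
  planted features by e·s in every non-reference group, so effect sizes
  are expressed in within-group SD units on the log scale and stay
  interpretable after exponentiation (a multiplicative fold-change).
  Recovery demonstrations use e = 1.5 with 10 planted features.
* **Correlation.** Block correlation is imposed on the latent Gaussian
  via a Gaussian copula (Cholesky factor of the block matrix), which is
  exactly the structure the augmentation module estimates; default
  fixture blocks are 10 features at ρ = 0.6 and 10 at ρ = 0.3.
* **Missingness** is MCAR at a configurable rate — nothing is known
  about the real missingness mechanism, so no informative mechanism is
  simulated.
* **Integer mode** rounds half away from zero and clamps at 0. Clamping
  biases moments for low-abundance features, so moment-recovery
  demonstrations in integer mode are restricted to features with
  mean ≥ 5 SD.

What the generator does **not** emulate: batch effects, heteroscedastic
measurement error, informative missingness, non-Gaussian dependence, or
any relation between features and clinical covariates. Passing tests
therefore show that the pipeline recovers structure *of the kind it
assumes*; they are not evidence about real bile data.

The NMR simulator produces sums of Lorentzian peaks on a ppm grid with a
TSP-like reference peak near 0 ppm, per-sample dilution factors
multiplying the signal, optional artifact bumps inside designated
regions (emulating residual water and contrast-reagent signal) that do
not scale with dilution, and additive Gaussian noise.

## Preprocessing

* **Imputation** is k-nearest-neighbour (default k = 5): missing cells
  are the distance-weighted mean of the k nearest samples, with
  distances computed over z-scored co-observed features
  (scikit-learn's `KNNImputer` with NaN-aware Euclidean distances does
  this step). The original analysis imputed with an R package whose
  exact settings are unrecorded; kNN is the fixed, documented stand-in.
  Imputation is idempotent on complete tables and never touches
  observed entries.
* **Referencing** shifts each spectrum so the window maximum
  (default ±0.2 ppm) sits at 0.00 ppm, re-interpolating linearly. The
  peak-picking rule (window maximum) is our convention.
* **Bucketing** uses half-open intervals `[low + i·w, low + (i+1)·w)`
  anchored at the region's low edge (default w = 0.01 ppm over
  δ 0.261–8.757, which yields 850 buckets, the last one truncated at
  the high edge). Bucket values are exact trapezoidal integrals of the
  piecewise-linear spectrum, so kept + dropped integrals reproduce the
  region integral to rounding error. Buckets overlapping an exclusion
  region (water δ 4.59–4.78; contrast-reagent windows δ 1.92–1.98,
  2.39–2.43, 3.39–3.71, 3.76–4.18) are dropped whole rather than
  clipped — clipping would create variable-width buckets.
* **Normalization** applies total-area first, then PQN, following the
  processing order of the emulated workflow. PQN divides each row by
  the median of its bucketwise quotients against the reference row
  (default: the bucketwise median across samples; zero-reference
  buckets excluded) and records that quotient as the sample's dilution
  factor. PQN identifies dilution only up to the reference's own
  scale, so recovery is assessed after rescaling estimated and true
  factors to unit median; on noiseless simulations the match is then
  exact to floating-point, and with noise the median relative error
  stays below 2%.

## Permutation statistics

The two-group statistic is fixed to the absolute difference of group
means (two-sided). All C(n, n₁) distinct splits are enumerated when
their count is within 50,000; otherwise 9,999 Monte-Carlo splits are
drawn and p = (b+1)/(m+1), which cannot be zero. "As extreme" means
statistic ≥ observed. Multi-group summaries report pairwise contrasts
against the reference group rather than an omnibus test, matching how
the clinical tables are presented. Fold-changes use a pseudocount of
half the smallest positive observed value, applied only when a group
mean is zero; q-values are Benjamini–Hochberg (statsmodels), verified
in the tests against an independently written step-up.

## Augmentation

Per-group moments are estimated with the n−1 SD and Pearson
correlation; zero-SD features get a zeroed correlation row/column and a
flag. Moments are per-group, not pooled, because classifier training
needs group-specific synthetic samples. Covariance is assembled as
D·R·D. Indefinite or rank-deficient R (certain when p ≫ n) is repaired
by eigenvalue flooring at 0 plus 1e-10 jitter and diagonal
renormalization; the minimum eigenvalue, clip magnitude and effective
rank are logged in the cohort provenance next to the moments hash, the
group sizes and the seed. No extra noise term is added by default — the
sample covariance already embodies measurement noise — but a
`jitter_sd` flag exists. Negative decimal draws are kept so moments are
preserved exactly (an optional clamp exists); integer mode rounds half
away from zero and clamps at 0. The default synthetic size is 500 per
group; the original analysis never states its synthetic n, and the
demonstrations here are insensitive to it above a few hundred.

## Feature selection

* **DAPC**: z-score each feature, PCA, retain the smallest number of
  components reaching 90% of variance capped at n − groups (the cap
  keeps the within-group scatter invertible), then linear discriminant
  analysis on the retained scores via the generalized eigenproblem
  between/within scatter with a tiny ridge. A feature's contribution is
  Σ over discriminant axes of (eigenvalue share × squared back-projected
  loading), normalized to sum to 1 — the standard DAPC loading-plot
  convention. Contributions are invariant to affine rescaling of any
  feature (the z-scoring absorbs it). The selection rule keeps features
  contributing ≥ 2% and applies to whichever table is passed (real or
  synthetic). The retained-variance threshold and the 2% rule operate on
  the combined (share-weighted) contribution rather than per axis.
* **RF importance** is permutation importance (mean decrease in
  accuracy) of a random-forest classifier, deterministic under a fixed
  seed.
* **AUC ranking** scores each feature by max(AUC, 1−AUC) of the
  normalized Mann–Whitney U with midranks, so direction does not matter.
* **Panels** are nested top-k prefixes for k = 3..10 per ranking — an
  exhaustive subset search over 162–2042 features is combinatorially
  infeasible, and ranked prefixes are what "best three to ten variable
  combinations" can mean at this scale. Ties everywhere break by
  ascending feature id for determinism. Panels built for ranking obey
  the 3–10 range; single-feature panels are permitted only as
  diagnostics for the robustness identities.

## Classifiers, evaluation, selection

Inputs are z-scored by training moments, identically at train and
predict time. Hyperparameters are tuned by stratified k-fold
cross-validation (default 3 folds) on the synthetic training cohort
maximizing AUC; ties keep the earlier grid entry.

* NN: one hidden layer (lbfgs), grid hidden ∈ {1,3,5} ×
  weight decay ∈ {0.001, 0.01, 0.1};
* BGLM: logistic regression with a fixed ridge penalty standing in for
  weakly-informative shrinkage priors (no grid; the penalty keeps
  coefficients finite even on separable data);
* C5TREE: entropy decision tree with a cost-complexity pruning grid —
  the information-gain and pruning elements that define the C5.0
  family, not a line-for-line port of the proprietary code;
* RF: tree-count/feature-subsample grid, admitted only with RF-derived
  panels (it enters as the reference algorithm for its own route).

AUC is the normalized Mann–Whitney U with midranks (identical to the
trapezoidal ROC area and verified against an all-pairs oracle). The
operating threshold maximizes Youden's J; ties prefer higher
specificity, then the higher threshold — the emulated study reports
sensitivity/specificity pairs without stating its threshold rule, so
Youden is the fixed convention here. The best combination is the
highest validation AUC, ties broken by fewer panel features, then
higher sensitivity, then algorithm name.

**Leakage, on purpose.** By default the validation set is the real
table itself, whose samples also produced the augmentation moments.
This reproduces the train-on-synthetic / validate-on-real design being
studied — including its optimism. Under a null cohort this leakage
alone yields winning validation AUCs near 0.9; that number measures the
design, not signal. The pipeline therefore also accepts an independent
held-out cohort (`validation_table`/`validation_labels`), and the null
calibration demonstrations use it: the winner chosen by the standard
pipeline, its AUC then measured on an independently drawn cohort, is
centred on 0.5 under the null. Robustness test 5 is the in-design check
of the same phenomenon.

## Robustness tests

All five tests share the AUC evaluator above and add-one p-values;
defaults are 999 permutations (tests 1–4) and 49 pipeline re-runs
(test 5), each test drawing an independent recorded sub-seed.

1. Label permutation — labels shuffled against *fixed* scores; the
   model is not refit. Refitting under shuffled labels is exactly what
   test 5 does, and keeping test 1 fit-free separates score-level
   significance from pipeline-level overfitting.
2. Single-variable noise — permute one panel column, re-apply the
   model; small p means performance depends on that feature's values.
3. All-variable noise — permute every panel column independently; the
   background prediction level. For a single-feature panel tests 2 and
   3 are the same procedure and give identical p under a shared seed
   (the permutation stream is consumed per feature in panel order).
4. Single-variable signal — keep one feature, permute the rest; small p
   means that feature alone cannot reach the full panel's performance.
   Undefined for single-feature panels.
5. Overfit check — shuffle the real labels, re-estimate moments,
   regenerate synthetic data, redo selection and training with the
   winning route, validate on the shuffled-label table; p compares the
   real pipeline's AUC against this shuffled distribution.

## Numerical conventions and degenerate inputs

Deterministic PCA signs (largest-magnitude loading positive); zero-SD
features scale by 1 instead of dividing by zero; exhaustive permutation
comparisons are exact (no tolerance) and verified against enumeration;
bucket-count arithmetic tolerates 1e-9 of floating error in the
region/width ratio; every stochastic component takes a seed and master
seeds fan out through `numpy.random.SeedSequence`, making whole-pipeline
reruns bitwise reproducible.

## Problem sizes used in the demonstrations

The shipped acceptance checks run the full pipeline twenty times at the
fixture scale (two groups of 36, 162 features, 150 synthetic samples
per group, a 2×2 NN grid at 150 lbfgs iterations, 50-tree forests) —
sizes at which the planted-recovery and null-calibration properties are
already stable; the library defaults are larger (500 per group, the
full NN grid) and are what `PipelineConfig()` uses.

## Known limitations

* The synthetic fixtures cannot validate claims about real bile; they
  validate the machinery.
* PQN dilution factors are identified only up to the reference scale.
* The C5.0 and BGLM families are realized by their defining elements
  (entropy/pruning tree; ridge-regularized logistic regression), not by
  ports of the original implementations, so tuned models will differ in
  detail from caret's.
* Integer-mode augmentation biases moments near zero (rounding and
  clamping); use decimal mode when moment fidelity matters.
* With 5 samples per group the estimated correlation has rank ≤ 4; the
  repaired matrix is the closest unit-diagonal PSD surrogate, not the
  population correlation.
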