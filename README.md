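# bilemark

Biomarker-panel discovery for **benign vs malignant biliary strictures**
from bile omics feature tables.

Distinguishing benign biliary stenoses from cholangiocarcinoma (CCA) or
pancreatic ductal adenocarcinoma (PDAC) at the time of ERCP is a hard
clinical problem: bile lipidomics and proteomics produce feature tables
with far more variables than patients (162 lipid features over ~129
patients; ~2000 proteins over 5 vs 5 samples), the data are non-normal
and unbalanced, and no single analyte separates the groups. `bilemark`
implements, as a tested and reusable library, a machine-learning pipeline
built for exactly this regime:

1. **Permutation statistics** replace parametric tests: for two groups
   the p-value is the fraction of label rearrangements whose
   |mean difference| is at least the observed one — enumerated
   exhaustively when feasible, otherwise Monte Carlo with the add-one
   estimator p = (b+1)/(m+1).
2. **Synthetic-data augmentation**: per-group means μ_g, SDs σ_g and
   Pearson correlations R_g are estimated from the real table and
   synthetic training samples are drawn from N(μ_g, D_g R_g D_g) with
   D_g = diag(σ_g) — decimal draws for metabolomics, rounded non-negative
   integers for proteomics counts.  Rank-deficient correlation matrices
   (unavoidable with 5 samples and 2000 proteins) are repaired by
   eigenvalue flooring with the repair logged.
3. **Three feature-reduction routes** on the synthetic cohort: DAPC
   (PCA + linear discriminant analysis, per-feature contributions to
   between-group separation with a ≥2% rule), random-forest permutation
   importance, and per-feature AUC (normalized Mann–Whitney U); each
   route yields nested candidate panels of 3–10 features.
4. **Train on synthetic, validate on real**: neural networks (one hidden
   layer), ridge-regularized Bayesian-style logistic regression and an
   entropy/pruning decision tree are tuned by cross-validated AUC on the
   synthetic cohort for every panel (random forest runs on its own
   panels only), then validated on the real table; the winning
   panel × algorithm combination is selected by validation AUC with
   sensitivity/specificity read off the Youden-optimal threshold.
5. **Five permutation robustness tests** on the winner: label
   permutation, per-feature noise injection, all-feature noise,
   single-feature signal, and a full pipeline re-run under shuffled
   labels that quantifies the overfitting pressure of moment-based
   augmentation.

Because the original bile tables are not published, the package ships a
first-class synthetic cohort generator (`bilemark.datagen`) with planted
effects, correlated feature blocks and missing values, plus a toy NMR
spectrum simulator feeding the 0.01-ppm bucketing / total-area / PQN
preprocessing chain, so the entire pipeline is testable end to end with
known ground truth.

## Worked example

```python
import bilemark as bm
from bilemark.pipeline import PipelineConfig, StricturePipeline

# a fixture cohort at the study's scale: two groups of 36, 162 features,
# ten features carrying a 1.5 SD effect on the log scale
spec = bm.GroundTruthSpec(
    n_per_group=(36, 36), n_features=162,
    planted_features=tuple(range(10)), effect_size=1.5,
    correlation_blocks=((tuple(range(20, 30)), 0.6),),
    missing_rate=0.02, seed=7, group_names=("benign", "CCA"))
table, labels, truth = bm.generate_cohort(spec)

# test 5 refits the whole pipeline under shuffled labels 49 times;
# switch it off for a quick first run
result = StricturePipeline(table, labels,
                           PipelineConfig(seed=1, run_test5=False)).fit()
print(result.summary())
```

```
StricturePipeline results
============================================================
groups                 benign (ref) vs CCA (positive)
synthetic cohort       500 per group, seed 1
combos evaluated       80
best combination       AUC panel (k=5) x BGLM
validation AUC         1.000
sensitivity            100.0%
specificity            100.0%
test 1 (labels)        p = 0.001
test 2 (per feature)   min p = 0.001, max p = 0.011
test 3 (all noise)     p = 0.001
test 4 (single signal) min p = 0.001, max p = 0.001
============================================================
```

Reading the output: all 80 panel × algorithm combinations were validated
on the real (fixture) table; the winner separates the groups perfectly
at the Youden threshold.  Test 1's p = 0.001 says random relabelling
never matched the observed AUC in 999 permutations; small test 2 p-values
flag the panel features the model actually leans on; test 3 confirms the
prediction collapses on structure-destroyed data; and the small test 4
p-values say no single feature alone reproduces the full panel's
performance.  `bilemark simulate` and `bilemark run` expose the same
flow on the command line, writing a run directory with the leaderboard,
the best combination, ROC table and robustness report.

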