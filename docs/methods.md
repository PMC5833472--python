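# Methods

This note documents the statistical model behind each stage, the defaults
and why they hold, what the synthetic generator does and does not emulate,
and the numerical choices made where the underlying protocol leaves room.

## Data model

A `FeatureTable` is a samples × features intensity matrix with explicit
missingness (an internal NaN mask; the on-disk token is `NA`). Missing is
never encoded as zero — zeros would corrupt both the QC coefficient of
variation and the log transform. Zeros found in raw input are interpreted
as below-detection and converted to missing, with a log message, because
aligned vendor exports encode absence either way. Tables are
single-polarity; positive- and negative-mode data are independent analyses.
"Present" means a non-missing intensity > 0 — the only observable
criterion after alignment. Injection order is batch-local; cross-batch
order is `(batch, injection_index)` lexicographic.

## Filter cascade

Three feature filters run in protocol order, before drift correction, so
the CVs recorded in the `FilterReport` are pre-correction values on the raw
scale:

1. **QC presence** — keep features present in ≥ 50% of QC injections
   (removal rule is "fewer than 50%", so exactly half survives).
2. **QC CV** — keep features with sd/mean ≤ 0.30 over present QC
   intensities, using the sample standard deviation (ddof = 1). The scale
   and denominator are a choice; raw scale with ddof 1 is the common QA
   convention. Features with < 2 present QC values cannot be assessed and
   are removed with reason `insufficient QC values`.
3. **Group presence** — keep features present in ≥ 90% of *some* study
   group ("any" semantics); QC samples never count.

Filters remove features only — never samples, never individual values —
and each removed feature is attributed to exactly one stage.

## Bracketing-QC drift correction

Within each batch, the expected QC level of feature *f* at injection index
*i* is the linear interpolation between the nearest preceding and following
QC injections with a present value of *f*; before the first (after the
last) such QC the value is held constant. Linear interpolation is the
minimal model that honors both bracketing anchors. The corrected value is

    x'(s, f) = x(s, f) · ref_f / expected_f(i(s))

with `ref_f` the **study-wide** median of *f*'s present QC intensities.
The global (not per-batch) reference makes corrected values comparable
across batches, which is the point of the correction; by construction a
QC's own corrected value equals `ref_f` exactly when evaluated at its own
index. Batches holding < 2 present QC values for a feature are left
uncorrected and logged. The log₁₀ transform then maps present values only;
re-transforming an already-log table is an error.

## PLS-DA and OPLS-DA

Both models autoscale X (mean-center, unit variance, sample sd) and center
a one-hot class-indicator matrix Y; autoscaling is the de-facto default of
the chemometric tooling this workflow emulates for this kind of
fingerprint. PLS-DA is NIPALS PLS2; component scores are mutually
orthogonal and the first weight vector is proportional to `Xᵀy_centered`
(both checked in tests, plus a cross-check against scikit-learn's NIPALS
`PLSRegression`). A deterministic sign convention (largest-magnitude weight
positive) removes the NIPALS sign ambiguity. OPLS-DA (two classes only)
removes `n_orthogonal` components of y-orthogonal structured variation
before extracting a single predictive component; with `n_orthogonal = 0` it
degenerates exactly to one-component PLS-DA.

Defaults: 2 predictive components for PLS-DA, 1 predictive + 1 orthogonal
for OPLS-DA — the configurations whose scores such studies display.

**Cross-validation.** Stratified random 7-fold partition (stratification is
a choice; the protocol says only "divided randomly", and stratification
protects the small third group), each sample predicted exactly once.
Q² = 1 − PRESS/TSS on the centered indicator matrix with PRESS pooled over
folds (per-fold pooling conventions differ between tools; pooled PRESS is
used here). Predicted class is the argmax of predicted indicators, ties
toward the smaller class index; the classification table and CC% come from
these held-out predictions. If the smallest class has fewer members than
folds, the fold count is reduced with a warning.

**Permutation test.** Labels are permuted `n` times (default 200; the
count is configurable and smaller values are used in the bundled scripts
purely for compute budget); `p = (1 + #{perm ≥ observed})/(1 + n)` for both
R²Y and Q², so `p ≥ 1/(n+1)` — the observed model counts itself.

## Univariate screen

Per feature and per two-group comparison, on log₁₀ intensities with
listwise exclusion of missing values:

- **Gates**: Shapiro-Wilk per group and Levene across groups. Levene uses
  the classical mean-centered form (the center is unstated in the protocol;
  mean is the original definition). Any gate p < α (= 0.05, the single
  declared level) selects the rank-sum test; groups below the Shapiro
  minimum (n = 3) or with zero within-group range fall back to the
  rank-sum test with gates marked not-evaluable.
- **Tests**: one-way ANOVA for two groups, algebraically the squared
  pooled-variance t; two-sided Wilcoxon rank-sum, exact enumeration for
  n ≤ 25 per group when the pooled sample is tie-free, otherwise the
  continuity-corrected normal approximation.
- **FDR**: Benjamini–Hochberg step-up per comparison and per polarity
  (matching how significant counts are reported per mode); untestable
  features (< 2 present values in a group) are excluded from the family.
- **Descriptives**: means, SEMs and the signed percent change
  `100·(mean_A − mean_B)/mean_B` are computed on the back-transformed
  corrected raw scale — reported fold differences refer to arithmetic mean
  abundances, while inference runs on the log scale.
- Features with identical values in both groups get p = 1 and a
  `zero_variance` flag: no evidence, not an error.

## ROC, DeLong, Youden

AUC is the Mann-Whitney pair-count `P(pos > neg) + ½P(pos = neg)`,
auto-oriented so the reported AUC ≥ 0.5 with the chosen "positive" group
recorded (equivalent to the convention of reporting tables where every AUC
is ≥ 0.5). The Youden threshold maximizes J = sensitivity + specificity − 1
over midpoints of adjacent distinct pooled scores plus ±∞, with ties broken
toward higher sensitivity and then lower threshold — fully deterministic.
DeLong inference uses the structural components V₁₀/V₀₁ with ddof-1
variances, a Wald 95% CI truncated to [0, 1], and a one-sided p for
AUC > 0.5. Perfect separation collapses the variance to zero; the result is
flagged degenerate and p is reported as 10⁻¹⁶ rather than 0.

## Imputation and SVM

Missing values are imputed with the feature's median within the sample's
group (QC samples use the QC median); features with an entirely missing
(group, feature) cell are dropped from the classification matrix and
listed. Imputation happens on the full matrix before leave-one-out
cross-validation, mirroring the protocol's order. **Caveat**: full-matrix
group-median imputation leaks group identity into imputed cells, which can
make null comparisons look separable when missingness is non-trivial (the
effect is visible in multivariate permutation p-values of null pairs). A
strict mode recomputing medians within each training fold is available for
the SVM path and off by default.

The SVM is a soft-margin RBF machine (C = 1, the `1/(p·Var)` kernel-width
default), with features z-scored using training-fold statistics inside
every leave-one-out iteration to avoid that particular leakage. Accuracy is
percent correct over all held-out predictions; order-invariant and
deterministic.

## Synthetic generator

The generator states a world mirroring the study design: groups I/II/III of
57/49/25 samples with a 37-sample subgroup Ia nested in I (labels are
disjoint — `Ia` samples carry the `Ia` label and comparisons against "I"
take the union); 4 batches each holding near-equal random quarters of every
group; per batch, a QC opens the run, another follows every 8 study
samples, and one closes the run (deduplicated on coincidence). Per-sample
raw intensity is

    10^(baseline_f + effect + batch_offset + ε) · drift(i)

with baselines uniform in log₁₀ [4.5, 6.5], effects multiplicative on the
raw scale (additive in log, expressed in log₂ units; default 30 features at
1.5×), Gaussian log₁₀ noise of sd 0.06 (raw QC CV ≈ 14%, the mid-range of
the QC CVs that features surviving a 30% filter display), per-feature batch
offsets of sd 0.02 (log₁₀), and a linear multiplicative drift decaying
0–20% across each batch (curvature configurable). Values below the
detection limit (default 10⁴) become missing — censoring, the stated
purpose of such missingness. QC injections use the pooled mean raw profile
of batch 1's study samples under the same drift/noise, which is why
projected QCs sit near the centroid of the groups dominating that batch
rather than at the global center.

**What it does not emulate**: m/z-level artifacts (adducts, isotopes),
retention-time shift, correlated features, non-Gaussian tails, alignment
dropouts distinct from censoring, or heteroscedastic noise. A green test on
this world therefore establishes correctness of the statistical machinery
and its bookkeeping, not performance on real chromatograms.

## Numerical and degenerate-input choices

- Constant (zero-variance) columns are an error in the projection models,
  named by feature; the workflow drops them before fitting.
- NIPALS stops early (with a warning) when the Y residual is exhausted
  before the requested component count; R²Y is cumulative, non-decreasing
  and bounded by 1.
- Orthogonality tolerances: 1e-8 relative for score vectors.
- Fold assignment, permutations and the SVM are all seeded; end-to-end
  reruns with the same seed are byte-identical, including written files
  (floats printed at `%.17g`).
- The acceptance script runs 49 permutations instead of the 200 default to
  stay inside a desk-scale compute budget; p-value resolution is 0.02.

## Known limitations

- The drift model is piecewise-linear between QC anchors; smooth LOESS-type
  corrections are deliberately out of scope.
- Two-class OPLS-DA only; the three-group model is plain PLS-DA.
- The imputation leakage described above is inherent to the emulated
  protocol ordering and is surfaced, not silently fixed.
- Comparisons whose groups share samples (I vs Ia) run the univariate
  screen only; classifier accuracy is undefined for overlapping classes.
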