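# Methods

`conceptome` analyzes paired embryo / visceral-yolk-sac bulk transcriptomes
from two-condition developmental studies: each conceptus contributes one
embryo and one yolk-sac UMI count profile, together with its somite-pair
count (a fine-grained proxy for developmental age around E8.5), metabolic
condition of the pregnancy (normal vs. diabetic), and, optionally, dam and
sex. This note records the models, the defaults and why they were chosen,
and what the synthetic benchmark does and does not establish.

## Preprocessing

Genes with fewer than `filter_min` (default 3) counts per sample are removed
before any testing. "Per sample" is interpreted as the **mean** count across
samples by default; `all` (every sample) and `any` (at least one sample) are
selectable and nested (`all` ⊆ `mean` ⊆ `any`). The mean interpretation is
the one consistent with retaining on the order of 13k genes from 3'-tag
libraries of this depth. Filtering is per tissue over the pooled conditions.

Normalization is log1p counts-per-10k with the natural logarithm
(`log(1 + c/total × 1e4)`), the common default for UMI data; per-gene
scaling standardizes each gene across samples (sample sd, `ddof=1`), with
constant genes zeroed and flagged. Correlations are computed on normalized
(not scaled) values: per-gene scaling is affine and cannot change a Pearson
coefficient, while the normalization choice can, so it is fixed and
documented.

### Sex inference

A conceptus is called female when the X-inactivation marker (Xist by
default) is expressed above `tau_x` while the summed Y markers (Ddx3y, Uty,
Kdm5d) stay at or below `tau_y`, male in the mirrored case, and unknown on
conflict. The rule is presence/absence in nature, so the thresholds default
to 0.5 on the normalized scale — any small positive value implements the
same rule. Embryo and yolk-sac calls of a conceptus must agree; a
disagreement leaves the conceptus unknown and flagged.

## Differential expression

Expression differences between conditions are tested per tissue with a
self-contained negative-binomial workflow:

1. **Size factors** — median-of-ratios over genes expressed in every
   sample, rescaled to geometric mean 1 (library-size ratios as fallback).
2. **Dispersion** — per-gene method of moments on normalized counts within
   each condition (so condition effects do not inflate the estimate),
   pooled by degrees of freedom, floored at 1e-8, then shrunk halfway in
   log space toward a log-log linear mean-dispersion trend. The halfway
   weight is a deliberate simplification of empirical-Bayes shrinkage and
   is configurable.
3. **Model and test** — `log mu = b0 + b1·I[diabetic]` (optional centered
   somite-stage covariate) with log size-factor offsets, fit by IRLS
   vectorized across genes; Wald test of `b1`.
4. **Quasi-likelihood moderation** — the Wald standard error is multiplied
   by `sqrt(max(X²/(n−p), 1))`, where X² is the gene's Pearson goodness-of-
   fit statistic. A plug-in Wald test treats the estimated dispersion as
   known; its sampling noise inflates the extreme p-value tail, which is
   exactly the region that drives false BH discoveries. The moderation
   factor (in the spirit of quasi-likelihood F-tests) widens the standard
   error where residual variation exceeds the fitted NB variance, and the
   floor at 1 makes it strictly one-sided: it can only make the test more
   conservative. p-values use a t reference with `n − p` degrees of
   freedom.
5. **Multiple testing** — Benjamini-Hochberg step-up across all tested
   genes; significance at adjusted p < 0.1 (the study-design default).
   Significant genes are categorized by direction and by whether the fold
   change exceeds 1.5×.

This reproduces the *operating characteristics* of the standard NB DE
workflow — error control and effect recovery — without depending on any
particular implementation of it; agreement with such tools is functional,
never bitwise.

## Stage correlation

For every gene, the Pearson correlation between log-normalized expression
and the somite-pair count is computed over all samples of a tissue
(`r_all`) and within each condition (`r_normal`, `r_diabetic`). Somite
stage is treated as a numeric covariate (5–9), not ordinal ranks.
Coefficients are NA for constant genes or strata with fewer than 3 samples
or fewer than 3 distinct stage values.

* **Strong sets** — |r| strictly greater than the cutoff (default 0.5);
  genes above are "correlated", below −cutoff "anti-correlated". On
  continuous data the strict/inclusive distinction at the boundary is
  immaterial, but strictness is fixed for reproducibility.
* **Set algebra** — the normal and diabetic strong sets are intersected
  sign-aware: a gene correlated under one condition and anti-correlated
  under the other is unique to both, never shared. The tail mass (fraction
  of genes with |r| > cutoff) quantifies how much more of the transcriptome
  is stage-coupled under each condition.
* **Shift classes** — per gene, `reversed` when the sign flips and at least
  one coefficient is strong; otherwise `weakened` / `strengthened` when |r|
  moves by at least `delta` (default 0.2); otherwise `stable`. The delta is
  this package's operationalization of the qualitative weakening /
  strengthening distinction and is reported with every output.

## Multivariate structure

PCA treats samples as observations over a chosen gene subset of the scaled
matrix (typically the significant DE genes, or the strong stage-correlated
genes). Variance fractions are squared singular values over their total.
Sign indeterminacy is resolved by orienting each dimension so its
largest-magnitude gene loading is positive; a helper re-orients a dimension
so the normal condition's mean coordinate is positive, which makes quadrant
language well defined in condition overlays.

Factor overlays are quantified per dimension: point-biserial correlation
for binary factors (condition, sex), Spearman for somite stage, with seeded
permutation p-values. The quadrant test cross-classifies samples by
condition and by coordinate sign on a chosen dimension (zero counts as
positive) and attaches a two-sided Fisher exact p, using the
summed-probabilities convention (all tables with the observed margins whose
hypergeometric probability does not exceed the observed one). Hierarchical
clustering is agglomerative with average linkage on 1 − Pearson distance
(uncentered-correlation distance selectable).

## Cross-tissue congruence

Within a conceptus, the embryo and yolk sac can be compared on three
levels: (1) sign agreement of stage correlations for genes strong in both
tissues (by `r_all`, or the diabetic-unique construction: strong under
diabetic minus strong under normal, per tissue, then intersected);
(2) direction agreement of fold changes for genes significantly
differentially expressed in both tissues; (3) composite coordination — each
conceptus's coordinates along the re-oriented Dimension 1 of the per-tissue
DE-gene PCAs, related by ordinary least squares, with per-condition
coordinate ranges quantifying the response spread.

## Synthetic data

The generator emulates the reference study design: 33 conceptuses per
condition, somite stages 5–9 with frequency profile 24:10:11:13:8 over 66,
29 female / 37 male, and paired tissues agreeing on all conceptus-level
covariates. Counts are negative binomial (variance = mean + α·mean²) with
per-gene dispersions drawn log-normal (median 0.05, the typical bulk-UMI
range), per-sample library sizes log-normal around 2×10⁵ total counts, and

    log mu = log(w_g · L_j) + ln2·lfc_g·e_c·I[diabetic]
           + beta_g(cond)·(s_j − s̄) + marker gating,

with the somite stage centered so the baseline is stage-independent
(decoupling DE from stage effects). Planted, disjoint gene classes carry the
signals the analysis is meant to detect: DE per tissue and shared across
tissues (log2 fold changes drawn from ±[0.3, 1.5] — a modeling choice, as
the reference design reports only fold-change category counts),
stage-coupled genes shared between conditions, diabetic-only, and
sign-reversed (slope default 0.25 natural-log units per somite), and one
Xist-like X marker plus three Y markers with female-only / male-only
expression.

Two choices deserve explanation:

* **Exposure severity** `e_c` — a per-conceptus gamma factor (mean 1, sd
  0.35 by default) scaling the diabetic condition effect, shared by both
  tissues of a conceptus. Bulk exposures are heterogeneous across
  individuals; this term produces both the larger coordinate spread of the
  diabetic group and the conceptus-level embryo–yolk-sac coordination that
  the composite analysis measures. Normal conceptuses have no condition
  effect.
* **Planted-gene placement** — planted classes are assigned to genes whose
  baseline expected count is at least 20 at the mean library size. The
  population correlation of a stage-coupled gene is
  `beta·sd(s) / sqrt(beta²·var(s) + 1/mu + alpha)`; with the default stage
  distribution (sd ≈ 1.45) and slope 0.25, well-expressed genes sit near
  |r| ≈ 0.7, the regime the strong-set machinery is designed for. Without
  the floor, shot noise at low counts would dilute the planted classes into
  an unintended mixture of strong and undetectable signals.

The generator does **not** model batch or lane effects, dam-level
correlation beyond the design labels, compositional renormalization after
planting effects, or sequence-level artifacts. Passing the synthetic
benchmark therefore demonstrates correct statistical behavior under the
assumed NB model and study design — not robustness to real-data artifacts
such as batch confounding or outlier samples.

### Problem sizes

Simulated runs default to 4,000 genes (a config flag scales to the full
~13k); operating-characteristic checks use 2,000-gene null datasets and
10–20 replicate seeds, sizes at which every reported statistic is stable to
well within its acceptance band.

## Design-table statistics

For per-dam pregnancy tables, litter sizes are compared between conditions
with Welch's two-sided t-test (the robust default when no test is
prescribed; identical zero-variance groups report p = 1 by convention), and
the relationship of litter size to maternal glucose at dissection within
the diabetic group is reported as the squared Pearson correlation. Censored
glucometer readings (">600") are replaced by the saturation value 600 by
default; the rule is configurable and logged.

## External validation (not desk-scale)

The real GSE197396 profiles yield headline counts — 891 embryo and 98
yolk-sac DE genes, strong-set sizes of 529 (normal) and 1,943 (diabetic)
embryo genes, 26.4% / 11.4% variance on the first two DE-gene dimensions,
and per-gene coefficients such as Nr2f1 (0.734 / 0.744) and Hif1a (−0.74 /
−0.712). Reproducing those numbers requires the deposited accession and the
original DE estimator's exact behavior; they are an optional external
validation for users with the data, not targets of the synthetic benchmark,
which checks the same procedures on generated data with known truth.

## Numerical notes

* IRLS runs to a 1e-8 coefficient tolerance (max 50 iterations) with the
  linear predictor clipped to ±30; genes with all-zero counts are excluded
  and reported, never silently dropped.
* BH adjustment passes NA through and enforces monotonicity by a cumulative
  minimum from the largest p.
* PCA uses full SVD; loadings are orthonormal to 1e-8 and variance
  fractions match an independent eigendecomposition at the same tolerance.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical (config, seed) pairs reproduce
  byte-identical outputs, including the pipeline summary JSON.
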