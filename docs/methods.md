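# Methods

## Overview

`exondsi` detects candidate alternative-splicing (AS) events between sample
groups on exon-array probeset data and embeds that detector in a complete
analysis pipeline: normalization → detection filtering → gene-level
differential expression → windowed splicing-index scan → enrichment. A
synthetic data generator with exactly recoverable ground truth makes every
stage testable without external downloads.

## Data model and processing order

A dataset is a probesets × samples matrix of log2 signals with a parallel
matrix of detection-above-background (DABG) p-values, an annotation mapping
each probeset to a transcript cluster with a 0-based ordinal along the
transcription direction (5′→3′; strand resolution happens upstream of this
package), and a sample→group table. Ordinals are re-densified per cluster on
read so windows are defined on contiguity in the retained series.

The fixed stage order is **scale → filter → summarize**:

1. **Percentile scaling** (`scale_percentile`, default q = 75): each sample
   is shifted additively on the log2 scale so its q-th percentile equals a
   common target (default: the median of per-sample percentiles). Additive
   on log2 = multiplicative on the raw scale; rank order within a sample is
   untouched. A constant-signal sample makes the shift meaningless and is
   rejected.
2. **DABG filter** (`dabg_filter`, alpha = 0.05, min_detected = 3): a
   probeset is retained iff at least 3 samples — counted over *all* samples
   jointly, not per group — have detection p ≤ 0.05 (boundary inclusive).
   The filter is a boolean mask, not a deletion, until materialized.
3. **Gene-level summarization** (`summarize_gene_level`): per-sample median
   (default; mean available) over each cluster's retained probesets. The
   median was chosen for robustness to residual outlier probesets; the
   summarization method is a parameter because no single convention is
   canonical for exon arrays.

## The dsi/dsiT splicing scan

For groups A and B, δ_i = mean-log2(A) − mean-log2(B) per retained probeset,
in ordinal order. Three zero-sum linear contrasts are evaluated on every
4-probeset window (coefficients in `DSI_COEFFICIENTS`, configurable):

| contrast | coefficients (n, n+1, n+2, n+3) | pattern matched |
|---|---|---|
| dsi₁ (step) | +½ +½ −½ −½ | alternative first/last exon, extension boundary |
| dsi₂ (bump) | −½ +½ +½ −½ | internal cassette / retained-intron block |
| dsi₃ (spike) | −⅓ +1 −⅓ −⅓ | single deviating probeset |

dsiT(n) = |dsi₁| + |dsi₂| + |dsi₃|, assigned to the window's **anchor**
(first) probeset; the last three probesets of each gene carry no score.
Anchoring was chosen as the simplest deterministic one-score-per-probeset
assignment; an alternative (summing |dsi| over all windows covering a
probeset) would smear event boundaries without improving ranking on the
synthetic benchmarks. Key properties, all property-tested:

* **shift invariance** — adding a constant to one group's signals changes no
  dsi (zero-sum contrasts), making the score robust to whole-gene expression
  differences and to per-gene dynamic-range differences between tissues;
* **antisymmetry** — swapping A and B negates each dsi and preserves dsiT;
* genes with fewer than 4 retained probesets are unscoreable and reported
  separately.

Per comparison, the K = 100 probesets with the highest dsiT are selected
(ties broken by ascending probeset id for determinism; a fewer-than-K or
all-zero comparison is logged). The default plan is the two hematopoietic
groups each vs 10 solid tissues plus blood vs CD34+ — 21 comparisons, hence
2,100 selections with multiplicity — and spleen is excluded because its
mixed hematopoietic/non-hematopoietic content blurs the contrast.
Selections deduplicate to the AS transcript list, each transcript annotated
with its supporting comparisons.

Because selection is quota-based, the list has no significance guarantee:
with nothing planted, 21 × 100 selections still occur and the false-positive
content is bounded only by the quota. This mirrors the source procedure; a
permutation-calibrated variant would be a natural extension.

## SAM differential expression

Two-group SAM with d = (mean_A − mean_B)/(s + s0), s the pooled two-sample
standard error and s0 the fudge constant chosen by the standard rule (the
percentile of s minimizing the coefficient of variation of the MADs of d
across quantile bins of s; a fixed percentile can be forced). The null is
built from label permutations (default 100; exhaustive with a warning when
fewer distinct assignments exist). For each gene, q = median over
permutations of the count of null |d*| ≥ |d|, divided by the observed count
at that threshold, clipped to [0,1] and made monotone non-increasing in the
|d| ranking (no π₀ estimate — conservative). Calls require both q ≤ 0.05
and a 2-fold cut-off on the de-logged ratio of group means. With s0 → 0 and
equal variances, d reduces to the ordinary two-sample t statistic (tested).

Signature decomposition (`venn_signatures`) is exact set algebra on two call
lists: common, A-specific, B-specific; cardinalities always satisfy
|A| = |common| + |A-specific| and |A ∪ B| = sum of the three parts.

## Enrichment

`fisher_enrichment` tests over-representation of a query list (the AS
transcripts) within the expressed background (genes surviving the DABG
filter) per category: two-sided Fisher exact on the 2×2 membership table
(scipy), with Benjamini–Hochberg adjusted p reported alongside raw p
(flagged at raw p ≤ 0.01 by default) because category counts depend on the
annotation supplied. The test suite verifies the p-values against an exact
integer hypergeometric tail enumeration for every table with all margins
≤ 30. No ontology release is bundled; real annotation is user-supplied
(two-column TSV or GMT).

## Synthetic data generator

`simulate_dataset` emulates the 13-group study design: whole blood
(4 samples), CD34+ HSPC (3) and 11 solid tissues (3 each), genes of 4–8
probesets. Per gene: baseline ~ N(8, 1) log2; per-probeset affinity offset
~ N(0, 0.5) (constant across samples, cancels in δ); replicate noise
additive Gaussian N(0, 0.3) on log2 — the standard log-normal microarray
error model. Defaults were fixed once at values typical for exon-array
probeset summaries.

Planted structure, deterministic given the seed (gene ids shuffled, first
k taken):

* **DE genes** (fraction 0.1, effect 2.0 log2 = 4-fold): whole-gene shift in
  blood, CD34, or both, with random sign.
* **AS events** (fraction 0.1, magnitude ±2.0 log2): one event per gene,
  types cycled through cassette, intron retention, alternative first/last
  exon, exon extension; the span moves in exactly one hematopoietic group.
  Spans never overlap within a gene, so truth is exactly recoverable.
* **Background probesets** (fraction 0.1, in structurally unplanted genes
  only, so planted truth survives filtering): signal at the noise floor
  (baseline − 4 log2).

DABG p-values are generated analytically as the upper Gaussian tail of
(signal − floor)/scale with scale = noise sd: background probesets get
exactly Uniform(0,1] p-values, expressed probesets (≥ 2 log2 above floor)
essentially always pass the filter. This supplies a filterable p-value
without modelling probe-level mismatch intensities.

What the generator does **not** emulate — and hence what passing tests do
not show about real arrays: probe-level (25-mer) intensities and
cross-hybridization, GC/affinity biases correlated with sequence, partial
isoform mixtures (events are clean binary shifts), correlated noise between
neighbouring probesets, and batch effects. Recovery rates on synthetic data
are therefore upper bounds on real-data sensitivity.

## Numerical and design choices

* All signal arithmetic is on log2; "fold" values are de-logged ratios.
* dsi contrasts annihilate constants exactly in exact arithmetic; floating
  evaluation leaves O(1e-16) residue, so exact-zero assertions use a 1e-12
  tolerance.
* Zero-variance genes in SAM get a clamped denominator (finite, huge |d|)
  rather than an infinity.
* Top-K ties break by ascending probeset id; permutation index sets are
  deduplicated draws from a seeded generator.
* PCA QC (2 components, full SVD) reports mean within-group pairwise
  distance vs mean between-centroid distance; duplicated samples coincide
  to numerical precision.
* Problem sizes in the test and acceptance runs (150–500 genes, 40 samples)
  were chosen as the smallest sizes at which every comparison of the
  21-comparison plan has a full selection quota and recovery statistics are
  stable across seeds.

## Limitations

* The scan scores probesets, not isoforms: it cannot distinguish one
  aberrant transcript from a mixture (no deconvolution), and events shorter
  than a probeset or at gene ends (last three anchors unscored) lose power.
* Quota-based selection reports a fixed number of candidates per comparison
  regardless of evidence strength.
* The DABG filter pools all samples, so a probeset expressed in only 1–2
  samples of a small group can be discarded.
* The SAM q-value uses no π₀ correction and is conservative.
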