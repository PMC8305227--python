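# Methods

## The ceRNA screen

The package operationalizes the miRNA-sponge hypothesis as a motif search
over pairwise Pearson correlation tables. Given expression matrices for
mRNAs, lncRNAs and miRNAs over a shared sample set (the canonical cohort
shape is 80 tumor samples; miRNA values on a log2(RPM+1) scale, mRNA and
lncRNA on log2(normalized count+1)), a triple (lncRNA y, miRNA x, mRNA z)
is a **triangle motif** at threshold *t* when

- r(x, y) ≤ −t and r(x, z) ≤ −t and r(y, z) ≥ +t (inclusive comparisons),
- optionally every edge's p-value is ≤ p_max, and
- with evidence gating, at least one interaction database supports the
  miRNA–mRNA axis (TarBase or miRTarBase) **and** at least one supports the
  miRNA–lncRNA axis (miRcode, LncBase validated/predicted, or Encori).

Evidence is OR within an axis and AND across the two miRNA axes; the
lncRNA–mRNA edge is never evidence-gated, because under the model that
coupling is an indirect consequence of shared miRNA regulation, not a
physical contact. Thresholds are inclusive because the reference screen at
"0.6" retains an edge printed as −0.60; at two-decimal precision an
exclusive rule would contradict the published count of eleven axes.

**Assumptions.** Pearson correlation (linear coupling on the log scale) is
the association measure; no partial correlation is attempted, so a motif is
correlational evidence only. Correlations are computed over all shared
samples, zeros included — the expression filter (below) has already removed
features whose zeros would dominate. No multiple-testing correction is
applied by default because the reference analysis reports raw p-values; an
optional Benjamini–Hochberg column is available
(`pearson_pairs(..., adjust="bh")`).

## Filtering, correlations, p-values

`filter_expressed` retains features strictly positive in at least
⌈fraction·n⌉ samples. The default fraction 0.75 at n=80 gives exactly the
keep-at-60, drop-at-59 boundary. ceil is deliberate so the printed rule is
reproduced at every n.

`pearson_pairs` computes all |A|·|B| cross-correlations by centered matrix
product; self-pairs (the same id present in both inputs, as happens for
TFs vs mRNAs) are excluded, so the record count is |A|·|B| − |A∩B|.
Zero-variance features yield r = NaN records that count toward the pair
total but never pass a threshold. One printed reference count (mRNA×miRNA,
8,568,000) is inconsistent with its own printed dimensions
(14,500 × 612 = 8,874,000) while the other published counts factor exactly;
the package implements the count identity and documents the discrepancy
rather than reproducing the inconsistent figure.

P-values use the exact null t-transform `t = r·√((n−2)/(1−r²))` with n−2
degrees of freedom, two-sided — standard for Pearson coefficients and
accurate at the n = 80 regime. |r| = 1 maps to the smallest positive
double rather than 0. The test suite cross-checks the transform against a
seeded 100,000-draw permutation oracle at a moderate correlation
(sample r ≈ 0.33, p ≈ 2.6e-3), where the oracle's Monte-Carlo resolution
supports a 10% relative comparison; at strong correlations (r ≈ 0.5,
n = 80, p ≈ 1e-6) any feasible permutation count saturates at its 1/B
floor, so the test instead bounds both routes from above.

## Ranking and sweeps

"Top n" output uses a deterministic rule of the package's own choosing:
motifs sort by descending weakest-edge magnitude
min(|r_xy|, |r_xz|, |r_yz|), ties broken lexicographically by
(lncRNA, miRNA, mRNA) id. The weakest edge is the binding constraint of a
triangle, so it is the natural strength score; any rule would do for
correctness, but this one is stable under input permutation.
`threshold_sweep` re-runs the enumeration per threshold; both the ungated
and gated counts are non-increasing in the threshold and gated ≤ ungated
by the subset relation — both facts are property-tested.

## Sense-antisense analysis

Intervals are 0-based half-open internally; GTF (1-based closed) is
converted on ingest via pyranges, BED is native. A sense-antisense pair is
an opposite-strand lncRNA/mRNA pair on one chromosome with ≥1 overlapping
base between some isoform pair. Classification operates on the union span
of each gene's isoforms so that every gene pair receives exactly one class:

- containment first — one span inside the other gives
  lncRNA_within_mRNA or mRNA_within_lncRNA; identical spans are a
  degenerate double containment, classified lncRNA_within_mRNA with a
  `degenerate` flag (documented tie-break);
- otherwise **convergent** when the shared region contains both 3′ termini,
  **divergent** when it contains both 5′ termini. For a − strand gene the
  5′ terminus is its highest coordinate; half-open ends are decremented
  before the terminus test. For opposite strands these two cases are
  exhaustive — a mixed 5′/3′ partial overlap is geometrically impossible,
  and hitting that branch raises an error as a coordinate-bug canary.

Overlap lengths (mean/min/max) are computed across overlapping isoform
combinations only; non-overlapping isoform pairs contribute no length.
`overlap_length_vs_correlation` then correlates the per-pair expression r
with each length statistic. Same-strand overlaps are never classified;
they can be surfaced separately but are outside the sense-antisense
definition.

## TF target search

TFs are a caller-supplied id list (the standard human TF catalogue has
1,278 entries) extracted from the mRNA matrix. Screening uses asymmetric
per-class cutoffs, defaulting to the most stringent published screen:
mRNA −0.9/+0.9, miRNA −0.6/+0.7, lncRNA −0.7/+0.8. Binding gating is OR
across ENCODE/ChEA/TransmiR flags. Self-loops (a TF passing the screen
against its own transcript) are legitimate autoregulation candidates and
are preserved. `frequent_tfs` keeps TFs with ≥ min_targets (default 3)
distinct targets across all classes combined; the published table this
mirrors contains one two-target row despite stating a three-target rule —
the package implements the stated rule and notes the discrepancy here.

## Expression views

Categorical clinical parameters partition samples (missing values form an
explicit "NA" group); numeric parameters sort samples ascending with ties
broken by sample id. The heatmap scale is piecewise-linear per feature:
min→0, median→0.5, max→1 (median of an even count is the central-pair
mean). Degenerate cases: a constant vector maps to all 0.5; when the
median coincides with an extreme the collapsed half-segment maps that
extreme to 0.5; values scaled against a reference range clip to [0, 1].
Outputs are data tables; plotting is a thin optional convenience with no
result semantics.

## Synthetic data

`make_expression` plants each triangle on a shared latent factor
z ~ N(0,1): lncRNA = a·z + σε, mRNA = b·z + σε′, miRNA = −c·z + σε″ with
independent N(0,1) noise, giving the closed-form expected edge correlation
ab/√((a²+σ²)(b²+σ²)) (and its negative for the miRNA edges). Defaults
a=b=c=1, σ=0.5 put the expected |r| at 0.8 — about 3.5 Fisher-z standard
errors above the 0.6 screen at n=80, so recovery tests can demand ≥95%
recall and ≤1% false positives over 20 seeds without being flaky. The
whole matrix is shifted by a constant (+8) so values are predominantly
positive: a shift preserves Pearson correlations exactly while keeping
planted features on the right side of the expression filter; an
exponential transform would not. Non-planted features are independent
noise. All generators are fully determined by their seed.

What the generator does **not** emulate: count-distribution shape
(negative binomial dispersion, library-size effects), correlated
background structure between non-planted features, batch effects, or
realistic genomic annotation density. Passing recovery tests therefore
demonstrates the screen's correctness under its own model assumptions, not
its behaviour on real cohort data, where background correlation raises the
false-positive rate of any correlation screen.

`make_loci` lays each requested overlap geometry out in its own 20 kb
window with randomized lengths and overlap sizes, plus never-overlapping
decoys; optional second isoforms are trimmed inside the span so the
intended class is preserved while isoform-level overlap lengths spread.
`make_tf_regulons` drives each target as sign·TF + σ·noise
(expected |r| = 1/√(1+σ²) ≈ 0.96 at σ = 0.3) and sets binding flags with a
coverage probability.

## Problem sizes and numerics

Unit and property tests run on matrices up to ~20 features per class and
~25 samples, where brute-force oracles (exhaustive triple scan, O(n²)
interval scan, two-pass covariance) are exact and fast; the engine-level
pair-count checks run once at the published dimensions (up to
14,500 × 733 ≈ 10.6 M records, a few seconds as a matrix product). The
planted-recovery suite uses 20 seeds × 5 planted triangles at n = 80.
Correlation agreement with the naive oracle is asserted at 1e-12 absolute;
correlations are clipped to [−1, 1] after the matrix product to guard
rounding overshoot before the p-value transform.

## Known limitations

- Identifier namespaces are the caller's responsibility: loci, expression
  rows, interaction and binding tables must share one naming scheme; the
  package joins on exact string ids.
- Expression matrices must be dense; missing cells are rejected, not
  imputed.
- No Spearman or partial-correlation options; no stratified statistical
  testing across clinical groups (group views are descriptive).
- Genome-wide result counts from the original cohort analysis require the
  external expression and interaction corpora and are out of scope; the
  packaged reference table covers the stringent-screen worked example
  only.
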