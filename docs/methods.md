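# Methods

`tissuespec` implements a multi-tissue specificity analysis for paired
single-cell RNA and bulk ATAC data from the same tissues, of the kind
used to characterize tissue adaptation of group 2 innate lymphoid cells
(ILC2s) across bone marrow (BM), large intestine (LI), small intestine
(SI), lung and pancreas. This note describes the model behind each
stage, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that make
results reproducible.

## Single-cell quality control

Cells are kept when they have at least 10^2.5 total UMIs and at most 10%
of UMIs from mitochondrial genes; both bounds are inclusive on the keep
side, because the removal conditions are strict inequalities ("fewer
than", "over"). Genes must reach 5 counts in at least 2 cells. That
sentence admits two readings; the default here is the per-cell reading
(count >= 5 in each of >= 2 cells), with the alternative summed-count
reading available as `filter_genes(mode="total")`. Normalization is the
standard LogNormalize: `ln(1 + 1e4 * count / cell_total)`.

Contaminant removal follows the marker-panel strategy: cluster the
cells, score each cluster by the mean normalized expression of a named
marker panel (ILC3, B cell, T cell, ... panels are user input), and drop
clusters whose panel score is extreme. "Extreme" means above both the
0.75 quantile of per-cluster scores and the global mean score plus a
margin of 1.0 log-normalized units; the two-part rule keeps null data
from ever being flagged (a quantile alone always flags something). The
built-in clusterer is deliberately plain plumbing — per-tissue
highly-variable-gene selection (top 300 by variance/mean), per-gene
standardization clipped at |z| = 10, PCA to 20 components, k-means with
k = 8 — chosen because tissue-level variance otherwise swamps small
contaminant populations; any external clustering can be supplied
instead. The removal can be iterated (`rounds`), mirroring protocols
that filter intestinal and pancreatic libraries twice.

After filtering, every tissue is downsampled without replacement to the
smallest tissue's cell count, so pooled analyses are not dominated by
the best-sampled tissue.

## Differential statistics

*Expression* uses the two-sided Wilcoxon rank-sum test on log-normalized
values, the default test of the standard single-cell toolkits. Fold
changes are computed on the expm1 scale with pseudocount 1:
`log2((mean(expm1 a)+1)/(mean(expm1 b)+1))`. Genes expressed in fewer
than 10% of cells in both groups, or with |log2FC| < 0.25, are reported
untested (p = 1 sentinel), mirroring the usual pre-filter. When the two
groups together have at most 30 cells the p-value comes from full
enumeration of the permutation null rather than the normal
approximation, which is visibly inaccurate at that size; above 30 cells
the tie-corrected asymptotic p is used.

*Accessibility* uses a deliberately transparent negative-binomial Wald
test on peak counts. Samples are normalized by median-of-ratios size
factors (geometric-mean centered; library-size ratios as a warned
fallback when no peak is positive everywhere). Per-peak dispersions are
method-of-moments estimates pooled across peaks within ~20 quantile bins
of the overall normalized mean. The bin summary is the plain mean:
per-peak moment estimates at 2 replicates are strongly right-skewed, and
robust summaries (median, trimmed mean) systematically underestimate the
dispersion, which inflates the test — with the plain mean the null
type-I rate at alpha = 0.05 sits near 0.05 on simulated null data. The
Wald z is the log2 ratio of normalized group means over a delta-method
standard error with variance `mu/s_i + alpha*mu^2` per sample; means are
floored at half a normalized count. All-zero peaks return (log2FC 0,
p 1). Numeric parity with full GLM frameworks is not a goal; calibration
and planted-truth recovery are the accuracy surface.

Multiple testing uses Benjamini–Hochberg. TS genes gate on adjusted q
(tool convention); TS OCRs gate on raw p < 0.05 (the stated rule for
peak intersections); both are configurable.

## Interval engine and region classes

Coordinates are 0-based half-open everywhere. Merging peaks follows the
MergePeaks convention (>= 1 bp transitive overlap by default; general
minimum overlaps handled exactly via union-find within overlap
envelopes). A peak's region class is promoter if it overlaps any
promoter window — TSS −1000/+100 bp, strand-aware, the conventional
promoter-TSS window, stated here explicitly because the choice is an
assumption, not a given — else intragenic if it overlaps any gene span
(5'UTR + exons + introns + 3'UTR), else intergenic. Gene assignment
takes the gene whose TSS is nearest the peak midpoint (integer floor),
ties broken by lexicographic gene id so results are exactly
reproducible.

## Specificity calling

"Genuine" peaks are merged replicate peaks supported by every
biological replicate. Per-tissue genuine peaks merge into the
cross-tissue atlas, with per-tissue presence defined by >= 1 bp overlap
and the "shared" subset present in all tissues. Counts are re-quantified
per atlas interval by summing overlapping source peaks.

A feature is tissue-specific (TS) for tissue T when it is significantly
higher in T than in *every* other tissue in one-vs-one comparisons — the
intersection over the (n−1) pairwise tests; "commonly decreased"
features use the same rule downward. Two-tissue shared signatures (the
LI+SI common signature) intersect each in-tissue's one-vs-one results
against every out-tissue (2 × 3 comparisons for five tissues). Up-sets
for different tissues are provably disjoint when the fold gate is
positive.

## ATAC–RNA integration

For one tissue contrast: the mRNA side is the one-vs-all rank-sum fold;
only genes with q < 0.05 and a linear fold above 1.2 enter. The
accessibility side is, per region class, the unweighted mean of the
log2FCs of *all* of the gene's atlas peaks in that class, significant or
not; genes with no peak in a class are absent from that class (the mean
is undefined at zero peaks, and imputing 0 would shrink correlations).
Because the accessibility test is pairwise, the one-vs-all accessibility
fold is taken as the mean of the four one-vs-one folds — a documented
choice where pooled quantification would also have been defensible. For
the two-intestine contrast, folds are averaged by the stated two-step
rule (sum over the three non-intestinal comparisons / 3, per intestine,
then mean of the two), which is algebraically the plain mean of the six
inputs — asserted as an invariant.

Concordance counts genes in the upper-right (both folds positive) and
lower-left quadrants; zeros are non-concordant. Pearson r is computed
per class. The package's summary pools the rows of all five tissue
contrasts before correlating, which keeps the promoter-class null band
tight (per-tissue tables have only ~100 genes).

## Correlation screen and reporting

The single-cell screen drops cells with zero *raw* target count (the
literal reading of "no detected expression"), optionally drops named
clusters (the criteria for suspect clusters are a user decision, never
inferred), then Pearson-correlates the target with every gene on
normalized values, p from the t distribution with n−2 df. Significant
genes (raw p < 0.05, no multiplicity correction by default, as stated)
are partitioned by sign; constant genes are flagged and excluded.

Z-scores use the population standard deviation (the formula names sigma
without a ddof; `ddof` is exposed). Sample Spearman matrices are
computed over promoter / non-promoter / all peak subsets; the
"separation" statistic is mean within-tissue rho minus mean
between-tissue rho. Ordination is plain PCA of samples on normalized
coverage with a deterministic sign convention (largest-magnitude loading
positive). Tissue proximity is average-linkage agglomeration on
Euclidean distances between mean profiles, serialized as Newick with
branch lengths equal to merge-height differences. The proximity tree is
built on plain mean log-normalized profiles, not z-scored ones:
gene-wise z-scoring inflates pure-noise genes to the same scale as
signal genes and erases the planted structure (z-scoring belongs to the
selected-feature heatmap, where features are already chosen).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with every planted effect recorded in a `TruthManifest` so recall and
precision of each caller are computable exactly.

RNA: negative-binomial (Gamma–Poisson) UMI counts, dispersion 0.5, for
five tissues at 500 cells/tissue scaled by fixed multipliers
(1.0, 1.3, 0.85, 0.7, 1.15 — ±30%, so downsampling is non-trivial) over
2000 genes with gamma-distributed baseline means (mean ~1.1, floored at
0.1) and log-normal cell size factors (sigma 0.3). Planted structure:
20 TS genes per tissue at 4-fold; 10 shared intestinal genes up in both
LI and SI; 13 mitochondrial genes (named `mt-*`, mean 5 so healthy cells
sit at ~3% mitochondrial fraction); a correlation block of 12 positive
and 3 negative partners around one target gene (named Ikzf3, with the
block carrying familiar partner names), implemented as a shared
log-normal latent factor (sigma 0.8, mean-one corrected) multiplying or
dividing the block genes' means so counts stay NB-marginal; and 5%
contaminant cells per tissue — one lineage marker panel per tissue
(panels cycle: ILC3, B cell, T cell) at absolute mean 8 on markers that
are otherwise near-silent (baseline 0.05), plus a quarter of
contaminants as "dying" cells with 6× mitochondrial means (>10%
fraction, exercising the mito filter). Lineage markers near-zero outside
their lineage is the realistic regime; it is what makes contaminant
clusters clusters.

ATAC: per gene, 1 promoter peak (inside the promoter window),
2 intragenic and 2 intergenic peaks at fixed offsets chosen so each
peak's class and nearest gene are unambiguous. Counts are NB
(dispersion 0.05, baseline mean ~100, gamma-spread across peaks) with
log-normal per-sample library factors (sigma 0.15), two replicates per
tissue. Non-promoter peaks of planted genes carry the 4-fold coupled
effect in the planted tissue; promoter peaks carry it only with
probability `promoter_coupling` (default 0 — the regime where tissue
character lives at non-promoter elements). Each replicate peak list
drops peaks independently at 5%, creating replicate-irreproducible peaks
for the genuine-peak filter.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, gene–gene correlation beyond the single block, mappability or
GC structure, overlapping genes, fragment-length structure, or peak
boundary jitter between replicates. Passing tests therefore demonstrate
that the pipeline's logic recovers effects of the assumed form at
realistic noise levels, not that it is robust to every artifact of real
libraries.

Determinism: one `SimParams.seed` fixes all outputs bit-for-bit;
annotation, role assignment, RNA draws and ATAC draws use independent
spawned RNG streams, so the gene-role assignment is identical whether or
not the expensive count draws are made.

## Problem sizes and degenerate inputs

The test-suite and acceptance runs use the generator's standard
conditions (5 × 500 cells × 2000 genes for expression; a 5000-peak atlas
at 1000 genes for the accessibility caller; 1000 LI cells for the
screen; 2000 null peaks for calibration), sizes at which every planted
effect is comfortably detectable on a single CPU in seconds to tens of
seconds. Degenerate inputs are handled explicitly: empty QC output warns
rather than raising; all-zero peaks and constant genes return sentinel
results; zero-total cells are a named error before normalization; ties
in merging, gene assignment and linkage have documented deterministic
resolutions.

## Known limitations

- The NB Wald test leans on pooled dispersion; with strong per-peak
  dispersion heterogeneity it will be mis-calibrated in the tails.
- One-vs-all accessibility folds are pairwise means, not a pooled
  re-fit; with very unbalanced replicate counts the two differ.
- Nearest-TSS gene assignment is the classical heuristic; it is wrong
  whenever an element regulates a non-nearest gene.
- The contaminant flagger assumes contaminants form clusters; diffuse
  low-level contamination (ambient RNA) passes through.
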