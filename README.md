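# tissuespec

Multi-tissue specificity analysis for paired single-cell RNA and bulk
ATAC-seq data.

Immune cells of the same lineage acquire distinct identities in
different organs. For group 2 innate lymphoid cells (ILC2s) profiled
across bone marrow (BM), large intestine (LI), small intestine (SI),
lung and pancreas, those identities show up twice: as tissue-specific
genes in single-cell expression, and as tissue-specific open chromatin
regions (TS OCRs) in accessibility — with the chromatin signal
concentrated at non-promoter elements. `tissuespec` packages that whole
analysis as a tested, reusable pipeline for anyone with a cell × gene
count matrix per tissue plus replicated peak × sample ATAC counts:

- **QC**: UMI / mitochondrial-fraction cell filters, gene-detection
  filter, LogNormalize, marker-panel contaminant-cluster removal,
  per-tissue downsampling.
- **Specificity calling**: a feature is tissue-specific for tissue *T*
  when it is significantly higher in *T* than in **every** other tissue
  under one-vs-one ("1 v 1") comparisons — the intersection over all
  n−1 pairwise tests. Genes use the Wilcoxon rank-sum test (BH-adjusted
  q < 0.05, |log2FC| > 0.25); peaks use a negative-binomial Wald test on
  median-of-ratios-normalized counts (raw p < 0.05), on an atlas built
  from replicate-reproducible ("genuine") peaks merged across tissues.
- **Integration**: per gene *g* and region class
  c ∈ {promoter, intragenic, intergenic},

  ⟨log2FC_acc⟩(g, c) = (1/|P_gc|) Σ_{p ∈ P_gc} log2FC_acc(p),

  the mean accessibility fold over all of the gene's peaks in that
  class, paired with the one-vs-all expression log2FC of genes passing
  q < 0.05 and fold > 1.2; summarized by quadrant concordance and
  per-class Pearson r. A two-intestine contrast averages the six 1v1
  folds as (ΣLI/3 + ΣSI/3)/2.
- **Screen**: single-cell Pearson correlation of every gene against a
  target gene (e.g. *Ikzf3*/Aiolos), over cells with detected target
  expression, p < 0.05, sign-partitioned.
- **Reporting**: Z = (x − μ)/σ transforms, sample Spearman matrices by
  peak region, PCA ordination, average-linkage tissue proximity trees
  (Newick).
- **Synthetic data**: a first-class generator producing five-tissue NB
  count matrices, replicate peak sets and a toy genome with planted,
  manifest-recorded effects — tissue-specific genes, shared intestinal
  genes, contaminant clusters, a correlation block, and accessibility
  effects routed through non-promoter peaks — so every caller's recall
  and precision are measurable exactly.

## Worked example

```python
import tissuespec as ts

params = ts.SimParams(seed=7)           # five tissues, 2000 genes, planted truth
ann = ts.generate_annotation(params)
adata, truth0 = ts.generate_scrna(params, ann)
pcm, replicates, truth = ts.generate_atac(params, ann, truth0)

qcd, report = ts.standard_qc(adata, marker_panels=params.contaminant_panels, seed=0)
print(f"cells kept: {qcd.n_obs}/{adata.n_obs}  genes kept: {qcd.n_vars}/{adata.n_vars}")

ts_sets = ts.call_ts_genes(qcd)
for tissue in params.tissues:
    recall, precision = ts.recall_precision(ts_sets[tissue].features,
                                            truth.ts_genes(tissue))
    print(f"{tissue:9s} TS genes called: {len(ts_sets[tissue]):3d}  "
          f"recall {recall:.2f}  precision {precision:.2f}")

atlas, presence, genuine = ts.build_atlas(replicates)
qpcm, mapping = ts.quantify_atlas(pcm, atlas)
print(f"atlas: {len(atlas)} peaks, {int(presence.all(axis=1).sum())} shared in all tissues")

rows, summary = ts.run_integration(qcd, qpcm, ann)
for cls in ("promoter", "intragenic", "intergenic"):
    s = summary[cls]
    print(f"{cls:10s} r={s['pearson_r']:+.3f}  "
          f"concordant={s['concordant_fraction']:.2f}  n={s['n_genes']}")

tree = ts.tissue_tree(ts.tissue_mean_profiles(qcd))
print("tissue tree:", tree.newick)
```

which prints:

```text
cells kept: 1670/2500  genes kept: 1831/2000
BM        TS genes called:  20  recall 1.00  precision 1.00
LI        TS genes called:  20  recall 1.00  precision 1.00
SI        TS genes called:  20  recall 1.00  precision 1.00
Lung      TS genes called:  21  recall 1.00  precision 0.95
Pancreas  TS genes called:  20  recall 1.00  precision 1.00
atlas: 10000 peaks, 5987 shared in all tissues
promoter   r=-0.012  concordant=0.49  n=535
intragenic r=+0.966  concordant=0.98  n=535
intergenic r=+0.971  concordant=0.98  n=535
tissue tree: ((LI:8.73865,SI:8.73865):1.04195,(BM:8.92132,(Lung:8.69638,Pancreas:8.69638):0.224936):0.859279);
```

Reading this: QC removed low-UMI/high-mito cells and planted contaminant
clusters, then downsampled each tissue to the smallest (334 cells × 5).
The pairwise-intersection caller recovered the planted 20 TS genes per
tissue essentially perfectly. On the ATAC side, the 10,000-peak atlas
retained ~6,000 peaks reproducible in all five tissues. The integration
scatter correlates strongly for intragenic and intergenic peaks and not
at all for promoters — exactly the planted design, where accessibility
effects ride on non-promoter elements — and the proximity tree pairs the
two intestinal tissues, pulled together by their shared planted
signature.

The same pipeline is drivable from the shell; `tissuespec simulate
--seed 7 --outdir data` writes a plain-text dataset (MTX/TSV/BED/JSON)
and `tissuespec qc|atlas|ts-genes|ts-ocrs|shared-sig|integrate|screen|
report` consume it. Run `tissuespec --help` for options.

## Layout

```
src/tissuespec/
  intervals.py    genomic interval engine (merge, classify, nearest gene)
  io.py           BED / GTF-lite / MTX / TSV / JSON readers and writers
  containers.py   PeakCountMatrix and normalization helpers
  simulate.py     synthetic five-tissue generator + TruthManifest
  qc.py           cell/gene filters, LogNormalize, contaminant removal
  diffstats.py    rank-sum DE, size factors, NB Wald test, BH
  specificity.py  genuine peaks, atlas, TS sets, shared signatures
  integration.py  ATAC/RNA fold integration and concordance
  screen.py       correlation screen, z-scores, Spearman, PCA, trees
  pipeline.py     end-to-end orchestration and truth scoring
  cli.py          `tissuespec` command-line interface
```
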