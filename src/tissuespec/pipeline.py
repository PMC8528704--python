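"""End-to-end orchestration: pairwise differential maps, TS gene / TS OCR
calling from raw inputs, atlas quantification, and the integration run.
These are thin compositions of the module-level operations; each step is
individually importable and tested.
"""

from __future__ import annotations

import itertools

import anndata as ad
import numpy as np
import pandas as pd

from .containers import PeakCountMatrix, normalized_counts
from .diffstats import median_ratio_size_factors, nb_wald_da, wilcoxon_de
from .integration import (
    accessibility_fold_table,
    build_integration_table,
    concordance_and_correlation,
    one_vs_all_accessibility,
    one_vs_all_log2fc,
)
from .intervals import GeneAnnotation, PeakSet, classify_peakset
from .specificity import TissueSpecificSet, call_tissue_specific, combined_atlas, genuine_peaks


def tissue_list(adata: ad.AnnData) -> list[str]:
    return list(dict.fromkeys(adata.obs["tissue"]))


def pairwise_de(
    adata: ad.AnnData,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    layer: str = "lognorm",
) -> dict[tuple[str, str], pd.DataFrame]:
    """Rank-sum DE for every unordered tissue pair (stored as A over B in
    tissue order of appearance)."""
    tissues = tissue_list(adata)
    tcol = adata.obs["tissue"].to_numpy()
    out = {}
    for a, b in itertools.combinations(tissues, 2):
        out[(a, b)] = wilcoxon_de(
            adata, tcol == a, tcol == b,
            min_pct=min_pct, logfc_min=logfc_min, layer=layer,
        )
    return out


def call_ts_genes(
    adata: ad.AnnData,
    alpha: float = 0.05,
    fc_min: float = 0.25,
    use_q: bool = True,
    de_results: dict | None = None,
) -> dict[str, TissueSpecificSet]:
    """Tissue-specific genes: up in one tissue versus every other tissue
    in one-vs-one rank-sum comparisons (adjusted p by default)."""
    tissues = tissue_list(adata)
    results = de_results if de_results is not None else pairwise_de(adata)
    return {
        t: call_tissue_specific(
            results, t, [o for o in tissues if o != t],
            direction="up", alpha=alpha, fc_min=fc_min, use_q=use_q,
        )
        for t in tissues
    }


def build_atlas(
    replicate_sets: dict[str, list[PeakSet]],
) -> tuple[PeakSet, pd.DataFrame, dict[str, PeakSet]]:
    """Genuine peaks per tissue, then the merged cross-tissue atlas.

    Returns (atlas PeakSet, per-tissue presence table, per-tissue genuine
    PeakSets).
    """
    genuine = {t: genuine_peaks(reps) for t, reps in replicate_sets.items()}
    atlas, presence = combined_atlas(genuine)
    return atlas, presence, genuine


def _overlap_map(atlas: PeakSet, peaks: PeakSet) -> dict[str, list[str]]:
    """atlas peak id -> ids of count-matrix peaks overlapping it."""
    out: dict[str, list[str]] = {pid: [] for pid in atlas.ids}
    pk = peaks.df
    for chrom, agrp in atlas.df.groupby("chrom"):
        sub = pk[pk["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["id"].to_numpy()
        for row in agrp.itertuples(index=False):
            lo = np.searchsorted(starts, row.end, side="left")
            cand = np.flatnonzero(ends[:lo] > row.start)
            out[row.id] = [str(ids[c]) for c in cand]
    return out


def quantify_atlas(
    pcm: PeakCountMatrix, atlas: PeakSet
) -> tuple[PeakCountMatrix, dict[str, list[str]]]:
    """Re-quantify counts over atlas intervals by summing the counts of
    overlapping source peaks. Returns the atlas-level count matrix and
    the atlas->source id map."""
    mapping = _overlap_map(atlas, pcm.peaks)
    rows = []
    keep_ids = []
    for pid in atlas.ids:
        members = mapping[pid]
        if not members:
            continue
        rows.append(pcm.counts.loc[members].sum(axis=0))
        keep_ids.append(pid)
    counts = pd.DataFrame(rows, index=pd.Index(keep_ids, name="peak_id"))
    mask = atlas.df["id"].isin(keep_ids)
    sub = PeakSet(atlas.df.loc[mask, ["chrom", "start", "end", "id"]],
                  provenance="atlas")
    return PeakCountMatrix(counts=counts, samples=pcm.samples, peaks=sub), mapping


def pairwise_da(
    pcm: PeakCountMatrix,
    size_factors: pd.Series | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """NB Wald differential accessibility for every unordered tissue
    pair, with size factors estimated once over all samples."""
    if size_factors is None:
        size_factors = median_ratio_size_factors(pcm.counts)
    tissues = pcm.tissues
    out = {}
    for a, b in itertools.combinations(tissues, 2):
        out[(a, b)] = nb_wald_da(
            pcm, pcm.samples_of(a), pcm.samples_of(b), size_factors=size_factors
        )
    return out


def call_ts_ocrs(
    da_results: dict[tuple[str, str], pd.DataFrame],
    tissues: list[str],
    alpha: float = 0.05,
    fc_min: float = 0.0,
    use_q: bool = False,
    direction: str = "up",
) -> dict[str, TissueSpecificSet]:
    """Tissue-specific OCRs (or commonly decreased peaks with
    direction='down'): raw p < alpha in every one-vs-one comparison."""
    return {
        t: call_tissue_specific(
            da_results, t, [o for o in tissues if o != t],
            direction=direction, alpha=alpha, fc_min=fc_min, use_q=use_q,
        )
        for t in tissues
    }


def integration_rows(
    adata: ad.AnnData,
    da_results: dict[tuple[str, str], pd.DataFrame],
    assignments: pd.DataFrame,
    tissue: str,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """IntegrationRow table for one tissue contrast: one-vs-all mRNA fold
    for qualifying genes joined with per-class mean accessibility folds
    (one-vs-all accessibility = mean of the one-vs-one peak folds)."""
    tissues = tissue_list(adata)
    others = [o for o in tissues if o != tissue]
    expr = one_vs_all_log2fc(adata, tissue)
    acc = one_vs_all_accessibility(da_results, tissue, others)
    acc_folds = accessibility_fold_table(acc, assignments)
    rows = build_integration_table(expr, acc_folds, fc_threshold=fc_threshold, alpha=alpha)
    rows.insert(0, "tissue", tissue)
    return rows


def run_integration(
    adata: ad.AnnData,
    pcm: PeakCountMatrix,
    ann: GeneAnnotation,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    tissues: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Integration over all (or selected) tissue contrasts, pooled.

    Returns the pooled IntegrationRow table and the per-region-class
    concordance / Pearson summary.
    """
    assignments = classify_peakset(pcm.peaks, ann)
    da = pairwise_da(pcm)
    tissues = tissues or tissue_list(adata)
    frames = [
        integration_rows(adata, da, assignments, t,
                         fc_threshold=fc_threshold, alpha=alpha)
        for t in tissues
    ]
    pooled = pd.concat(frames, axis=0)
    summary = concordance_and_correlation(pooled)
    return pooled, summary


# ---------------------------------------------------------------------------
# planted-truth scoring

def recall_precision(called, truth) -> tuple[float, float]:
    """Recall and precision of a called feature set against truth ids."""
    called, truth = set(called), set(truth)
    tp = len(called & truth)
    recall = tp / len(truth) if truth else float("nan")
    precision = tp / len(called) if called else float("nan")
    return recall, precision


def atlas_ids_to_source(called_atlas_ids, mapping: dict[str, list[str]]) -> set[str]:
    """Translate atlas-level peak ids back to source peak ids."""
    out: set[str] = set()
    for pid in called_atlas_ids:
        out.update(mapping.get(pid, []))
    return out


def tissue_mean_profiles(adata: ad.AnnData, layer: str = "lognorm") -> pd.DataFrame:
    """Mean normalized expression per tissue (tissues x genes), the input
    for hierarchical tissue-proximity analysis."""
    V = np.asarray(adata.layers[layer])
    df = pd.DataFrame(V, index=adata.obs_names, columns=adata.var_names)
    return df.groupby(adata.obs["tissue"]).mean()


def normalized_atlas_counts(pcm: PeakCountMatrix) -> pd.DataFrame:
    """Median-of-ratios normalized counts for reporting/ordination."""
    sf = median_ratio_size_factors(pcm.counts)
    return normalized_counts(pcm, sf)
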