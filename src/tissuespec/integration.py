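"""ATAC-RNA integration: one-vs-all expression folds, region-class
averaged accessibility folds, the two-intestine averaging rule, the
>1.2-fold gene gate, and quadrant concordance / per-class correlation.

For each qualifying gene the accessibility side is the plain mean of the
log2 fold changes of all peaks assigned to the gene in a region class
(promoter / intragenic / intergenic), regardless of the peaks' own
significance; genes with no peak in a class are absent from that class's
correlation rather than imputed.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats

from .diffstats import wilcoxon_de

REGION_CLASSES = ("promoter", "intragenic", "intergenic")


def one_vs_all_log2fc(
    adata: ad.AnnData,
    tissue: str,
    min_pct: float = 0.1,
    logfc_min: float = 0.0,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Rank-sum differential expression of one tissue versus the pooled
    rest ("1 versus all"). Returns the full wilcoxon_de table."""
    mask = (adata.obs["tissue"] == tissue).to_numpy()
    if mask.all() or not mask.any():
        raise ValueError("one_vs_all_log2fc needs at least 2 tissues present")
    return wilcoxon_de(
        adata, mask, ~mask, min_pct=min_pct, logfc_min=logfc_min, layer=layer
    )


def one_vs_all_accessibility(
    da_results: dict[tuple[str, str], pd.DataFrame],
    tissue: str,
    others: list[str],
) -> pd.Series:
    """Per-peak accessibility fold for a one-vs-all contrast, formed as
    the unweighted mean of the one-vs-one folds against each other
    tissue (the peak test itself is pairwise)."""
    from .specificity import _oriented_result

    folds = [_oriented_result(da_results, tissue, o)["log2fc"] for o in others]
    return pd.concat(folds, axis=1).mean(axis=1)


def avg_accessibility_log2fc(
    da_log2fc: pd.Series,
    assignments: pd.DataFrame,
    gene: str,
    region_class: str,
) -> float | None:
    """Mean peak log2fc over one gene's peaks of one region class;
    None when the gene has no peak in that class."""
    if region_class not in REGION_CLASSES:
        raise ValueError(f"unknown region class {region_class!r}")
    mask = (assignments["gene_id"] == gene) & (
        assignments["region_class"] == region_class
    )
    peaks = assignments.index[mask]
    peaks = [p for p in peaks if p in da_log2fc.index]
    if not peaks:
        return None
    return float(da_log2fc.loc[peaks].mean())


def accessibility_fold_table(
    da_log2fc: pd.Series, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene, per-class mean accessibility fold and peak counts.

    Returns a DataFrame indexed by gene with columns
    acc_log2fc_<class> (NaN when absent) and n_peaks_<class>.
    """
    df = assignments.copy()
    df = df.loc[df.index.intersection(da_log2fc.index)]
    df["log2fc"] = da_log2fc.loc[df.index]
    grouped = df.groupby(["gene_id", "region_class"])["log2fc"].agg(["mean", "size"])
    genes = sorted(df["gene_id"].unique())
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for cls in REGION_CLASSES:
        try:
            sub = grouped.xs(cls, level="region_class")
        except KeyError:
            sub = pd.DataFrame(columns=["mean", "size"])
        out[f"acc_log2fc_{cls}"] = sub["mean"].reindex(genes)
        out[f"n_peaks_{cls}"] = sub["size"].reindex(genes).fillna(0).astype(int)
    return out


def shared_intestinal_log2fc(
    folds: dict[tuple[str, str], pd.Series],
    intestinal: tuple[str, str] = ("LI", "SI"),
    others: tuple[str, ...] = ("BM", "Lung", "Pancreas"),
) -> pd.Series:
    """The two-intestine averaging rule: per feature, sum the three
    one-vs-one folds of each intestinal tissue over the non-intestinal
    tissues, divide each sum by 3, then average the two results.

    Algebraically this equals the unweighted mean of the six inputs; the
    computation follows the stated two-step form.
    """
    li, si = intestinal
    for t in intestinal:
        for o in others:
            if (t, o) not in folds:
                raise KeyError(f"missing fold series for pair ({t}, {o})")
    li_avg = sum(folds[(li, o)] for o in others) / len(others)
    si_avg = sum(folds[(si, o)] for o in others) / len(others)
    return (li_avg + si_avg) / 2.0


def build_integration_table(
    expr: pd.DataFrame,
    acc_folds: pd.DataFrame,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Join expression and accessibility folds for qualifying genes.

    Keeps genes with q < ``alpha`` and a linear fold beyond
    ``fc_threshold`` in either direction (|log2fc| > log2(threshold))
    in the one-vs-all expression contrast. ``expr`` must carry log2fc
    and q columns indexed by gene.
    """
    gate = (expr["q"] < alpha) & (np.abs(expr["log2fc"]) > np.log2(fc_threshold))
    genes = expr.index[gate]
    rows = acc_folds.reindex(genes)
    rows.insert(0, "mrna_log2fc", expr.loc[genes, "log2fc"])
    rows.insert(1, "mrna_q", expr.loc[genes, "q"])
    return rows


def concordance_and_correlation(rows: pd.DataFrame) -> dict[str, dict]:
    """Quadrant concordance and Pearson correlation per region class.

    For each class, over genes with at least one peak there: counts of
    genes in the upper-right (both folds positive) and lower-left (both
    negative) quadrants, concordant_fraction = (UR + LL) / n (zeros are
    non-concordant), and Pearson r / two-sided p between the mRNA fold
    and the class's accessibility fold. Classes with fewer than 3 genes
    are reported with NaN correlation.
    """
    out: dict[str, dict] = {}
    for cls in REGION_CLASSES:
        col = f"acc_log2fc_{cls}"
        sub = rows[["mrna_log2fc", col]].dropna()
        n = len(sub)
        ur = int(((sub["mrna_log2fc"] > 0) & (sub[col] > 0)).sum())
        ll = int(((sub["mrna_log2fc"] < 0) & (sub[col] < 0)).sum())
        if n >= 3:
            r, p = scipy.stats.pearsonr(sub["mrna_log2fc"], sub[col])
        else:
            r, p = float("nan"), float("nan")
        out[cls] = {
            "n_genes": n,
            "n_upper_right": ur,
            "n_lower_left": ll,
            "concordant_fraction": (ur + ll) / n if n else float("nan"),
            "pearson_r": float(r),
            "pearson_p": float(p),
        }
    return out
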