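"""Single-cell quality control: UMI/mito cell filters, gene-detection
filter, LogNormalize, marker-panel contaminant-cluster removal, and
per-tissue downsampling.

Thresholds follow the source protocol for tissue ILC2s: cells with fewer
than 10^2.5 total UMIs or more than 10% mitochondrial UMIs are removed
(both bounds inclusive on the keep side), genes must reach 5 counts in at
least 2 cells, normalization is ln(1 + 1e4 * count / cell_total), and
tissues are downsampled to the smallest tissue after filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


@dataclass
class QCReport:
    n_input_cells: int = 0
    n_removed_low_umi: int = 0
    n_removed_high_mito: int = 0
    n_removed_contaminant: int = 0
    n_genes_removed: int = 0
    cell_status: pd.DataFrame | None = None
    flagged_clusters: dict[str, list] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_removed_low_umi": self.n_removed_low_umi,
            "n_removed_high_mito": self.n_removed_high_mito,
            "n_removed_contaminant": self.n_removed_contaminant,
            "n_genes_removed": self.n_genes_removed,
            "flagged_clusters": {k: list(v) for k, v in self.flagged_clusters.items()},
        }


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def _mito_mask(adata: ad.AnnData) -> np.ndarray:
    mito = adata.uns.get("mito_genes")
    if mito is None:
        mito = [g for g in adata.var_names if g.lower().startswith("mt-")]
    return adata.var_names.isin(mito)


def filter_cells(
    adata: ad.AnnData,
    umi_min_log10: float = 2.5,
    mito_max_frac: float = 0.10,
) -> tuple[ad.AnnData, QCReport]:
    """Drop cells with < 10**umi_min_log10 total UMIs or a mitochondrial
    UMI fraction above ``mito_max_frac``; equality keeps the cell."""
    X = _dense(adata)
    total = X.sum(axis=1)
    mito = X[:, _mito_mask(adata)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)
    low_umi = total < 10.0**umi_min_log10
    high_mito = frac > mito_max_frac
    keep = ~(low_umi | high_mito)

    status = pd.DataFrame(
        {
            "total_umi": total,
            "mito_frac": frac,
            "pass": keep,
            "reason": np.select(
                [low_umi, high_mito], ["low_umi", "high_mito"], default=""
            ),
        },
        index=adata.obs_names,
    )
    report = QCReport(
        n_input_cells=adata.n_obs,
        n_removed_low_umi=int(low_umi.sum()),
        n_removed_high_mito=int((high_mito & ~low_umi).sum()),
        cell_status=status,
    )
    if not keep.any():
        warnings.warn("all cells removed by QC filters")
    return adata[keep].copy(), report


def filter_genes(
    adata: ad.AnnData,
    min_total: int = 5,
    min_cells: int = 2,
    mode: str = "per_cell",
) -> ad.AnnData:
    """Keep genes detected at ``min_total`` counts in at least
    ``min_cells`` cells.

    ``mode='per_cell'`` (default) requires count >= min_total in each of
    >= min_cells cells; ``mode='total'`` is the alternative reading that
    requires a summed count >= min_total plus detection (>0) in
    >= min_cells cells.
    """
    X = _dense(adata)
    if mode == "per_cell":
        keep = (X >= min_total).sum(axis=0) >= min_cells
    elif mode == "total":
        keep = (X.sum(axis=0) >= min_total) & ((X > 0).sum(axis=0) >= min_cells)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return adata[:, keep].copy()


def log_normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Seurat-style LogNormalize: ln(1 + scale * count / cell_total).

    Stores the result in ``layers['lognorm']`` (raw counts stay in X).
    """
    X = _dense(adata).astype(float)
    total = X.sum(axis=1)
    if (total == 0).any():
        bad = adata.obs_names[np.flatnonzero(total == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts")
    out = adata.copy()
    out.layers["lognorm"] = np.log1p(scale * X / total[:, None])
    return out


def cluster_cells(
    adata: ad.AnnData,
    n_components: int = 20,
    n_clusters: int = 12,
    seed: int = 0,
    layer: str = "lognorm",
    n_hvg: int = 300,
) -> pd.Series:
    """Plumbing clusterer: highly-variable-gene selection, per-gene
    scaling, PCA, then k-means.

    The usual single-cell recipe: restrict to the ``n_hvg`` genes with
    the highest variance-to-mean ratio of normalized values, standardize
    them (|z| clipped at 10), and cluster in PC space, so rare
    populations marked by low-background genes are not drowned by noise
    dimensions. Any clustering can stand in; contaminant flagging only
    needs labels.
    """
    V = np.asarray(adata.layers[layer])
    mean = V.mean(axis=0)
    var = V.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    if n_hvg and n_hvg < V.shape[1]:
        hvg = np.sort(np.argsort(disp)[::-1][:n_hvg])
        V = V[:, hvg]
        mean, var = mean[hvg], var[hvg]
    sd = np.sqrt(var)
    Z = (V - mean) / np.where(sd == 0, 1.0, sd)
    Z = np.clip(Z, -10.0, 10.0)
    n_components = min(n_components, min(Z.shape) - 1)
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(Z)
    n_clusters = min(n_clusters, adata.n_obs)
    labels = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(pcs)
    return pd.Series(labels, index=adata.obs_names, name="cluster")


def panel_scores(
    adata: ad.AnnData, marker_panels: dict[str, list[str]], layer: str = "lognorm"
) -> pd.DataFrame:
    """Per-cell mean normalized expression over each marker panel."""
    V = np.asarray(adata.layers[layer])
    out = {}
    for panel, genes in marker_panels.items():
        idx = adata.var_names.get_indexer(genes)
        missing = [g for g, i in zip(genes, idx) if i < 0]
        if missing:
            warnings.warn(f"panel {panel!r}: unknown marker genes {missing} ignored")
        idx = idx[idx >= 0]
        if len(idx) == 0:
            out[panel] = np.zeros(adata.n_obs)
        else:
            out[panel] = V[:, idx].mean(axis=1)
    return pd.DataFrame(out, index=adata.obs_names)


def flag_contaminants(
    adata: ad.AnnData,
    clusters: pd.Series,
    marker_panels: dict[str, list[str]],
    score_quantile: float = 0.75,
    margin: float = 1.0,
    layer: str = "lognorm",
) -> tuple[dict[str, list], QCReport]:
    """Flag clusters whose mean marker-panel score is extreme.

    A cluster is flagged for panel P when its mean P score exceeds both
    the ``score_quantile`` quantile of per-cluster P scores and the global
    mean P score by ``margin`` (log-normalized units).
    """
    scores = panel_scores(adata, marker_panels, layer=layer)
    cluster_means = scores.groupby(clusters.reindex(adata.obs_names)).mean()
    flagged: dict[str, list] = {}
    for panel in scores.columns:
        col = cluster_means[panel]
        cutoff = col.quantile(score_quantile)
        global_mean = scores[panel].mean()
        hits = col.index[(col > cutoff) & (col > global_mean + margin)]
        if len(hits):
            flagged[panel] = list(hits)
    flagged_all = sorted({c for cl in flagged.values() for c in cl})
    n_cells = int(clusters.reindex(adata.obs_names).isin(flagged_all).sum())
    report = QCReport(
        n_input_cells=adata.n_obs,
        n_removed_contaminant=n_cells,
        flagged_clusters=flagged,
    )
    return flagged, report


def cluster_cells_per_tissue(
    adata: ad.AnnData,
    n_components: int = 20,
    n_clusters: int = 8,
    seed: int = 0,
    layer: str = "lognorm",
) -> pd.Series:
    """Cluster each tissue's cells separately (labels ``tissue:k``).

    Tissue-level variance otherwise dominates the embedding and hides
    small contaminant clusters; libraries are also QC'd per tissue.
    """
    labels = pd.Series("", index=adata.obs_names, dtype=object, name="cluster")
    for t in pd.unique(adata.obs["tissue"]):
        mask = (adata.obs["tissue"] == t).to_numpy()
        sub = adata[mask]
        cl = cluster_cells(
            sub, n_components=n_components, n_clusters=n_clusters,
            seed=seed, layer=layer,
        )
        labels.loc[sub.obs_names] = [f"{t}:{c}" for c in cl]
    return labels


def remove_contaminants(
    adata: ad.AnnData,
    marker_panels: dict[str, list[str]],
    rounds: int = 1,
    seed: int = 0,
    score_quantile: float = 0.75,
    margin: float = 1.0,
    n_clusters: int = 8,
) -> tuple[ad.AnnData, QCReport]:
    """Iterated cluster-and-flag contaminant removal (``rounds`` passes),
    clustering within each tissue."""
    report = QCReport(n_input_cells=adata.n_obs)
    current = adata
    for r in range(rounds):
        if "lognorm" not in current.layers:
            current = log_normalize(current)
        clusters = cluster_cells_per_tissue(
            current, seed=seed + r, n_clusters=n_clusters
        )
        flagged, sub = flag_contaminants(
            current, clusters, marker_panels,
            score_quantile=score_quantile, margin=margin,
        )
        flagged_all = sorted({c for cl in flagged.values() for c in cl})
        if not flagged_all:
            break
        keep = ~clusters.isin(flagged_all).to_numpy()
        report.n_removed_contaminant += int((~keep).sum())
        for panel, cl in flagged.items():
            report.flagged_clusters.setdefault(f"round{r + 1}:{panel}", []).extend(cl)
        current = current[keep].copy()
    return current, report


def downsample_per_tissue(adata: ad.AnnData, seed: int = 0) -> ad.AnnData:
    """Subsample every tissue, without replacement, to the smallest
    tissue's cell count. Rows are carried over unmodified."""
    rng = np.random.default_rng(seed)
    tissues = adata.obs["tissue"]
    n_min = int(tissues.value_counts().min())
    keep_idx: list[int] = []
    for t in pd.unique(tissues):
        pos = np.flatnonzero((tissues == t).to_numpy())
        chosen = rng.choice(pos, size=n_min, replace=False)
        keep_idx.extend(sorted(chosen))
    return adata[sorted(keep_idx)].copy()


def standard_qc(
    adata: ad.AnnData,
    marker_panels: dict[str, list[str]] | None = None,
    umi_min_log10: float = 2.5,
    mito_max_frac: float = 0.10,
    min_total: int = 5,
    min_cells: int = 2,
    rounds: int = 1,
    seed: int = 0,
    downsample: bool = True,
) -> tuple[ad.AnnData, QCReport]:
    """The full QC chain: cell filters, gene filter, LogNormalize,
    contaminant removal, per-tissue downsampling."""
    out, report = filter_cells(adata, umi_min_log10, mito_max_frac)
    n_genes_before = out.n_vars
    out = filter_genes(out, min_total=min_total, min_cells=min_cells)
    report.n_genes_removed = n_genes_before - out.n_vars
    out = log_normalize(out)
    if marker_panels:
        out, crep = remove_contaminants(out, marker_panels, rounds=rounds, seed=seed)
        report.n_removed_contaminant = crep.n_removed_contaminant
        report.flagged_clusters = crep.flagged_clusters
    if downsample:
        out = downsample_per_tissue(out, seed=seed)
    return out, report
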