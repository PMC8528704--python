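"""Single-cell target-gene correlation screen, z-score transform, and the
descriptive reporting computations: sample Spearman correlation by peak
region, principal-component ordination, and hierarchical tissue proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats
from sklearn.decomposition import PCA


@dataclass
class CorrelationScreenResult:
    target: str
    table: pd.DataFrame  # per gene: pearson_r, p, constant flag
    positive: list[str]  # r > 0, p < alpha
    negative: list[str]  # r < 0, p < alpha
    n_cells_used: int
    alpha: float


def target_correlation_screen(
    adata: ad.AnnData,
    target: str,
    alpha: float = 0.05,
    exclude_clusters: list | None = None,
    cluster_key: str = "cluster",
    layer: str = "lognorm",
) -> CorrelationScreenResult:
    """Pearson-correlate every gene with one target gene across cells.

    Cells with zero *raw* target count are dropped (no detected
    expression), as are cells in ``exclude_clusters``. Two-sided p-values
    come from the t distribution with n-2 df; genes constant across the
    used cells are flagged and reported non-significant. The target gene
    itself is excluded from the significant sets.
    """
    if target not in adata.var_names:
        raise ValueError(f"target gene {target!r} not present")
    X = adata.X
    raw = np.asarray(X.toarray() if hasattr(X, "toarray") else X)
    t_idx = adata.var_names.get_loc(target)
    keep = raw[:, t_idx] > 0
    if exclude_clusters:
        cl = adata.obs[cluster_key]
        keep &= ~cl.isin(exclude_clusters).to_numpy()
    n = int(keep.sum())
    if n < 10:
        raise ValueError(f"only {n} usable cells with detected {target!r} expression")

    V = np.asarray(adata.layers[layer])[keep]
    y = V[:, t_idx]
    Vc = V - V.mean(axis=0)
    yc = y - y.mean()
    sd = Vc.std(axis=0)
    y_sd = yc.std()
    constant = (sd == 0) | (y_sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc * yc[:, None]).mean(axis=0) / (sd * y_sd)
    r = np.where(constant, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * scipy.stats.t.sf(np.abs(t_stat), df=n - 2)
    p = np.where(constant, 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))

    table = pd.DataFrame(
        {"pearson_r": r, "p": p, "constant": constant},
        index=pd.Index(adata.var_names, name="gene_id"),
    )
    sig = (table["p"] < alpha) & ~table["constant"] & (table.index != target)
    positive = sorted(table.index[sig & (table["pearson_r"] > 0)])
    negative = sorted(table.index[sig & (table["pearson_r"] < 0)])
    return CorrelationScreenResult(
        target=target, table=table, positive=positive, negative=negative,
        n_cells_used=n, alpha=alpha,
    )


def zscore_rows(
    values: pd.DataFrame, ddof: int = 0
) -> tuple[pd.DataFrame, list]:
    """Standardize each row to Z = (x - mu) / sigma.

    Uses the population standard deviation by default. Constant rows
    (sigma = 0) are excluded and returned as the second element.
    """
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("zscore_rows needs at least 2 columns")
    mu = arr.mean(axis=1, keepdims=True)
    sigma = arr.std(axis=1, ddof=ddof, keepdims=True)
    constant = sigma[:, 0] == 0
    z = (arr - mu) / np.where(sigma == 0, 1.0, sigma)
    out = pd.DataFrame(z, index=values.index, columns=values.columns)
    return out.loc[~constant], list(values.index[constant])


def sample_spearman_by_region(
    peak_norm: pd.DataFrame,
    classes: pd.Series,
    subset: str = "all",
) -> pd.DataFrame:
    """Spearman rho between every sample pair over a peak subset.

    ``subset`` is 'promoter', 'non-promoter' or 'all'; ``classes`` maps
    peak id to region class. The result is symmetric with unit diagonal.
    """
    cls = classes.reindex(peak_norm.index)
    if subset == "all":
        mask = np.ones(len(peak_norm), dtype=bool)
    elif subset == "promoter":
        mask = (cls == "promoter").to_numpy()
    elif subset == "non-promoter":
        mask = (cls != "promoter").to_numpy()
    else:
        raise ValueError(f"unknown subset {subset!r}")
    sub = peak_norm.loc[mask]
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 peaks in subset {subset!r}")
    rho = scipy.stats.spearmanr(sub.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=peak_norm.columns, columns=peak_norm.columns)


def spearman_separation(rho: pd.DataFrame, sample_tissue: pd.Series) -> float:
    """Mean within-tissue rho minus mean between-tissue rho
    (off-diagonal pairs only)."""
    tissues = sample_tissue.reindex(rho.index)
    within, between = [], []
    cols = list(rho.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            (within if tissues[a] == tissues[b] else between).append(rho.loc[a, b])
    return float(np.mean(within) - np.mean(between))


def ordination(peak_norm: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on normalized peak coverage.

    Samples are columns of ``peak_norm``. Components are sign-fixed so
    the largest-magnitude loading is positive. Returns (coordinates
    DataFrame samples x components, explained variance fractions).
    """
    M = peak_norm.to_numpy(dtype=float).T  # samples x peaks
    if M.shape[0] < 3:
        raise ValueError("ordination needs at least 3 samples")
    n_components = min(n_components, M.shape[0] - 1, M.shape[1])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(M - M.mean(axis=0))
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1.0
    df = pd.DataFrame(
        coords,
        index=peak_norm.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return df, pca.explained_variance_ratio_


@dataclass
class TissueTree:
    labels: list[str]
    linkage: np.ndarray
    newick: str

    def sister_leaves(self) -> list[tuple[str, str]]:
        """All pairs of labels joined directly as two leaves."""
        n = len(self.labels)
        pairs = []
        for row in self.linkage:
            a, b = int(row[0]), int(row[1])
            if a < n and b < n:
                pairs.append(tuple(sorted((self.labels[a], self.labels[b]))))
        return pairs


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick with branch lengths = merge-height differences."""
    n = len(labels)

    def build(node: int) -> tuple[str, float]:
        if node < n:
            return labels[node], 0.0
        row = Z[node - n]
        h = row[2]
        ls, lh = build(int(row[0]))
        rs, rh = build(int(row[1]))
        return f"({ls}:{h - lh:.6g},{rs}:{h - rh:.6g})", h

    s, _ = build(2 * n - 2)
    return s + ";"


def tissue_tree(mean_profiles: pd.DataFrame, method: str = "average") -> TissueTree:
    """Average-linkage agglomeration of tissues on Euclidean distance
    between mean feature profiles (rows = tissues)."""
    if len(mean_profiles) < 3:
        raise ValueError("tissue_tree needs at least 3 tissues")
    Z = scipy.cluster.hierarchy.linkage(
        mean_profiles.to_numpy(dtype=float), method=method, metric="euclidean"
    )
    labels = [str(x) for x in mean_profiles.index]
    return TissueTree(labels=labels, linkage=Z, newick=_linkage_to_newick(Z, labels))
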