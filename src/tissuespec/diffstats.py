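"""Differential statistics: rank-sum differential expression for single
cells, median-of-ratios size factors and a simplified negative-binomial
Wald test for bulk peak counts, and Benjamini-Hochberg adjustment.

The peak test is a deliberately transparent stand-in for a full NB GLM
framework: per-peak method-of-moments dispersions are pooled across peaks
within count-mean bins, and a Wald z is formed on the log2 ratio of
size-factor-normalized group means. Numeric parity with external tools is
not a goal; calibration and planted-truth recovery are.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import PeakCountMatrix


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _resolve_cells(adata: ad.AnnData, cells) -> np.ndarray:
    """Cells as positional indices, from names, bool mask or positions."""
    arr = np.asarray(cells)
    if arr.dtype == bool:
        if arr.size != adata.n_obs:
            raise ValueError("boolean cell mask has wrong length")
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        return arr
    idx = adata.obs_names.get_indexer(arr)
    if (idx < 0).any():
        raise ValueError("unknown cell names in group")
    return idx


def wilcoxon_de(
    adata: ad.AnnData,
    cells_a,
    cells_b,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Two-sided rank-sum differential expression of group A over B.

    Operates on log-normalized values; the fold change is computed on the
    expm1 scale with pseudocount 1 (the convention of the standard
    single-cell toolkits). Genes whose expressing fraction fails
    ``min_pct`` in both groups, or whose |log2fc| is below ``logfc_min``,
    are reported untested with the sentinel p = 1.

    Returns a DataFrame indexed by gene with columns log2fc, stat, p, q,
    pct_a, pct_b, tested.
    """
    ia = _resolve_cells(adata, cells_a)
    ib = _resolve_cells(adata, cells_b)
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups overlap")
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("each group needs at least 3 cells")
    V = np.asarray(adata.layers[layer])
    A = V[ia]
    B = V[ib]

    # exact permutation null at small n, normal approximation otherwise
    small = len(ia) + len(ib) <= 30
    mwu_method = (
        scipy.stats.PermutationMethod(n_resamples=200_000, rng=0)
        if small
        else "asymptotic"
    )

    pct_a = (A > 0).mean(axis=0)
    pct_b = (B > 0).mean(axis=0)
    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)

    tested = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(log2fc) >= logfc_min)

    p = np.ones(V.shape[1])
    stat = np.zeros(V.shape[1])
    if tested.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-tied genes -> p=1 below
            res = scipy.stats.mannwhitneyu(
                A[:, tested], B[:, tested], axis=0,
                alternative="two-sided", method=mwu_method,
            )
        pt = np.nan_to_num(res.pvalue, nan=1.0)
        p[tested] = np.clip(pt, 0.0, 1.0)
        stat[tested] = res.statistic
    q = np.ones_like(p)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat": stat,
            "p": p,
            "q": q,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "tested": tested,
        },
        index=pd.Index(adata.var_names, name="feature_id"),
    )


def median_ratio_size_factors(counts: pd.DataFrame | PeakCountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Peaks with a zero in any sample are excluded from the reference, as in
    the standard bulk normalization. Falls back to library-size ratios
    (with a warning) when no peak is positive everywhere.
    """
    if isinstance(counts, PeakCountMatrix):
        counts = counts.counts
    K = counts.to_numpy(dtype=float)
    positive = (K > 0).all(axis=1)
    if positive.any():
        logK = np.log(K[positive])
        log_geo = logK.mean(axis=1, keepdims=True)
        log_sf = np.median(logK - log_geo, axis=0)
    else:
        warnings.warn("no peak positive in all samples; using library-size ratios")
        totals = K.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        log_sf = np.log(totals)
    log_sf = log_sf - log_sf.mean()  # geometric-mean centering
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def _pooled_dispersions(
    norm: np.ndarray, groups: list[np.ndarray], inv_sf_mean: float, n_bins: int = 20
) -> np.ndarray:
    """Binned method-of-moments NB dispersions on the normalized scale.

    Per peak: alpha = (within-group variance - Poisson part) / mean^2,
    then averaged across peaks within quantile bins of the overall mean
    and floored at 1e-8. The plain bin mean is used: per-peak moment
    estimates are strongly right-skewed at few replicates, so robust
    (trimmed/median) bin summaries systematically underestimate the
    dispersion and inflate the test.
    """
    mu = norm.mean(axis=1)
    ss = 0.0
    df = 0
    parts = []
    for g in groups:
        sub = norm[:, g]
        parts.append(((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
        df += len(g) - 1
    s2 = sum(parts) / max(df, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_raw = (s2 - mu * inv_sf_mean) / np.maximum(mu, 1e-12) ** 2
    alpha_raw = np.where(mu > 0, alpha_raw, 0.0)

    order = np.argsort(mu, kind="stable")
    alpha = np.full(norm.shape[0], 1e-8)
    bins = np.array_split(order, min(n_bins, max(1, norm.shape[0] // 10)))
    for b in bins:
        if len(b) == 0:
            continue
        alpha[b] = max(float(alpha_raw[b].mean()), 1e-8)
    return alpha


def nb_wald_da(
    pcm: PeakCountMatrix,
    group_a: list[str],
    group_b: list[str],
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test for differential accessibility,
    group A over group B, on size-factor-normalized peak counts.

    Returns a DataFrame indexed by peak id with columns log2fc, stat
    (Wald z), p, q. All-zero peaks come back with log2fc 0 and p 1.
    """
    for g, name in ((group_a, "A"), (group_b, "B")):
        if len(g) < 2:
            raise ValueError(f"group {name} needs at least 2 samples")
    if size_factors is None:
        size_factors = median_ratio_size_factors(pcm.counts[list(group_a) + list(group_b)])
    sf = size_factors.reindex(pcm.counts.columns)

    cols = list(pcm.counts.columns)
    ia = np.array([cols.index(s) for s in group_a])
    ib = np.array([cols.index(s) for s in group_b])
    K = pcm.counts.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    norm = K / s[None, :]

    used = np.concatenate([ia, ib])
    inv_sf_mean = float(np.mean(1.0 / s[used]))
    alpha = _pooled_dispersions(norm[:, used], [np.arange(len(ia)),
                                                np.arange(len(ia), len(used))],
                                inv_sf_mean)

    eps = 0.5 * inv_sf_mean  # half a raw count on the normalized scale
    mu_a = norm[:, ia].mean(axis=1)
    mu_b = norm[:, ib].mean(axis=1)
    all_zero = (K[:, used].sum(axis=1) == 0)

    mu_a_s = np.maximum(mu_a, eps)
    mu_b_s = np.maximum(mu_b, eps)
    log2fc = np.log2(mu_a_s) - np.log2(mu_b_s)

    def group_var(mu, idx):
        # Var(mean of K_i/s_i) with Var(K_i) = s_i mu + alpha (s_i mu)^2
        contrib = mu[:, None] / s[idx][None, :] + alpha[:, None] * mu[:, None] ** 2
        return contrib.sum(axis=1) / len(idx) ** 2

    var_a = group_var(mu_a_s, ia)
    var_b = group_var(mu_b_s, ib)
    se = np.sqrt(var_a / mu_a_s**2 + var_b / mu_b_s**2) / np.log(2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))

    log2fc[all_zero] = 0.0
    z[all_zero] = 0.0
    p[all_zero] = 1.0
    q = bh_adjust(p)

    return pd.DataFrame(
        {"log2fc": log2fc, "stat": z, "p": p, "q": q},
        index=pcm.counts.index.rename("feature_id"),
    )
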