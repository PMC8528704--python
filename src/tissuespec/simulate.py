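"""Synthetic five-tissue ILC2 data with planted, manifest-recorded truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial (Gamma-Poisson) UMI counts across five tissues
(BM, LI, SI, Lung, Pancreas) with planted tissue-specific genes, a set of
genes shared between the two intestinal tissues, mitochondrial genes,
contaminant cell clusters carrying named marker panels, a latent-factor
correlation block around one target gene (Ikzf3 by default), and replicate
ATAC peak counts whose planted accessibility effects are routed to the
planted genes preferentially through non-promoter peaks.

Everything is deterministic given ``SimParams.seed``; independent RNG
streams per stage keep the gene-role assignment identical whether or not
the expensive count draws are made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .containers import PeakCountMatrix
from .intervals import GeneAnnotation, GeneModel, PeakSet

TISSUES = ("BM", "LI", "SI", "Lung", "Pancreas")

# mouse mitochondrial protein/rRNA gene symbols, used to name mito genes
MITO_NAMES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]

DEFAULT_PANELS = {
    "ILC3": ["Il22", "Rorc", "Ccr6", "Klrb1c"],
    "Bcell": ["Jchain", "Mzb1", "Ebf1", "Cd79a"],
    "Tcell": ["Cd28", "Cd3e", "Cd8a"],
}

POS_BLOCK_NAMES = ["Rora", "Gata3", "Pdcd1", "Areg", "Il5"]
NEG_BLOCK_NAMES = ["Hspa1a", "Jun", "Fos"]


@dataclass
class CorrBlockParams:
    """Latent-factor correlation block around one target gene."""

    target_gene: str = "Ikzf3"
    n_pos: int = 12
    n_neg: int = 3
    latent_sigma: float = 0.8
    target_mean: float = 2.0


@dataclass
class AtacParams:
    replicates_per_tissue: int = 2
    peaks_promoter: int = 1
    peaks_intragenic: int = 2
    peaks_intergenic: int = 2
    coupled_fold: float = 4.0
    promoter_coupling: float = 0.0
    peak_nb_dispersion: float = 0.05
    peak_baseline_mean: float = 100.0
    dropout: float = 0.05
    libsize_sigma: float = 0.15


@dataclass
class SimParams:
    tissues: tuple[str, ...] = TISSUES
    cells_per_tissue: int = 500
    # fixed per-tissue multipliers (~±30%) so downsampling is non-trivial
    tissue_size_multipliers: tuple[float, ...] = (1.0, 1.3, 0.85, 0.7, 1.15)
    n_genes: int = 2000
    nb_dispersion: float = 0.5
    baseline_mean: float = 1.0
    ts_genes_per_tissue: int = 20
    ts_fold: float = 4.0
    shared_intestinal_genes: int = 10
    mito_gene_count: int = 13
    mito_mean: float = 5.0
    contaminant_fraction: float = 0.05
    contaminant_panels: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PANELS.items()}
    )
    # lineage markers are near-silent outside their lineage and high within
    marker_baseline: float = 0.05
    marker_mean: float = 8.0
    dying_mito_fold: float = 6.0
    cell_size_sigma: float = 0.3
    corr_block: CorrBlockParams = field(default_factory=CorrBlockParams)
    atac: AtacParams = field(default_factory=AtacParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ts_fold < 1:
            raise ValueError("ts_fold must be >= 1")
        if not (0 <= self.contaminant_fraction < 1):
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.atac.replicates_per_tissue < 2:
            raise ValueError("need at least 2 ATAC replicates per tissue")
        if len(self.tissue_size_multipliers) != len(self.tissues):
            raise ValueError("one size multiplier per tissue required")

    def _streams(self) -> dict[str, np.random.Generator]:
        kids = np.random.SeedSequence(self.seed).spawn(4)
        names = ["annotation", "roles", "scrna", "atac"]
        return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


@dataclass
class TruthManifest:
    """Planted ground truth: per-gene effects, per-cell identities,
    per-peak coupling. Sufficient to score any downstream caller."""

    genes: pd.DataFrame
    cells: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    replicate_presence: pd.DataFrame | None = None

    def ts_genes(self, tissue: str) -> list[str]:
        g = self.genes
        return list(g.index[(g["role"] == "ts") & (g["tissue"] == tissue)])

    def shared_intestinal(self) -> list[str]:
        return list(self.genes.index[self.genes["role"] == "shared_intestinal"])

    def coupled_peaks(self, tissue: str | None = None) -> list[str]:
        if self.peaks is None:
            return []
        p = self.peaks
        mask = p["coupled"]
        if tissue is not None:
            mask = mask & (p["tissue"] == tissue)
        return list(p.index[mask])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "cells": None if self.cells is None
            else self.cells.reset_index().to_dict(orient="list"),
            "peaks": None if self.peaks is None
            else self.peaks.reset_index().to_dict(orient="list"),
            "replicate_presence": None if self.replicate_presence is None
            else {
                "index": list(self.replicate_presence.index),
                "columns": list(self.replicate_presence.columns),
                "values": self.replicate_presence.to_numpy().astype(int).tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)

        def df(d, index_col):
            if d is None:
                return None
            return pd.DataFrame(d).set_index(index_col)

        rp = payload["replicate_presence"]
        return cls(
            genes=df(payload["genes"], "gene_id"),
            cells=df(payload["cells"], "cell_id"),
            peaks=df(payload["peaks"], "peak_id"),
            replicate_presence=None if rp is None else pd.DataFrame(
                np.array(rp["values"], dtype=bool),
                index=rp["index"], columns=rp["columns"],
            ),
        )


# ---------------------------------------------------------------------------
# annotation

GENE_SPAN = 10_000
GENE_STEP = 40_000
FLANK_MARGIN = 10_000


def generate_annotation(params: SimParams) -> GeneAnnotation:
    """Lay ``n_genes`` non-overlapping gene models on two synthetic
    chromosomes, alternating strand, with >=2 exons and terminal UTRs."""
    if params.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = params._streams()["annotation"]
    n = params.n_genes
    n_chr1 = (n + 1) // 2
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    per_chrom = {"chrS1": n_chr1, "chrS2": n - n_chr1}
    gi = 0
    for chrom, count in per_chrom.items():
        for k in range(count):
            start = FLANK_MARGIN + k * GENE_STEP
            end = start + GENE_SPAN
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [
                (start, start + 500),
                (start + 4000, start + 5000),
                (start + 9500, end),
            ]
            if strand == "+":
                utr5 = [(start, start + 200)]
                utr3 = [(end - 300, end)]
            else:
                utr5 = [(end - 200, end)]
                utr3 = [(start, start + 300)]
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:04d}",  # renamed later by role assignment
                    chrom=chrom,
                    strand=strand,
                    gene_start=start,
                    gene_end=end,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
            gi += 1
        chrom_sizes[chrom] = FLANK_MARGIN + count * GENE_STEP + FLANK_MARGIN
    if per_chrom["chrS2"] == 0:
        chrom_sizes["chrS2"] = 2 * FLANK_MARGIN
    ann = GeneAnnotation(genes=genes, chrom_sizes=chrom_sizes)
    _apply_gene_names(ann, params)
    return ann


def gene_roles(params: SimParams) -> pd.DataFrame:
    """Deterministic role assignment for every gene.

    Returns a DataFrame indexed by gene_id with columns
    role (none/ts/shared_intestinal/mito/marker/target/corr_pos/corr_neg),
    tissue (planted tissue, '' if none), fold, mito (bool),
    corr_sign (+1/-1/0), and name (display symbol).
    """
    rng = params._streams()["roles"]
    n = params.n_genes
    marker_names = [g for panel in params.contaminant_panels.values() for g in panel]
    n_special = (
        params.mito_gene_count
        + len(marker_names)
        + 1
        + params.corr_block.n_pos
        + params.corr_block.n_neg
        + params.ts_genes_per_tissue * len(params.tissues)
        + params.shared_intestinal_genes
    )
    if n_special > n:
        raise ValueError(f"n_genes={n} too small for {n_special} special roles")
    pool = list(rng.permutation(n))

    def take(k):
        out = [pool.pop() for _ in range(k)]
        return out

    roles = pd.DataFrame(
        {
            "role": ["none"] * n,
            "tissue": [""] * n,
            "fold": [1.0] * n,
            "mito": [False] * n,
            "corr_sign": [0] * n,
            "name": [f"Gene{i:04d}" for i in range(n)],
        }
    )
    for i, idx in enumerate(take(params.mito_gene_count)):
        roles.loc[idx, ["role", "mito"]] = ["mito", True]
        roles.loc[idx, "name"] = (
            MITO_NAMES[i] if i < len(MITO_NAMES) else f"mt-Gene{i}"
        )
    for i, idx in enumerate(take(len(marker_names))):
        roles.loc[idx, "role"] = "marker"
        roles.loc[idx, "name"] = marker_names[i]
    (t_idx,) = take(1)
    roles.loc[t_idx, "role"] = "target"
    roles.loc[t_idx, "name"] = params.corr_block.target_gene
    for i, idx in enumerate(take(params.corr_block.n_pos)):
        roles.loc[idx, ["role", "corr_sign"]] = ["corr_pos", 1]
        if i < len(POS_BLOCK_NAMES):
            roles.loc[idx, "name"] = POS_BLOCK_NAMES[i]
    for i, idx in enumerate(take(params.corr_block.n_neg)):
        roles.loc[idx, ["role", "corr_sign"]] = ["corr_neg", -1]
        if i < len(NEG_BLOCK_NAMES):
            roles.loc[idx, "name"] = NEG_BLOCK_NAMES[i]
    for tissue in params.tissues:
        for idx in take(params.ts_genes_per_tissue):
            roles.loc[idx, ["role", "tissue", "fold"]] = [
                "ts", tissue, params.ts_fold,
            ]
    for idx in take(params.shared_intestinal_genes):
        roles.loc[idx, ["role", "tissue", "fold"]] = [
            "shared_intestinal", "LI+SI", params.ts_fold,
        ]
    roles.index = pd.Index(roles["name"], name="gene_id")
    roles = roles.drop(columns=["name"])
    roles["pos"] = np.arange(n)
    return roles


def _apply_gene_names(ann: GeneAnnotation, params: SimParams) -> None:
    names = gene_roles(params).index
    for g, name in zip(ann.genes, names):
        g.gene_id = name
    ann.__post_init__()  # rebuild chromosome index


def _tissue_fold_matrix(roles: pd.DataFrame, tissues) -> pd.DataFrame:
    """tissues x genes multiplicative fold matrix from planted roles."""
    folds = pd.DataFrame(1.0, index=list(tissues), columns=roles.index)
    for gid, row in roles.iterrows():
        if row["role"] == "ts":
            folds.loc[row["tissue"], gid] = row["fold"]
        elif row["role"] == "shared_intestinal":
            folds.loc["LI", gid] = row["fold"]
            folds.loc["SI", gid] = row["fold"]
    return folds


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_scrna(
    params: SimParams, ann: GeneAnnotation | None = None
) -> tuple[ad.AnnData, TruthManifest]:
    """Simulate the five-tissue single-cell count matrix.

    Counts are NB with mean = per-gene baseline x planted tissue fold x
    cell size factor, modulated by the correlation-block latent factor and
    contaminant marker elevation. Returns AnnData (cells x genes, raw
    integer counts) plus the TruthManifest (genes + cells).
    """
    rng = params._streams()["scrna"]
    roles = gene_roles(params)
    n_genes = params.n_genes
    tissues = list(params.tissues)

    baseline = rng.gamma(2.0, 0.5 * params.baseline_mean, size=n_genes) \
        + 0.1 * params.baseline_mean
    baseline[roles["mito"].to_numpy()] = params.mito_mean
    baseline[(roles["role"] == "marker").to_numpy()] = params.marker_baseline
    target_mask = (roles["role"] == "target").to_numpy()
    baseline[target_mask] = params.corr_block.target_mean

    folds = _tissue_fold_matrix(roles, tissues)

    n_per_tissue = [
        max(1, int(round(params.cells_per_tissue * m)))
        for m in params.tissue_size_multipliers
    ]
    cell_tissue = np.repeat(tissues, n_per_tissue)
    n_cells = len(cell_tissue)
    cell_ids = [f"{t}_{i:05d}" for i, t in enumerate(cell_tissue)]

    size = np.exp(rng.normal(0.0, params.cell_size_sigma, size=n_cells))
    sigma = params.corr_block.latent_sigma
    z = rng.normal(0.0, 1.0, size=n_cells)

    mu = np.outer(size, baseline)
    for ti, t in enumerate(tissues):
        lo = sum(n_per_tissue[:ti])
        hi = lo + n_per_tissue[ti]
        mu[lo:hi, :] *= folds.loc[t].to_numpy()[None, :]

    # correlation block: shared log-normal latent factor, mean-one corrected
    exponent = np.zeros(n_genes)
    exponent[target_mask] = 1.0
    exponent[(roles["corr_sign"] == 1).to_numpy()] = 1.0
    exponent[(roles["corr_sign"] == -1).to_numpy()] = -1.0
    active = exponent != 0
    if active.any() and sigma > 0:
        latent = np.exp(
            np.outer(sigma * z, exponent[active]) - sigma**2 / 2.0
        )
        mu[:, active] *= latent

    # contaminants: each tissue carries one marker-panel cluster (panels
    # cycle across tissues) plus a smaller high-mito 'dying' group, so
    # contaminants form coherent clusters as they do in real libraries
    panel_names = list(params.contaminant_panels)
    contaminant = np.array([""] * n_cells, dtype=object)
    marker_cols = {
        panel: roles.index.get_indexer(genes)
        for panel, genes in params.contaminant_panels.items()
    }
    mito_cols = np.flatnonzero(roles["mito"].to_numpy())
    for ti, t in enumerate(tissues):
        lo = sum(n_per_tissue[:ti])
        n_t = n_per_tissue[ti]
        n_con = int(np.floor(params.contaminant_fraction * n_t))
        chosen = lo + rng.choice(n_t, size=n_con, replace=False)
        n_dying = n_con // 4
        panel = panel_names[ti % len(panel_names)] if panel_names else "dying"
        for k, c in enumerate(chosen):
            ctype = "dying" if k < n_dying else panel
            contaminant[c] = ctype
            if ctype == "dying":
                mu[c, mito_cols] *= params.dying_mito_fold
            else:
                cols = marker_cols[ctype]
                cols = cols[cols >= 0]
                mu[c, cols] = params.marker_mean * size[c]

    counts = _nb_draw(rng, mu, params.nb_dispersion).astype(np.int32)

    obs = pd.DataFrame(
        {"tissue": cell_tissue, "contaminant": contaminant},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {"mito": roles["mito"].to_numpy()},
        index=pd.Index(roles.index, name="gene_id"),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["mito_genes"] = list(roles.index[roles["mito"]])

    truth = TruthManifest(
        genes=roles.drop(columns=["pos"]),
        cells=obs.copy(),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# ATAC

PEAK_WIDTH = {"promoter": 200, "intragenic": 300, "intergenic": 300}


def _place_peaks(gene: GeneModel, atac: AtacParams) -> list[tuple[str, int, int, str]]:
    """Deterministic peak placement per gene: (class, start, end, id)."""
    s, e = gene.gene_start, gene.gene_end
    tss = gene.tss
    out = []
    # promoter peaks: inside the strand-aware promoter window
    for k in range(atac.peaks_promoter):
        if gene.strand == "+":
            a = tss - 800 + k * 220
        else:
            a = tss + 400 + k * 220
        out.append(("promoter", a, a + PEAK_WIDTH["promoter"],
                    f"{gene.gene_id}_prom{k}"))
    # intragenic: mid-span, clear of the promoter window on either strand
    intra_anchors = [s + 2000, s + 6000, s + 3500, s + 7200]
    for k in range(atac.peaks_intragenic):
        a = intra_anchors[k % len(intra_anchors)]
        out.append(("intragenic", a, a + PEAK_WIDTH["intragenic"],
                    f"{gene.gene_id}_intra{k}"))
    # intergenic: flanks, within FLANK_MARGIN/2 of the span so the nearest
    # TSS is this gene's
    inter_anchors = [s - 6000, e + 5000, s - 4500, e + 3500]
    for k in range(atac.peaks_intergenic):
        a = inter_anchors[k % len(inter_anchors)]
        out.append(("intergenic", a, a + PEAK_WIDTH["intergenic"],
                    f"{gene.gene_id}_inter{k}"))
    return out


def generate_atac(
    params: SimParams, ann: GeneAnnotation, truth: TruthManifest
) -> tuple[PeakCountMatrix, dict[str, list[PeakSet]], TruthManifest]:
    """Simulate replicate ATAC peak counts coupled to the planted genes.

    Non-promoter peaks of planted genes carry ``coupled_fold`` in the
    gene's tissue(s); promoter peaks carry it only with probability
    ``promoter_coupling``. Returns the peak count matrix, per-tissue
    replicate PeakSets (with dropout), and the truth manifest extended
    with the per-peak table.
    """
    atac = params.atac
    rng = params._streams()["atac"]
    tissues = list(params.tissues)
    roles = truth.genes

    rows = []
    for gene in ann.genes:
        role = roles.loc[gene.gene_id]
        planted = role["role"] in ("ts", "shared_intestinal")
        up_tissues: list[str] = []
        if planted:
            up_tissues = ["LI", "SI"] if role["tissue"] == "LI+SI" else [role["tissue"]]
        for cls, a, b, pid in _place_peaks(gene, atac):
            coupled = False
            if planted:
                if cls == "promoter":
                    coupled = bool(rng.random() < atac.promoter_coupling)
                else:
                    coupled = True
            rows.append(
                (pid, gene.chrom, a, b, gene.gene_id, cls, coupled,
                 role["tissue"] if coupled else "",
                 atac.coupled_fold if coupled else 1.0)
            )
    peaks_df = pd.DataFrame(
        rows,
        columns=["peak_id", "chrom", "start", "end", "gene_id",
                 "region_class", "coupled", "tissue", "fold"],
    ).set_index("peak_id")

    all_peaks = PeakSet(
        peaks_df.reset_index()[["chrom", "start", "end", "peak_id"]].rename(
            columns={"peak_id": "id"}
        ),
        provenance="synthetic-atlas",
    )
    order = all_peaks.ids  # PeakSet sorts by coordinate
    peaks_df = peaks_df.loc[order]

    n_peaks = len(peaks_df)
    baseline = rng.gamma(4.0, atac.peak_baseline_mean / 4.0, size=n_peaks)

    sample_names = []
    sample_tissue = []
    sample_rep = []
    for t in tissues:
        for r in range(1, atac.replicates_per_tissue + 1):
            sample_names.append(f"{t}_rep{r}")
            sample_tissue.append(t)
            sample_rep.append(r)
    lib = np.exp(rng.normal(0.0, atac.libsize_sigma, size=len(sample_names)))

    fold_matrix = np.ones((n_peaks, len(sample_names)))
    coupled_mask = peaks_df["coupled"].to_numpy()
    for j, t in enumerate(sample_tissue):
        up = coupled_mask & (
            (peaks_df["tissue"] == t).to_numpy()
            | ((peaks_df["tissue"] == "LI+SI").to_numpy() & (t in ("LI", "SI")))
        )
        fold_matrix[up, j] = atac.coupled_fold

    mu = baseline[:, None] * fold_matrix * lib[None, :]
    counts = _nb_draw(rng, mu, atac.peak_nb_dispersion).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=peaks_df.index, columns=sample_names)

    # replicate peak presence with dropout -> irreproducible peaks
    presence = rng.random((n_peaks, len(sample_names))) >= atac.dropout
    presence_df = pd.DataFrame(presence, index=peaks_df.index, columns=sample_names)
    replicate_sets: dict[str, list[PeakSet]] = {}
    base = all_peaks.df.set_index("id")
    for t in tissues:
        sets = []
        for name in [s for s, st in zip(sample_names, sample_tissue) if st == t]:
            keep = presence_df[name]
            sub = base.loc[keep[keep].index]
            sub = sub.reset_index().rename(columns={sub.index.name or "index": "id"})
            sets.append(
                PeakSet(sub[["chrom", "start", "end", "id"]], provenance=name)
            )
        replicate_sets[t] = sets

    samples = pd.DataFrame(
        {"tissue": sample_tissue, "replicate": sample_rep},
        index=pd.Index(sample_names, name="sample"),
    )
    pcm = PeakCountMatrix(counts=counts_df, samples=samples, peaks=all_peaks)
    truth_out = TruthManifest(
        genes=truth.genes,
        cells=truth.cells,
        peaks=peaks_df[["gene_id", "region_class", "coupled", "tissue", "fold"]],
        replicate_presence=presence_df,
    )
    return pcm, replicate_sets, truth_out
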