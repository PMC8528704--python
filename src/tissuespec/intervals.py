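"""Genomic interval engine: peak sets, merging, region classification,
nearest-gene assignment.

All coordinates are 0-based, half-open (BED convention). Region
classification follows the HOMER-style precedence promoter > intragenic >
intergenic, with a strand-aware promoter window of 1000 bp upstream to
100 bp downstream of the TSS. Gene assignment uses the peak midpoint
(integer floor) against gene TSSs, breaking exact distance ties by
lexicographic gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100

PEAK_COLUMNS = ["chrom", "start", "end", "id"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with a stable id."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """An ordered collection of peaks with a provenance label.

    Backed by a DataFrame with columns chrom/start/end/id, sorted by
    (chrom, start, end). Ids are unique within a set.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in PEAK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"PeakSet missing columns {missing}")
        df = df[PEAK_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"start >= end for peak {df.loc[bad, 'id']!r}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate peak id {dup!r}")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        self.df = df

    @classmethod
    def from_intervals(cls, intervals, provenance: str = "") -> "PeakSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.id or f"{iv.chrom}:{iv.start}-{iv.end}")
                for iv in intervals]
        return cls(pd.DataFrame(rows, columns=PEAK_COLUMNS), provenance=provenance)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), row.id)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()


@dataclass
class GeneModel:
    """A gene with TSS, strand and exon/UTR structure (all half-open)."""

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.gene_start >= self.gene_end:
            raise ValueError(f"empty span for {self.gene_id}")
        for s, e in self.exons + self.utr5 + self.utr3:
            if not (self.gene_start <= s < e <= self.gene_end):
                raise ValueError(f"exon/UTR outside span for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1

    def promoter_window(
        self,
        upstream: int = PROMOTER_UPSTREAM,
        downstream: int = PROMOTER_DOWNSTREAM,
    ) -> tuple[int, int]:
        """Strand-aware promoter interval around the TSS, clipped at 0."""
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream + 1, self.tss + upstream + 1
        return max(0, lo), hi


@dataclass
class GeneAnnotation:
    """A collection of gene models plus chromosome sizes."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.gene_end > size:
                raise ValueError(f"gene {g.gene_id} extends past {g.chrom} ({size})")
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _components(starts, ends, members: list[int], min_overlap: int) -> list[list[int]]:
    """Connected components of the >=min_overlap overlap graph over
    ``members`` (indices into starts/ends), sorted by (start, end)."""
    parent = {m: m for m in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ai in range(len(members)):
        a = members[ai]
        for bi in range(ai + 1, len(members)):
            b = members[bi]
            ov = min(ends[a], ends[b]) - max(starts[a], starts[b])
            if ov >= min_overlap:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for m in members:
        comps.setdefault(find(m), []).append(m)
    return sorted(
        comps.values(),
        key=lambda c: (min(starts[m] for m in c), max(ends[m] for m in c)),
    )


def merge_overlapping(peaksets: list[PeakSet], min_overlap: int = 1) -> PeakSet:
    """Merge peaks across sets into maximal intervals (HOMER MergePeaks style).

    Two intervals belong to the same merged peak when they share at least
    ``min_overlap`` bases, transitively. The output records, per merged
    interval, the contributing source ids from each input set in a
    ``sources`` column (list of lists, parallel to the inputs).
    """
    if not peaksets:
        raise ValueError("merge_overlapping requires at least one PeakSet")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    frames = []
    for k, ps in enumerate(peaksets):
        f = ps.df.copy()
        f["_set"] = k
        frames.append(f)
    allp = pd.concat(frames, ignore_index=True)
    allp = allp.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    out_rows = []
    out_sources: list[list[list[str]]] = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        ids = grp["id"].to_numpy()
        sets = grp["_set"].to_numpy()
        n = len(grp)
        # envelope clusters: maximal runs of >=1 bp transitive overlap
        i = 0
        while i < n:
            cur_end = int(ends[i])
            j = i + 1
            while j < n and starts[j] < cur_end:
                cur_end = max(cur_end, int(ends[j]))
                j += 1
            members = list(range(i, j))
            for comp in _components(starts, ends, members, min_overlap):
                comp_start = int(min(starts[m] for m in comp))
                comp_end = int(max(ends[m] for m in comp))
                srcs: list[list[str]] = [[] for _ in peaksets]
                for m in comp:
                    srcs[int(sets[m])].append(str(ids[m]))
                out_rows.append(
                    (chrom, comp_start, comp_end, f"{chrom}:{comp_start}-{comp_end}")
                )
                out_sources.append(srcs)
            i = j

    merged = pd.DataFrame(out_rows, columns=PEAK_COLUMNS)
    if merged["id"].duplicated().any():  # identical spans in one envelope
        merged["id"] = merged["id"] + np.where(
            merged["id"].duplicated(keep=False),
            "." + merged.groupby("id").cumcount().astype(str),
            "",
        )
    merged["sources"] = out_sources
    ps = PeakSet(merged[PEAK_COLUMNS], provenance="merged")
    # PeakSet re-sorts; rows were appended chrom-sorted so order is preserved
    ps.df["sources"] = out_sources
    return ps


def classify_region(peak: GenomicInterval, ann: GeneAnnotation) -> str:
    """Classify a peak as 'promoter', 'intragenic' or 'intergenic'.

    Promoter wins if the peak overlaps any gene's promoter window;
    otherwise intragenic if it overlaps any gene span; else intergenic.
    """
    if peak.chrom not in ann.chrom_sizes:
        raise ValueError(f"unknown chromosome {peak.chrom!r}")
    genes = ann.genes_on(peak.chrom)
    for g in genes:
        lo, hi = g.promoter_window()
        if _overlaps(peak.start, peak.end, lo, hi):
            return "promoter"
    for g in genes:
        if _overlaps(peak.start, peak.end, g.gene_start, g.gene_end):
            return "intragenic"
    return "intergenic"


def nearest_gene(peak: GenomicInterval, ann: GeneAnnotation) -> tuple[str | None, int]:
    """Assign the gene whose TSS is nearest the peak midpoint.

    Returns (gene_id, signed strand-oriented distance midpoint - TSS);
    positive means downstream of the TSS in the gene's orientation.
    Exact-distance ties break to the lexicographically smaller gene id.
    Returns (None, 0) when the chromosome carries no gene.
    """
    genes = ann.genes_on(peak.chrom)
    if not genes:
        return None, 0
    mid = peak.midpoint
    best: GeneModel | None = None
    best_abs = None
    for g in sorted(genes, key=lambda g: g.gene_id):
        d = abs(mid - g.tss)
        if best_abs is None or d < best_abs:
            best, best_abs = g, d
    assert best is not None
    signed = mid - best.tss
    if best.strand == "-":
        signed = -signed
    return best.gene_id, int(signed)


class _ChromIndex:
    """Sorted-array index over one chromosome's promoter windows, gene
    spans and TSSs, answering overlap/nearest queries in O(log n)."""

    def __init__(self, genes: list[GeneModel]):
        prom = np.array([g.promoter_window() for g in genes], dtype=np.int64)
        span = np.array([(g.gene_start, g.gene_end) for g in genes], dtype=np.int64)
        self.prom_lo, self.prom_hi_cummax = self._prep(prom)
        self.span_lo, self.span_hi_cummax = self._prep(span)
        order = np.argsort([g.tss for g in genes], kind="stable")
        self.tss = np.array([genes[i].tss for i in order], dtype=np.int64)
        self.tss_gene = [genes[i] for i in order]

    @staticmethod
    def _prep(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(arr[:, 0], kind="stable")
        lo = arr[order, 0]
        hi = arr[order, 1]
        return lo, np.maximum.accumulate(hi)

    @staticmethod
    def _any_overlap(lo, hi_cummax, start: int, end: int) -> bool:
        # windows sorted by lo with running max of hi: overlap exists iff
        # some window with lo < end has hi > start
        k = int(np.searchsorted(lo, end, side="left"))
        return k > 0 and hi_cummax[k - 1] > start

    def classify(self, start: int, end: int) -> str:
        if self._any_overlap(self.prom_lo, self.prom_hi_cummax, start, end):
            return "promoter"
        if self._any_overlap(self.span_lo, self.span_hi_cummax, start, end):
            return "intragenic"
        return "intergenic"

    def nearest(self, mid: int) -> tuple[str, int]:
        k = int(np.searchsorted(self.tss, mid))
        best_d = None
        for j in (k - 1, k):
            if 0 <= j < len(self.tss):
                d = abs(mid - int(self.tss[j]))
                if best_d is None or d < best_d:
                    best_d = d
        assert best_d is not None
        # all genes at exactly best_d (same-position TSSs included)
        cands = []
        for pos in (mid - best_d, mid + best_d):
            a = int(np.searchsorted(self.tss, pos, side="left"))
            b = int(np.searchsorted(self.tss, pos, side="right"))
            cands.extend(self.tss_gene[a:b])
        g = min(cands, key=lambda g: g.gene_id)
        signed = mid - g.tss
        if g.strand == "-":
            signed = -signed
        return g.gene_id, int(signed)


def classify_peakset(peaks: PeakSet, ann: GeneAnnotation) -> pd.DataFrame:
    """Region class + nearest gene for every peak in one pass.

    Returns a DataFrame indexed by peak id with columns
    region_class / gene_id / tss_distance. Equivalent to calling
    :func:`classify_region` and :func:`nearest_gene` per peak, but uses a
    per-chromosome sorted index.
    """
    indexes = {
        chrom: _ChromIndex(genes)
        for chrom, genes in ann._by_chrom.items()
        if genes
    }
    rows = []
    for row in peaks.df.itertuples(index=False):
        if row.chrom not in ann.chrom_sizes:
            raise ValueError(f"unknown chromosome {row.chrom!r}")
        idx = indexes.get(row.chrom)
        if idx is None:
            rows.append((row.id, "intergenic", None, 0))
            continue
        start, end = int(row.start), int(row.end)
        cls = idx.classify(start, end)
        gid, dist = idx.nearest((start + end) // 2)
        rows.append((row.id, cls, gid, dist))
    return pd.DataFrame(
        rows, columns=["id", "region_class", "gene_id", "tss_distance"]
    ).set_index("id")
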