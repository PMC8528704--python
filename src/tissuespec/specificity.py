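"""Set construction for tissue specificity: genuine peaks, the combined
peak atlas, tissue-specific feature calling by pairwise one-vs-one
intersection, two-tissue shared signatures, and set overlaps.

A feature is tissue-specific for tissue T when it is significantly higher
(or lower, for commonly decreased features) in T than in *every* other
tissue in one-vs-one comparisons — the intersection over all
(n_tissues - 1) pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import PeakSet, merge_overlapping


@dataclass
class TissueSpecificSet:
    tissue: str
    features: list[str]
    direction: str  # "up" | "down"
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)


def genuine_peaks(replicates: list[PeakSet], min_overlap: int = 1) -> PeakSet:
    """Merged peaks supported by every biological replicate.

    A merged interval is genuine only when each replicate contributes at
    least one overlapping source peak.
    """
    if len(replicates) < 2:
        raise ValueError("genuine_peaks requires at least 2 replicate PeakSets")
    merged = merge_overlapping(replicates, min_overlap=min_overlap)
    keep = merged.df["sources"].map(lambda srcs: all(len(s) > 0 for s in srcs))
    out = merged.df.loc[keep].reset_index(drop=True)
    ps = PeakSet(out[["chrom", "start", "end", "id"]], provenance="genuine")
    ps.df["sources"] = out["sources"].tolist()
    return ps


def combined_atlas(
    tissue_genuine: dict[str, PeakSet] | list[PeakSet],
    min_overlap: int = 1,
) -> tuple[PeakSet, pd.DataFrame]:
    """Merge per-tissue genuine peaks into one atlas.

    Returns the merged PeakSet plus a boolean presence table
    (atlas peak x tissue, >=1 bp overlap). The 'shared' subset is the
    rows present in every tissue.
    """
    if isinstance(tissue_genuine, dict):
        names = list(tissue_genuine)
        sets = [tissue_genuine[t] for t in names]
    else:
        sets = list(tissue_genuine)
        names = [ps.provenance or f"set{i}" for i, ps in enumerate(sets)]
    if not sets:
        raise ValueError("combined_atlas requires at least one PeakSet")
    merged = merge_overlapping(sets, min_overlap=min_overlap)
    presence = pd.DataFrame(
        [[len(srcs[k]) > 0 for k in range(len(sets))] for srcs in merged.df["sources"]],
        index=pd.Index(merged.df["id"], name="peak_id"),
        columns=names,
    )
    atlas = PeakSet(merged.df[["chrom", "start", "end", "id"]], provenance="atlas")
    return atlas, presence


def shared_peaks(presence: pd.DataFrame) -> list[str]:
    """Atlas peaks present in every tissue."""
    return list(presence.index[presence.all(axis=1)])


def _oriented_result(
    results: dict[tuple[str, str], pd.DataFrame], a: str, b: str
) -> pd.DataFrame:
    """Differential result for (a over b), flipping a stored (b over a)."""
    if (a, b) in results:
        return results[(a, b)]
    if (b, a) in results:
        flipped = results[(b, a)].copy()
        flipped["log2fc"] = -flipped["log2fc"]
        return flipped
    raise KeyError(f"missing differential comparison for pair ({a}, {b})")


def call_tissue_specific(
    results: dict[tuple[str, str], pd.DataFrame],
    tissue: str,
    others: list[str],
    direction: str = "up",
    alpha: float = 0.05,
    fc_min: float = 0.0,
    use_q: bool = False,
) -> TissueSpecificSet:
    """Features consistently up (or down) in ``tissue`` versus every
    tissue in ``others`` under one-vs-one comparisons.

    ``use_q`` switches the significance gate from raw p to BH-adjusted q.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if tissue in others:
        raise ValueError("tissue cannot be compared against itself")
    surviving: set[str] | None = None
    provenance: dict = {
        "alpha": alpha, "fc_min": fc_min, "use_q": use_q,
        "direction": direction, "comparisons": [],
    }
    for other in others:
        df = _oriented_result(results, tissue, other)
        stat = df["q"] if use_q else df["p"]
        if direction == "up":
            hits = df.index[(stat < alpha) & (df["log2fc"] > fc_min)]
        else:
            hits = df.index[(stat < alpha) & (df["log2fc"] < -fc_min)]
        provenance["comparisons"].append(
            {"pair": (tissue, other), "n_hits": int(len(hits))}
        )
        surviving = set(hits) if surviving is None else surviving & set(hits)
    assert surviving is not None
    return TissueSpecificSet(
        tissue=tissue,
        features=sorted(surviving),
        direction=direction,
        provenance=provenance,
    )


def shared_signature(
    results: dict[tuple[str, str], pd.DataFrame],
    tissues_in: list[str],
    tissues_out: list[str],
    direction: str = "up",
    alpha: float = 0.05,
    fc_min: float = 0.0,
    use_q: bool = False,
) -> list[str]:
    """Features up in every in-tissue versus every out-tissue.

    With a single in-tissue this reduces to :func:`call_tissue_specific`.
    """
    if set(tissues_in) & set(tissues_out):
        raise ValueError("tissues_in and tissues_out must be disjoint")
    shared: set[str] | None = None
    for t in tissues_in:
        ts = call_tissue_specific(
            results, t, tissues_out,
            direction=direction, alpha=alpha, fc_min=fc_min, use_q=use_q,
        )
        shared = set(ts.features) if shared is None else shared & set(ts.features)
    return sorted(shared or set())


@dataclass
class SetOverlap:
    a_only: list[str]
    both: list[str]
    b_only: list[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.a_only), len(self.both), len(self.b_only)


def overlap_sets(a, b) -> SetOverlap:
    """Exact set algebra with stable (sorted) ordering."""
    sa, sb = set(a), set(b)
    return SetOverlap(
        a_only=sorted(sa - sb),
        both=sorted(sa & sb),
        b_only=sorted(sb - sa),
    )
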