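"""In-memory containers shared across the pipeline.

Single-cell counts live in AnnData (cells x genes, ``obs['tissue']``,
optional ``obs['cluster']``; mitochondrial gene names in
``uns['mito_genes']``). Bulk ATAC counts live in :class:`PeakCountMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import PeakSet


@dataclass
class PeakCountMatrix:
    """Raw fragment counts per (peak, sample) with sample metadata.

    counts:  DataFrame, peaks x samples, non-negative integers,
             indexed by peak id.
    samples: DataFrame indexed by sample name with columns
             ``tissue`` and ``replicate``.
    peaks:   PeakSet giving the genomic interval of every row.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    peaks: PeakSet

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative peak counts")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("counts columns must match sample metadata index")
        missing = set(self.counts.index) - set(self.peaks.ids)
        if missing:
            raise ValueError(f"{len(missing)} count rows missing from PeakSet")

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.samples["tissue"]))

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.samples.index[self.samples["tissue"] == tissue])

    def subset_peaks(self, peak_ids) -> "PeakCountMatrix":
        keep = [p for p in self.counts.index if p in set(peak_ids)]
        mask = self.peaks.df["id"].isin(keep)
        return PeakCountMatrix(
            counts=self.counts.loc[keep],
            samples=self.samples,
            peaks=PeakSet(self.peaks.df.loc[mask, ["chrom", "start", "end", "id"]],
                          provenance=self.peaks.provenance),
        )


def normalized_counts(pcm: PeakCountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Size-factor-normalized counts (counts / factor, per sample)."""
    sf = size_factors.reindex(pcm.counts.columns)
    if sf.isna().any():
        raise ValueError("size factors missing for some samples")
    return pcm.counts / sf.to_numpy()[None, :]


def log_normalized_counts(
    pcm: PeakCountMatrix, size_factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    return np.log2(normalized_counts(pcm, size_factors) + pseudocount)
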