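"""Readers and writers for the plain-text formats the pipeline touches.

Peaks travel as BED3/BED4, gene annotation as a GTF-lite TSV, count
matrices as MatrixMarket triplets with name sidecars or as TSV. All
coordinates are 0-based half-open on disk and in memory.

GTF-lite layout (tab-separated, one gene per line)::

    #chrom_size <chrom> <length>          (header lines, one per chromosome)
    gene_id  chrom  strand  start  end  exons  utr5  utr3

where ``exons``/``utr5``/``utr3`` are comma-joined ``start-end`` blocks
(``.`` for none).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .intervals import GeneAnnotation, GeneModel, PeakSet


def read_peaks(path: str | Path, provenance: str = "") -> PeakSet:
    """Read a BED3/BED4 file into a PeakSet.

    Ids come from column 4 when present, otherwise ``chrom:start-end``.
    Raises ValueError (naming the line) on malformed coordinates.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            pid = parts[3] if len(parts) >= 4 and parts[3] not in ("", ".") \
                else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, pid))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    return PeakSet(df, provenance=provenance or str(path))


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    peaks.df[["chrom", "start", "end", "id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def _blocks_to_str(blocks: list[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks) if blocks else "."


def _str_to_blocks(s: str) -> list[tuple[int, int]]:
    if s in (".", ""):
        return []
    out = []
    for part in s.split(","):
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return out


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"#chrom_size\t{chrom}\t{ann.chrom_sizes[chrom]}\n")
        fh.write("gene_id\tchrom\tstrand\tstart\tend\texons\tutr5\tutr3\n")
        for g in ann.genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.chrom,
                        g.strand,
                        str(g.gene_start),
                        str(g.gene_end),
                        _blocks_to_str(g.exons),
                        _blocks_to_str(g.utr5),
                        _blocks_to_str(g.utr3),
                    ]
                )
                + "\n"
            )


def read_annotation(path: str | Path) -> GeneAnnotation:
    chrom_sizes: dict[str, int] = {}
    genes: list[GeneModel] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#chrom_size"):
                _, chrom, size = line.split("\t")
                chrom_sizes[chrom] = int(size)
                continue
            if not line:
                continue
            if not header_seen:
                header_seen = True  # column header line
                continue
            gid, chrom, strand, start, end, exons, utr5, utr3 = line.split("\t")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    gene_start=int(start),
                    gene_end=int(end),
                    exons=_str_to_blocks(exons),
                    utr5=_str_to_blocks(utr5),
                    utr3=_str_to_blocks(utr3),
                )
            )
    return GeneAnnotation(genes=genes, chrom_sizes=chrom_sizes)


def _check_counts(values: np.ndarray, path) -> None:
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(f"{path}: negative count at row {r}, column {c}")
    if not np.allclose(values, np.round(values)):
        r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(f"{path}: non-integer count at row {r}, column {c}")


def read_count_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a counts matrix from a ``.mtx`` triplet or a TSV.

    MTX expects sidecars ``<stem>.rows.txt`` / ``<stem>.cols.txt`` next to
    the matrix. TSV expects a header row and the row names in the first
    column. Returns (dense int array, row names, column names).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        _check_counts(mat, path)
        rows = Path(str(path)[: -len(".mtx")] + ".rows.txt")
        cols = Path(str(path)[: -len(".mtx")] + ".cols.txt")
        row_names = rows.read_text().splitlines()
        col_names = cols.read_text().splitlines()
        if len(row_names) != mat.shape[0] or len(col_names) != mat.shape[1]:
            raise ValueError(f"{path}: sidecar name counts do not match matrix shape")
        return mat.astype(np.int64), row_names, col_names
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_counts(df.to_numpy(dtype=float), path)
    return (
        df.to_numpy(dtype=np.int64),
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
    )


def write_count_matrix(
    matrix: np.ndarray,
    row_names: list[str],
    col_names: list[str],
    path: str | Path,
) -> None:
    """Write counts as MTX (+ name sidecars) or TSV, by extension."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(np.asarray(matrix)))
        Path(str(path)[: -len(".mtx")] + ".rows.txt").write_text(
            "\n".join(row_names) + "\n"
        )
        Path(str(path)[: -len(".mtx")] + ".cols.txt").write_text(
            "\n".join(col_names) + "\n"
        )
    else:
        pd.DataFrame(matrix, index=row_names, columns=col_names).to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
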