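"""Interval engine: BED reading, merging, region classification and
nearest-gene assignment, cross-checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from tissuespec.intervals import (
    GeneAnnotation,
    GeneModel,
    GenomicInterval,
    PeakSet,
    classify_peakset,
    classify_region,
    merge_overlapping,
    nearest_gene,
)
from tissuespec.io import read_peaks, write_peaks


def make_peakset(triples, provenance="test"):
    df = pd.DataFrame(
        [(c, s, e, f"{c}:{s}-{e}") for c, s, e in triples],
        columns=["chrom", "start", "end", "id"],
    )
    return PeakSet(df, provenance=provenance)


def simple_gene(gene_id="gA", chrom="chr1", strand="+", start=10_000, end=20_000):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        gene_start=start, gene_end=end,
        exons=[(start, start + 500), (end - 500, end)],
    )


@pytest.fixture
def two_gene_ann():
    g1 = simple_gene("gA", start=10_000, end=20_000)
    g2 = simple_gene("gB", start=50_000, end=60_000, strand="-")
    return GeneAnnotation(genes=[g1, g2], chrom_sizes={"chr1": 100_000})


class TestReadPeaks:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t300\n")
        ps = read_peaks(p)
        assert len(ps) == 1
        iv = next(iter(ps))
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 100, 300)

    def test_inverted_coordinates_rejected_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t300\t100\n")
        with pytest.raises(ValueError, match="line 1"):
            read_peaks(p)

    def test_overlapping_records_preserved(self, tmp_path):
        recs = [("chr1", 100, 300), ("chr1", 150, 350), ("chr1", 200, 400)]
        p = tmp_path / "c.bed"
        p.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in recs))
        ps = read_peaks(p)
        assert len(ps) == 3  # no auto-merge
        out = tmp_path / "out.bed"
        write_peaks(ps, out)
        assert read_peaks(out).df[["chrom", "start", "end"]].equals(
            ps.df[["chrom", "start", "end"]]
        )

    def test_name_column_used(self, tmp_path):
        p = tmp_path / "d.bed"
        p.write_text("chr1\t5\t10\tpk1\n")
        assert read_peaks(p).ids == ["pk1"]


class TestMergeOverlapping:
    def test_transitive_union(self):
        a = make_peakset([("chr1", 100, 300)])
        b = make_peakset([("chr1", 250, 400)])
        merged = merge_overlapping([a, b])
        assert len(merged) == 1
        row = merged.df.iloc[0]
        assert (row.start, row.end) == (100, 400)
        assert all(len(s) == 1 for s in row.sources)

    def test_disjoint_stay_separate(self):
        ps = make_peakset([("chr1", 100, 200), ("chr1", 300, 400)])
        merged = merge_overlapping([ps])
        assert len(merged) == 2

    def test_chain_collapses_to_one(self):
        ps = make_peakset([("chr1", i * 50, i * 50 + 80) for i in range(5)])
        merged = merge_overlapping([ps])
        assert len(merged) == 1
        assert (merged.df.iloc[0].start, merged.df.iloc[0].end) == (0, 280)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_overlapping([])

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 5000, 60)
        ps = make_peakset([("chr1", int(s), int(s) + int(w))
                           for s, w in zip(starts, rng.integers(50, 400, 60))])
        once = merge_overlapping([ps])
        twice = merge_overlapping([PeakSet(once.df[["chrom", "start", "end", "id"]])])
        assert once.df[["chrom", "start", "end"]].equals(
            twice.df[["chrom", "start", "end"]]
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_union_find_oracle(self, seed):
        """Random fixtures against an O(n^2) union-find on the overlap graph."""
        rng = np.random.default_rng(seed)
        n = 120
        chroms = rng.choice(["chr1", "chr2"], n)
        starts = rng.integers(0, 4000, n)
        widths = rng.integers(1, 300, n)
        rows = [(c, int(s), int(s + w), f"p{i}")
                for i, (c, s, w) in enumerate(zip(chroms, starts, widths))]
        ps = PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "id"]))
        merged = merge_overlapping([ps])

        # oracle: union-find over all pairwise >=1bp overlaps
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                ci, si, ei, _ = rows[i]
                cj, sj, ej, _ = rows[j]
                if ci == cj and si < ej and sj < ei:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        expected = sorted(
            (rows[m[0]][0], min(rows[i][1] for i in m), max(rows[i][2] for i in m))
            for m in comps.values()
        )
        got = sorted(
            (r.chrom, int(r.start), int(r.end))
            for r in merged.df.itertuples(index=False)
        )
        assert got == expected


class TestClassifyRegion:
    def test_peak_over_tss_is_promoter(self, two_gene_ann):
        assert classify_region(GenomicInterval("chr1", 9_950, 10_050), two_gene_ann) == "promoter"

    def test_intronic_peak_is_intragenic(self, two_gene_ann):
        # inside gA span, past the promoter window, between exons
        assert classify_region(GenomicInterval("chr1", 15_000, 15_200), two_gene_ann) == "intragenic"

    def test_distal_peak_is_intergenic(self, two_gene_ann):
        assert classify_region(GenomicInterval("chr1", 80_000, 80_200), two_gene_ann) == "intergenic"

    def test_unknown_chromosome_rejected(self, two_gene_ann):
        with pytest.raises(ValueError):
            classify_region(GenomicInterval("chrX", 0, 10), two_gene_ann)

    def test_minus_strand_promoter_is_downstream_of_end(self, two_gene_ann):
        # gB is minus strand with TSS at 59_999
        assert classify_region(GenomicInterval("chr1", 60_200, 60_400), two_gene_ann) == "promoter"

    def test_partition_sums(self, two_gene_ann):
        rng = np.random.default_rng(0)
        peaks = make_peakset(
            [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 99_800, 200)]
        )
        table = classify_peakset(peaks, two_gene_ann)
        counts = table["region_class"].value_counts()
        assert counts.sum() == len(peaks)
        assert set(counts.index) <= {"promoter", "intragenic", "intergenic"}


class TestNearestGene:
    def test_midpoint_at_tss(self, two_gene_ann):
        gid, d = nearest_gene(GenomicInterval("chr1", 9_900, 10_100), two_gene_ann)
        assert (gid, d) == ("gA", 0)

    def test_equidistant_tie_breaks_lexicographically(self):
        g1 = simple_gene("gB", start=10_000, end=20_000)
        g2 = simple_gene("gA", start=30_000, end=40_000)
        ann = GeneAnnotation(genes=[g1, g2], chrom_sizes={"chr1": 100_000})
        # midpoint 20_000 is 10_000 from both TSSs
        gid, _ = nearest_gene(GenomicInterval("chr1", 19_900, 20_100), ann)
        assert gid == "gA"

    def test_signed_distance_strand_oriented(self, two_gene_ann):
        # 1 kb downstream of gB's TSS (minus strand at 59_999)
        gid, d = nearest_gene(GenomicInterval("chr1", 58_900, 59_100), two_gene_ann)
        assert gid == "gB"
        assert d == 59_999 - 59_000  # downstream positive in gene orientation

    def test_no_gene_on_chromosome_unassigned(self):
        ann = GeneAnnotation(
            genes=[simple_gene()], chrom_sizes={"chr1": 100_000, "chr2": 50_000}
        )
        gid, d = nearest_gene(GenomicInterval("chr2", 10, 20), ann)
        assert gid is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan(self, seed):
        """Random peak fixtures: assignment equals exhaustive min-distance
        scan with lexicographic ties, classification equals naive overlap."""
        rng = np.random.default_rng(100 + seed)
        genes = []
        used = set()
        for i in range(25):
            start = int(rng.integers(0, 180) * 1000)
            if start in used:
                continue
            used.add(start)
            genes.append(simple_gene(
                f"g{i:02d}", start=start, end=start + 800,
                strand="+" if rng.random() < 0.5 else "-",
            ))
        ann = GeneAnnotation(genes=genes, chrom_sizes={"chr1": 200_000})
        peaks = make_peakset(
            [("chr1", int(s), int(s) + int(w))
             for s, w in zip(rng.integers(0, 199_000, 500), rng.integers(1, 900, 500))]
        )
        table = classify_peakset(peaks, ann)
        for iv in peaks:
            mid = iv.midpoint
            best = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
            assert table.loc[iv.id, "gene_id"] == best.gene_id
            prom = any(
                iv.start < g.promoter_window()[1] and g.promoter_window()[0] < iv.end
                for g in genes
            )
            intra = any(iv.start < g.gene_end and g.gene_start < iv.end for g in genes)
            expected = "promoter" if prom else ("intragenic" if intra else "intergenic")
            assert table.loc[iv.id, "region_class"] == expected


class TestInvariants:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            [("chr1", 0, 10, "a"), ("chr1", 20, 30, "a")],
            columns=["chrom", "start", "end", "id"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            PeakSet(df)
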