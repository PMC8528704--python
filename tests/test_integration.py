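"""ATAC-RNA integration: fold conventions, the two-intestine averaging
identity, the 1.2-fold gene gate, and quadrant concordance."""

import numpy as np
import pandas as pd
import pytest

import tissuespec as ts
from tissuespec.integration import accessibility_fold_table

from conftest import make_adata


def make_assignments(entries):
    """entries: (peak_id, gene, class)"""
    return pd.DataFrame(
        [(p, g, c) for p, g, c in entries],
        columns=["id", "gene_id", "region_class"],
    ).set_index("id")


class TestOneVsAll:
    def test_two_identical_tissues_null(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(80, 30))
        adata = make_adata(counts, tissues=["A"] * 40 + ["B"] * 40)
        res = ts.one_vs_all_log2fc(adata, "A")
        assert np.abs(res["log2fc"]).max() < 0.6
        assert (res["q"] > 0.05).mean() > 0.9

    def test_equals_pairwise_with_pooled_rest(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(90, 10))
        adata = make_adata(counts, tissues=["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        ova = ts.one_vs_all_log2fc(adata, "A")
        mask = (adata.obs["tissue"] == "A").to_numpy()
        direct = ts.wilcoxon_de(adata, mask, ~mask, min_pct=0.1, logfc_min=0.0)
        pd.testing.assert_frame_equal(ova, direct)

    def test_planted_fold_magnitude(self, default_sim):
        adata = default_sim["adata"]
        params = default_sim["params"]
        truth = default_sim["truth"]
        qcd, _ = ts.standard_qc(adata, marker_panels=params.contaminant_panels, seed=0)
        res = ts.one_vs_all_log2fc(qcd, "BM")
        planted = [g for g in truth.ts_genes("BM") if g in res.index]
        med = res.loc[planted, "log2fc"].median()
        assert 1.0 < med < 2.5  # 4-fold against a pooled background


class TestAvgAccessibility:
    def test_mean_of_two_peaks(self):
        asg = make_assignments([("p1", "g", "intragenic"), ("p2", "g", "intragenic")])
        da = pd.Series({"p1": 2.0, "p2": 0.0})
        assert ts.avg_accessibility_log2fc(da, asg, "g", "intragenic") == 1.0

    def test_absent_class_is_none(self):
        asg = make_assignments([("p1", "g", "promoter")])
        da = pd.Series({"p1": 2.0})
        assert ts.avg_accessibility_log2fc(da, asg, "g", "intergenic") is None

    def test_table_matches_brute_force(self):
        rng = np.random.default_rng(2)
        entries = []
        k = 0
        genes = [f"g{i}" for i in range(30)]
        for g in genes:
            for cls in ("promoter", "intragenic", "intergenic"):
                for _ in range(rng.integers(0, 3)):
                    entries.append((f"p{k}", g, cls))
                    k += 1
        asg = make_assignments(entries)
        da = pd.Series(rng.normal(size=k), index=[f"p{i}" for i in range(k)])
        table = accessibility_fold_table(da, asg)
        for g in table.index:
            for cls in ("promoter", "intragenic", "intergenic"):
                peaks = [p for p, gg, cc in entries if gg == g and cc == cls]
                expected = da.loc[peaks].mean() if peaks else np.nan
                got = table.loc[g, f"acc_log2fc_{cls}"]
                if peaks:
                    assert got == pytest.approx(expected)
                    assert table.loc[g, f"n_peaks_{cls}"] == len(peaks)
                else:
                    assert np.isnan(got)

    def test_permutation_invariant_in_peak_order(self):
        asg = make_assignments(
            [("p1", "g", "intergenic"), ("p2", "g", "intergenic"),
             ("p3", "g", "intergenic")]
        )
        da = pd.Series({"p1": 1.0, "p2": 2.0, "p3": 6.0})
        a = ts.avg_accessibility_log2fc(da, asg, "g", "intergenic")
        asg2 = asg.iloc[[2, 0, 1]]
        b = ts.avg_accessibility_log2fc(da, asg2, "g", "intergenic")
        assert a == b


class TestSharedIntestinalFold:
    def pack(self, li, si):
        others = ("BM", "Lung", "Pancreas")
        folds = {}
        for i, o in enumerate(others):
            folds[("LI", o)] = pd.Series(li[i])
            folds[("SI", o)] = pd.Series(si[i])
        return folds

    def test_constant_inputs(self):
        folds = self.pack([[2.0]] * 3, [[2.0]] * 3)
        assert ts.shared_intestinal_log2fc(folds).iloc[0] == pytest.approx(2.0)

    def test_asymmetric_arithmetic(self):
        folds = self.pack([[3.0]] * 3, [[1.0]] * 3)
        assert ts.shared_intestinal_log2fc(folds).iloc[0] == pytest.approx(2.0)

    def test_missing_pair_rejected(self):
        folds = self.pack([[1.0]] * 3, [[1.0]] * 3)
        del folds[("SI", "Lung")]
        with pytest.raises(KeyError):
            ts.shared_intestinal_log2fc(folds)

    def test_equals_mean_of_six_on_random_draws(self):
        """Algebraic identity: the divide-by-3-then-by-2 rule is the
        unweighted mean of the six pairwise folds (1000 random draws)."""
        rng = np.random.default_rng(3)
        draws = rng.normal(scale=3.0, size=(1000, 6))
        folds = self.pack(
            [draws[:, 0], draws[:, 1], draws[:, 2]],
            [draws[:, 3], draws[:, 4], draws[:, 5]],
        )
        got = ts.shared_intestinal_log2fc(folds)
        assert np.allclose(got.to_numpy(), draws.mean(axis=1), atol=1e-12)


class TestIntegrationTable:
    def make_expr(self):
        return pd.DataFrame(
            {
                "log2fc": [np.log2(1.1), np.log2(1.3), np.log2(1.3), -np.log2(1.5)],
                "q": [1e-4, 0.2, 1e-4, 1e-4],
            },
            index=["small_fold", "not_sig", "ok_up", "ok_down"],
        )

    def make_acc(self):
        idx = ["small_fold", "not_sig", "ok_up", "ok_down"]
        return pd.DataFrame(
            {
                "acc_log2fc_promoter": [0.1, 0.1, 0.5, -0.5],
                "n_peaks_promoter": [1, 1, 1, 1],
                "acc_log2fc_intragenic": [np.nan] * 4,
                "n_peaks_intragenic": [0] * 4,
                "acc_log2fc_intergenic": [0.2, 0.2, 1.0, -1.0],
                "n_peaks_intergenic": [2, 2, 2, 2],
            },
            index=idx,
        )

    def test_fold_and_significance_gates(self):
        rows = ts.build_integration_table(self.make_expr(), self.make_acc())
        assert set(rows.index) == {"ok_up", "ok_down"}

    def test_concordance_counts(self):
        rows = ts.build_integration_table(self.make_expr(), self.make_acc())
        summary = ts.concordance_and_correlation(rows)
        assert summary["intragenic"]["n_genes"] == 0
        assert summary["intergenic"]["n_genes"] == 2
        assert summary["intergenic"]["n_upper_right"] == 1
        assert summary["intergenic"]["n_lower_left"] == 1
        assert summary["intergenic"]["concordant_fraction"] == 1.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(4)
        rows = pd.DataFrame(
            {
                "mrna_log2fc": rng.normal(size=30),
                "acc_log2fc_promoter": rng.normal(size=30),
                "acc_log2fc_intragenic": rng.normal(size=30),
                "acc_log2fc_intergenic": rng.normal(size=30),
            }
        )
        a = ts.concordance_and_correlation(rows)
        b = ts.concordance_and_correlation(-rows)
        for cls in a:
            assert a[cls]["concordant_fraction"] == pytest.approx(
                b[cls]["concordant_fraction"]
            )

    def test_antisymmetric_fixture_discordant(self):
        rows = pd.DataFrame(
            {
                "mrna_log2fc": [1.0, 2.0, -1.0, -2.0],
                "acc_log2fc_promoter": [-1.0, -2.0, 1.0, 2.0],
                "acc_log2fc_intragenic": [np.nan] * 4,
                "acc_log2fc_intergenic": [np.nan] * 4,
            }
        )
        s = ts.concordance_and_correlation(rows)["promoter"]
        assert s["concordant_fraction"] == 0.0
        assert s["pearson_r"] < 0


class TestPlantedCouplingDirectionality:
    def test_non_promoter_classes_correlate_promoter_does_not(self, default_sim):
        """With coupling routed only through non-promoter peaks, the
        integrated scatter correlates for intragenic/intergenic classes
        and stays flat for promoters."""
        adata = default_sim["adata"]
        params = default_sim["params"]
        qcd, _ = ts.standard_qc(adata, marker_panels=params.contaminant_panels, seed=0)
        atlas, presence, _ = ts.build_atlas(default_sim["replicates"])
        qpcm, _ = ts.quantify_atlas(default_sim["pcm"], atlas)
        rows, summary = ts.run_integration(qcd, qpcm, default_sim["ann"])
        assert summary["intragenic"]["pearson_r"] >= 0.4
        assert summary["intergenic"]["pearson_r"] >= 0.4
        assert abs(summary["promoter"]["pearson_r"]) <= 0.15
        assert summary["intragenic"]["concordant_fraction"] > 0.5
        assert summary["intergenic"]["concordant_fraction"] > 0.5
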