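"""Statistical contracts of the NB differential-expression engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippolink import de, synth
from hippolink.io import CountMatrix
from tests.conftest import null_truth


def _cm(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm(np.tile([[10], [20], [30]], (1, 4)))
        assert np.allclose(de.size_factors(cm), 1.0)

    def test_doubled_column_doubles_factor(self):
        # direct evaluation of the median-of-ratios formula
        base = np.array([[10, 20], [40, 80], [7, 14], [100, 200]])
        cm = _cm(base)
        sf = de.size_factors(cm)
        assert np.isclose(sf.iloc[1] / sf.iloc[0], 2.0)

    def test_single_sample_convention(self):
        cm = _cm([[5], [9]])
        assert de.size_factors(cm).iloc[0] == 1.0

    def test_no_common_positive_gene_raises_then_fallback(self):
        cm = _cm([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo"):
            de.size_factors(cm)
        sf = de.size_factors(cm, allow_pseudo_reference=True)
        assert (sf > 0).all()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 200, size=(50, 4))
        scaled = base.copy()
        scaled[:, 2] *= 3
        r1 = de.size_factors(_cm(base))
        r2 = de.size_factors(_cm(scaled))
        # factors are defined up to a common scale: compare relative to s0
        assert np.isclose((r2.iloc[2] / r2.iloc[0]) / (r1.iloc[2] / r1.iloc[0]), 3.0)


class TestVST:
    def test_fixed_points(self):
        cm = _cm([[0, 3]])
        # factor-1 transform: 0 -> 0, 3 -> log2(4) = 2
        out = de.vst_transform(cm, pd.Series([1.0, 1.0], index=["s0", "s1"]))
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == 2.0

    def test_monotone_in_counts(self):
        counts = np.arange(0, 1001)
        cm = _cm(counts[None, :], samples=[f"s{i}" for i in range(1001)])
        out = de.vst_transform(cm, pd.Series(1.0, index=cm.sample_ids)).to_numpy()[0]
        assert np.all(np.diff(out) > 0)  # strictly monotone, brute-force scan


class TestDispersion:
    def test_poisson_data_gives_near_zero(self):
        design = synth.DesignSpec(
            replicate_map={("germ", "mid", "control"): 10, ("germ", "mid", "hpo_RNAi"): 10},
            n_genes=500,
        )
        cm, meta, _ = synth.make_counts(design, null_truth(500, dispersion=0.0), seed=2)
        disp = de.estimate_dispersion(cm, meta)
        assert np.median(disp) < 0.01

    def test_constant_gene_gets_zero(self):
        cm = _cm([[7, 7, 7, 7], [1, 2, 3, 4]])
        meta = pd.DataFrame(
            {"cell_type": "germ", "stage": "mid", "genotype": "control", "replicate": range(4)},
            index=cm.sample_ids,
        )
        disp = de.estimate_dispersion(
            cm, meta, factors=pd.Series(1.0, index=cm.sample_ids), trend_weight=0.0
        )
        assert disp.iloc[0] == 0.0

    def test_planted_dispersion_recovered(self):
        design = synth.DesignSpec(
            replicate_map={("germ", "mid", "control"): 10, ("germ", "mid", "hpo_RNAi"): 10},
            n_genes=500,
        )
        cm, meta, _ = synth.make_counts(design, null_truth(500, dispersion=0.2), seed=7)
        disp = de.estimate_dispersion(cm, meta)
        assert 0.1 <= np.median(disp) <= 0.3

    def test_unreplicated_design_falls_back(self, caplog):
        cm = _cm([[10, 20], [5, 8]])
        meta = pd.DataFrame(
            {
                "cell_type": "germ", "stage": "mid",
                "genotype": ["control", "hpo_RNAi"], "replicate": 1,
            },
            index=cm.sample_ids,
        )
        with caplog.at_level("WARNING", logger="hippolink"):
            disp = de.estimate_dispersion(cm, meta)
        assert (disp == 0.1).all()
        assert any("falling back" in r.message for r in caplog.records)


class TestBH:
    def test_step_up_worked_example(self):
        out = de.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert de.bh_adjust(np.array([0.3]))[0] == 0.3

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        ours = de.bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)

    def test_nan_passthrough_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.04])
        out = de.bh_adjust(p)
        assert np.isnan(out[1])
        # m = 2, not 3
        assert np.isclose(out[0], 0.02)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_bh_dominates_raw_p_and_capped(self, pvals):
        p = np.array(pvals)
        out = de.bh_adjust(p)
        assert np.all(out >= p - 1e-12)
        assert np.all(out <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust(np.array([1.5]))


class TestWaldDE:
    @pytest.fixture(scope="class")
    def planted(self, two_group_design):
        truth = null_truth(2000)
        truth.loc[truth.index[:300], "germ_hpo"] = 2.0
        cm, meta, _ = synth.make_counts(two_group_design, truth, seed=43)
        res = de.wald_de(cm, meta, ("genotype", "hpo_RNAi", "control"), alpha=0.05)
        return truth, cm, meta, res

    def test_planted_effect_recovered_in_mean(self, planted):
        truth, _, _, res = planted
        est = res.table.loc[truth.index[:300], "log2FC"]
        assert abs(est.mean() - 2.0) < 0.3

    def test_type_i_error_controlled(self, two_group_design):
        cm, meta, _ = synth.make_counts(two_group_design, null_truth(2000), seed=42)
        res = de.wald_de(cm, meta, ("genotype", "hpo_RNAi", "control"), alpha=0.05)
        tab = res.table.dropna(subset=["padj"])
        assert (tab["padj"] < 0.05).mean() <= 0.05

    def test_contrast_antisymmetry(self, planted):
        _, cm, meta, res = planted
        flipped = de.wald_de(cm, meta, ("genotype", "control", "hpo_RNAi"), alpha=0.05)
        ok = res.table["pvalue"].notna()
        assert np.allclose(
            res.table.loc[ok, "log2FC"], -flipped.table.loc[ok, "log2FC"], atol=1e-6
        )
        assert np.allclose(
            res.table.loc[ok, "pvalue"], flipped.table.loc[ok, "pvalue"], atol=1e-10
        )

    def test_padj_monotone_with_p(self, planted):
        *_, res = planted
        tab = res.table.dropna(subset=["pvalue"])
        by_p = tab.sort_values("pvalue", kind="mergesort").index
        by_padj = tab.sort_values(["padj", "pvalue"], kind="mergesort").index
        assert list(by_p) == list(by_padj)

    def test_strong_knockdown_detected_like_hpo_self_target(self):
        """A gene planted at log2FC=-4.1 under knockdown is found significant
        with an estimate within +/-1 of truth."""
        design = synth.DesignSpec(
            replicate_map={("germ", "mid", "control"): 3, ("germ", "mid", "hpo_RNAi"): 3},
            n_genes=500,
        )
        truth = null_truth(500)
        truth.iloc[0, truth.columns.get_loc("germ_hpo")] = -4.1
        cm, meta, _ = synth.make_counts(design, truth, seed=17)
        res = de.wald_de(cm, meta, ("genotype", "hpo_RNAi", "control"), alpha=0.05)
        row = res.table.iloc[0]
        assert -5.1 < row["log2FC"] < -3.1
        assert row["padj"] < 0.05

    def test_null_single_gene_large_groups(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(200, size=(1, 20))
        cm = _cm(y, samples=[f"s{i}" for i in range(20)])
        meta = pd.DataFrame(
            {
                "cell_type": "germ", "stage": "mid",
                "genotype": ["control"] * 10 + ["hpo_RNAi"] * 10,
                "replicate": list(range(10)) * 2,
            },
            index=cm.sample_ids,
        )
        res = de.wald_de(cm, meta, ("genotype", "hpo_RNAi", "control"))
        assert abs(res.table.iloc[0]["log2FC"]) < 0.2
        assert res.table.iloc[0]["pvalue"] > 0.5

    def test_all_zero_gene_gets_nan_and_is_excluded_from_bh(self):
        y = np.array([[0, 0, 0, 0, 0, 0], [10, 12, 9, 30, 33, 28]])
        cm = _cm(y, samples=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame(
            {
                "cell_type": "germ", "stage": "mid",
                "genotype": ["control"] * 3 + ["hpo_RNAi"] * 3,
                "replicate": [1, 2, 3] * 2,
            },
            index=cm.sample_ids,
        )
        res = de.wald_de(cm, meta, ("genotype", "hpo_RNAi", "control"))
        assert np.isnan(res.table.iloc[0]["pvalue"])
        # m = 1 for BH, so padj equals p for the expressed gene
        assert res.table.iloc[1]["padj"] == res.table.iloc[1]["pvalue"]

    def test_confounded_design_rejected(self):
        cm = _cm([[5, 6, 7, 8]])
        meta = pd.DataFrame(
            {
                "cell_type": "germ",
                "stage": ["mid", "mid", "late", "late"],
                "genotype": ["control", "control", "hpo_RNAi", "hpo_RNAi"],
                "replicate": [1, 2, 1, 2],
            },
            index=cm.sample_ids,
        )
        with pytest.raises(ValueError, match="full rank|confounded"):
            de.wald_de(cm, meta, ("genotype", "hpo_RNAi", "control"), covariates=["stage"])

    def test_agrees_with_pydeseq2_on_strong_effects(self):
        """Independent cross-check: genes called strongly DE by an external
        NB engine overlap ours, and fold-change estimates correlate."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        design = synth.DesignSpec(
            replicate_map={("germ", "mid", "control"): 4, ("germ", "mid", "hpo_RNAi"): 4},
            n_genes=300,
        )
        truth = null_truth(300)
        truth.loc[truth.index[:40], "germ_hpo"] = 2.5
        truth.loc[truth.index[40:80], "germ_hpo"] = -2.5
        cm, meta, _ = synth.make_counts(design, truth, seed=99)
        ours = de.wald_de(cm, meta, ("genotype", "hpo_RNAi", "control"))

        dds = DeseqDataSet(
            counts=cm.data.T,
            metadata=meta.assign(condition=meta["genotype"]),
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "hpo_RNAi", "control"], quiet=True)
        stat.summary()
        ref = stat.results_df

        planted = truth.index[:80]
        r = np.corrcoef(
            ours.table.loc[planted, "log2FC"], ref.loc[planted, "log2FoldChange"]
        )[0, 1]
        assert r > 0.98
        ref_sig = set(ref.index[(ref.padj < 0.01).fillna(False) & (ref.log2FoldChange.abs() > 1)])
        our_sig = set(ours.table.index[ours.table.significant])
        assert len(ref_sig & our_sig) / max(len(ref_sig), 1) > 0.9


class TestOutlierControls:
    def _fixture(self, values):
        n = len(values)
        cm = _cm(
            np.vstack([values, np.full(n, 50)]),
            genes=["yki", "other"],
            samples=[f"s{i}" for i in range(n)],
        )
        meta = pd.DataFrame(
            {
                "cell_type": "germ",
                "stage": ["early", "mid", "late"] * (n // 3),
                "genotype": "control",
                "replicate": 1,
            },
            index=cm.sample_ids,
        )
        return cm, meta

    def test_planted_suppression_flagged_exactly(self):
        # construction with known MAD: 8 peers near 100, one at 10
        cm, meta = self._fixture([100, 102, 98, 101, 99, 103, 97, 100, 10])
        flagged = de.flag_outlier_controls(
            cm, meta, "yki", k=3.0, factors=pd.Series(1.0, index=cm.sample_ids)
        )
        assert flagged == ["s8"]

    def test_homogeneous_controls_unflagged(self):
        cm, meta = self._fixture([100] * 9)
        assert de.flag_outlier_controls(
            cm, meta, "yki", factors=pd.Series(1.0, index=cm.sample_ids)
        ) == []

    def test_infinite_k_never_flags(self):
        cm, meta = self._fixture([100, 102, 98, 101, 99, 103, 97, 100, 10])
        assert de.flag_outlier_controls(
            cm, meta, "yki", k=np.inf, factors=pd.Series(1.0, index=cm.sample_ids)
        ) == []

    def test_too_few_peers_warns_and_skips(self, caplog):
        cm, meta = self._fixture([100, 10, 100])
        meta = meta.iloc[:2]
        cm = cm.subset_samples(meta.index)
        with caplog.at_level("WARNING", logger="hippolink"):
            flagged = de.flag_outlier_controls(
                cm, meta, "yki", factors=pd.Series(1.0, index=cm.sample_ids)
            )
        assert flagged == []
        assert any("skipped" in r.message for r in caplog.records)

    def test_simulated_planted_outlier_recovered(self, default_simulation):
        counts, meta, truth = default_simulation
        flagged = de.flag_outlier_controls(counts, meta, "yki", k=3.0)
        assert truth.attrs["outlier_sample"] in flagged
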