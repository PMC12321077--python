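"""Instrument selection, Wald ratios, FDR and per-pair deduplication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sescore.config import RunConfig
from sescore.io import FrameGwasStore
from sescore.mr import (
    bh_fdr,
    dedupe_pair_results,
    f_statistic,
    screen,
    select_instruments,
    wald_ratio,
)

from .oracles import naive_bh, naive_dedupe


def _eqtl(rows):
    df = pd.DataFrame(
        rows,
        columns=["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n",
                 "gene", "tissue"],
    )
    return df


class TestSelectInstruments:
    GENE = ("1", 1_000_000, 1_050_000)

    def test_smallest_p_wins(self):
        eqtl = _eqtl(
            [
                ["rs1", "1", 1_000_100, "A", "G", 0.3, 0.3, 0.01, 1e-8, 100, "G1", "cortex"],
                ["rs2", "1", 1_000_200, "A", "G", 0.3, 0.1, 0.01, 1e-5, 100, "G1", "cortex"],
                ["rs3", "1", 1_000_300, "A", "G", 0.3, 0.02, 0.01, 0.2, 100, "G1", "cortex"],
            ]
        )
        inst = select_instruments(eqtl, "G1", self.GENE)
        assert list(inst["snp"]) == ["rs1"]

    def test_five_tissues_sharing_top_snp_keep_five_instruments(self):
        tissues = ["basal_ganglia", "cerebellum", "cortex", "hippocampus", "spinal_cord"]
        rows = [
            ["rs1", "1", 1_000_100, "A", "G", 0.3, 0.3, 0.01, 1e-8, 100, "G1", t]
            for t in tissues
        ]
        inst = select_instruments(_eqtl(rows), "G1", self.GENE)
        assert len(inst) == 5
        assert inst["snp"].nunique() == 1

    def test_cis_window_boundary(self):
        inside = 1_050_000 + 1_000_000  # gene end + window, still cis
        outside = inside + 1
        rows = [
            ["rs_in", "1", inside, "A", "G", 0.3, 0.3, 0.01, 1e-8, 100, "G1", "cortex"],
            ["rs_out", "1", outside, "A", "G", 0.3, 0.5, 0.01, 1e-10, 100, "G1", "cortex"],
        ]
        inst = select_instruments(_eqtl(rows), "G1", self.GENE)
        assert list(inst["snp"]) == ["rs_in"]

    def test_other_chromosome_is_trans(self):
        rows = [["rs1", "2", 1_000_100, "A", "G", 0.3, 0.3, 0.01, 1e-8, 100, "G1", "cortex"]]
        assert select_instruments(_eqtl(rows), "G1", self.GENE).empty

    def test_no_cis_association_gives_empty(self):
        assert select_instruments(_eqtl([]), "G1", self.GENE).empty


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expected,weak",
        [(0.1, 0.01, 100.0, False), (0.01, 0.01, 1.0, True), (0.0, 0.05, 0.0, True)],
    )
    def test_hand_values_and_weak_flag(self, beta, se, expected, weak):
        f = f_statistic(beta, se)
        assert f == pytest.approx(expected, abs=1e-12)
        assert (f <= RunConfig().f_min) is weak


class TestWaldRatio:
    def test_hand_evaluation(self):
        beta_iv, se_iv, _ = wald_ratio(0.2, 0.05, 0.1, 0.01)
        assert beta_iv == pytest.approx(2.0)
        assert se_iv == pytest.approx(0.5)

    def test_null_outcome(self):
        beta_iv, _, pval = wald_ratio(0.0, 0.05, 0.1, 0.01)
        assert beta_iv == 0.0
        assert pval == 1.0

    def test_sign_symmetry(self):
        beta_iv, _, _ = wald_ratio(-0.3, 0.1, 0.15, 0.01)
        assert beta_iv == pytest.approx(-2.0)

    def test_zero_exposure_effect_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            wald_ratio(0.2, 0.05, 0.0, 0.01)

    def test_second_order_se_is_larger(self):
        _, se1, _ = wald_ratio(0.2, 0.05, 0.1, 0.02)
        _, se2, _ = wald_ratio(0.2, 0.05, 0.1, 0.02, second_order=True)
        assert se2 > se1

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(-1, 1).filter(lambda x: abs(x) > 1e-3),
        st.floats(0.001, 1),
        st.floats(-1, 1).filter(lambda x: abs(x) > 1e-3),
        st.floats(0.1, 10),
    )
    def test_homogeneity_in_outcome_scale(self, beta_zy, se_zy, beta_zx, k):
        b1, s1, _ = wald_ratio(beta_zy, se_zy, beta_zx, 0.01)
        b2, s2, _ = wald_ratio(k * beta_zy, k * se_zy, beta_zx, 0.01)
        assert b2 == pytest.approx(k * b1, rel=1e-9)
        assert s2 == pytest.approx(k * s1, rel=1e-9)


class TestBhFdr:
    def test_single_test_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_against_quadratic_oracle_200_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            p = rng.uniform(1e-12, 1, size=n)
            np.testing.assert_allclose(bh_fdr(p), naive_bh(list(p)), atol=1e-12)

    def test_qvals_dominate_pvals_and_are_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1, size=200)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])


def _screen_setup():
    """Two instruments x three phenotypes, all records present."""
    inst = pd.DataFrame(
        {
            "snp": ["rs1", "rs2"],
            "chr": ["1", "1"],
            "pos": [100, 200],
            "ea": ["A", "C"],
            "oa": ["G", "T"],
            "eaf": [0.3, 0.3],
            "beta": [0.3, 0.25],
            "se": [0.01, 0.01],
            "pval": [1e-10, 1e-10],
            "n": [1e4, 1e4],
            "gene": ["G1", "G2"],
            "tissue": ["cortex", "cortex"],
            "f_stat": [900.0, 625.0],
        }
    )
    gwas = pd.DataFrame(
        {
            "snp": ["rs1", "rs2"],
            "chr": ["1", "1"],
            "pos": [100, 200],
            "ea": ["A", "C"],
            "oa": ["G", "T"],
            "eaf": [0.3, 0.3],
            "beta": [0.15, 0.0],
            "se": [0.02, 0.02],
            "pval": [1e-5, 1.0],
            "n": [1e4, 1e4],
        }
    )
    store = FrameGwasStore({"ph1": gwas, "ph2": gwas, "ph3": gwas})
    semap = pd.DataFrame(
        {
            "side_effect": ["se1", "se2", "se3"],
            "phenotype_id": ["ph1", "ph2", "ph3"],
            "brain_relevant": [True, True, True],
        }
    )
    return inst, store, semap


class TestScreen:
    def test_cardinality_two_by_three(self):
        inst, store, semap = _screen_setup()
        res = screen(inst, store, semap)
        assert len(res) == 6
        assert res.attrs["n_skipped"] == 0

    def test_missing_phenotype_skipped_and_counted(self):
        inst, store, semap = _screen_setup()
        store._frames.pop("ph3")
        res = screen(inst, store, semap)
        assert len(res) == 4
        assert res.attrs["n_skipped"] == 2
        assert len(res) + res.attrs["n_skipped"] == len(inst) * len(semap)

    def test_swapped_outcome_alleles_sign_corrected(self):
        inst, store, semap = _screen_setup()
        gwas = store.get("ph1").copy()
        gwas.loc[0, ["ea", "oa"]] = ["G", "A"]  # swapped, same information
        gwas.loc[0, "beta"] = -gwas.loc[0, "beta"]
        store._frames["ph1"] = gwas
        res = screen(inst, store, semap)
        r = res.set_index(["snp", "phenotype_id"])
        assert r.loc[("rs1", "ph1"), "beta_iv"] == pytest.approx(
            r.loc[("rs1", "ph2"), "beta_iv"]
        )


class TestDedupe:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["side_effect", "gene", "phenotype_id", "qval", "f_stat", "snp"]
        )

    def test_smallest_q_kept(self):
        df = self._frame(
            [["se1", "G1", "ph1", 0.001, 100, "rs1"], ["se1", "G1", "ph2", 0.01, 100, "rs2"]]
        )
        out = dedupe_pair_results(df)
        assert list(out["phenotype_id"]) == ["ph1"]

    def test_f_stat_breaks_q_ties(self):
        df = self._frame(
            [["se1", "G1", "ph1", 0.01, 50, "rs1"], ["se1", "G1", "ph2", 0.01, 400, "rs2"]]
        )
        assert list(dedupe_pair_results(df)["f_stat"]) == [400]

    def test_snp_breaks_remaining_ties(self):
        df = self._frame(
            [["se1", "G1", "ph1", 0.01, 50, "rs9"], ["se1", "G1", "ph2", 0.01, 50, "rs2"]]
        )
        assert list(dedupe_pair_results(df)["snp"]) == ["rs2"]

    def test_against_brute_force_group_argmin(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            df = self._frame(
                [
                    [
                        f"se{rng.integers(4)}",
                        f"G{rng.integers(4)}",
                        f"ph{i}",
                        float(rng.choice([0.001, 0.01, 0.04])),
                        float(rng.choice([10, 50, 400])),
                        f"rs{rng.integers(20)}",
                    ]
                    for i in range(n)
                ]
            )
            got = dedupe_pair_results(df)
            want = naive_dedupe(df.to_dict("records"))
            assert len(got) == len(want)
            for g, w in zip(got.to_dict("records"), want):
                assert (g["side_effect"], g["gene"], g["qval"], g["f_stat"], g["snp"]) == (
                    w["side_effect"], w["gene"], w["qval"], w["f_stat"], w["snp"]
                )
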