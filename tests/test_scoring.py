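"""Score terms, entry sums, parametric bootstrap and aggregation."""

import numpy as np
import pandas as pd
import pytest

from sescore.affinity import AffinitySummary
from sescore.config import RunConfig
from sescore.scoring import (
    NonBindingError,
    aggregate,
    bootstrap_replicates,
    bootstrap_se,
    score_side_effect,
    signed_term,
)

from .oracles import naive_aggregate


def _aff(pki=1.0, action="agonist", is_default=False, is_nonbinding=False,
         drug="d", receptor="R"):
    return AffinitySummary(
        drug=drug, receptor=receptor, action=action, pki=pki, pki_se=0.15,
        ki_mean_m=float("nan"), ki_se_m=float("nan"), n_used=3,
        is_default=is_default, is_nonbinding=is_nonbinding,
    )


def _terms_df(rows):
    """Rows: (drug, side_effect, receptor, beta_iv, se_iv, de, direction,
    used_default_pki, ki_mean_m, ki_se_m)."""
    return pd.DataFrame(
        rows,
        columns=["drug", "side_effect", "receptor", "beta_iv", "se_iv", "de",
                 "direction", "used_default_pki", "ki_mean_m", "ki_se_m"],
    )


class TestSignedTerm:
    def test_unit_case(self):
        t = signed_term(1.0, _aff(pki=1.0, action="agonist"), de=1.0)
        assert t.signed_value == pytest.approx(1.0)
        assert t.a_d == 0.0

    def test_dose_scaled_agonist(self):
        t = signed_term(0.5, _aff(pki=2.0, action="agonist"), de=10.0)
        assert t.signed_value == pytest.approx(2.0)
        assert t.a_d == pytest.approx(2.0)

    def test_antagonist_flips_sign(self):
        t = signed_term(0.5, _aff(pki=2.0, action="antagonist"), de=10.0)
        assert t.signed_value == pytest.approx(-2.0)
        assert t.direction == -1

    @pytest.mark.parametrize(
        "action,direction",
        [("agonist", 1), ("positive_modulator", 1), ("antagonist", -1),
         ("inverse_agonist", -1), ("inhibitor", -1), ("partial_agonist", 1),
         ("unknown", 1)],
    )
    def test_direction_by_action(self, action, direction):
        assert signed_term(1.0, _aff(action=action), de=1.0).direction == direction

    def test_nonbinding_pair_is_omitted_not_zeroed(self):
        with pytest.raises(NonBindingError):
            signed_term(1.0, _aff(is_nonbinding=True), de=1.0)


class TestScoreSideEffect:
    def test_signed_and_absolute_sums(self):
        terms = [
            signed_term(1.0, _aff(pki=2.0, action="agonist", receptor="R1"), de=1.0),
            signed_term(0.25, _aff(pki=2.0, action="antagonist", receptor="R2"), de=1.0),
        ]
        entry = score_side_effect(terms)
        assert entry.score == pytest.approx(1.5)
        assert entry.abs_score == pytest.approx(2.5)

    def test_single_term_identity(self):
        t = signed_term(0.7, _aff(pki=3.0), de=1.0)
        entry = score_side_effect([t])
        assert entry.score == pytest.approx(t.signed_value)

    def test_empty_terms_flagged_no_evidence(self):
        entry = score_side_effect([])
        assert entry.score == 0.0 and entry.n_terms == 0

    def test_mixed_entries_rejected(self):
        a = signed_term(1.0, _aff(drug="d1"), de=1.0)
        b = signed_term(1.0, _aff(drug="d2"), de=1.0)
        with pytest.raises(ValueError):
            score_side_effect([a, b])


class TestBootstrap:
    def test_all_input_ses_zero_gives_exactly_zero(self):
        terms = _terms_df([("d", "t", "R", 1.0, 0.0, 1.0, 1, False, 1e-8, 0.0)])
        assert bootstrap_se(terms, n_boot=100, seed=0) == 0.0

    def test_linear_propagation_single_term(self):
        # pKi fixed at 4 (Ki = 1 nM, zero SE); S = beta * pki, beta ~ N(1, 0.1)
        terms = _terms_df([("d", "t", "R", 1.0, 0.1, 1.0, 1, False, 1e-8, 0.0)])
        se = bootstrap_se(terms, n_boot=1000, seed=1)
        assert se == pytest.approx(4.0 * 0.1, rel=0.1)

    def test_default_pki_uncertainty_propagates(self):
        # beta fixed; pKi ~ N(0.824, 0.15) => SE ~ |beta| * 0.15
        terms = _terms_df([("d", "t", "R", 2.0, 0.0, 1.0, 1, True, np.nan, np.nan)])
        se = bootstrap_se(terms, n_boot=2000, seed=2)
        assert se == pytest.approx(2.0 * 0.15, rel=0.1)

    def test_same_seed_reproduces_exactly(self):
        terms = _terms_df(
            [
                ("d", "t", "R1", 1.0, 0.2, 2.0, 1, False, 5e-8, 1e-8),
                ("d", "t", "R2", -0.5, 0.1, 2.0, -1, True, np.nan, np.nan),
            ]
        )
        assert bootstrap_se(terms, 500, seed=7) == bootstrap_se(terms, 500, seed=7)
        assert bootstrap_se(terms, 500, seed=7) != bootstrap_se(terms, 500, seed=8)

    def test_n_boot_below_two_rejected(self):
        terms = _terms_df([("d", "t", "R", 1.0, 0.1, 1.0, 1, False, 1e-8, 0.0)])
        with pytest.raises(ValueError):
            bootstrap_se(terms, n_boot=1, seed=0)

    def test_affinity_draws_shared_within_drug(self):
        # two terms on the same (drug, receptor) with opposite directions:
        # shared pKi draws make their sum's affinity component cancel exactly
        terms = _terms_df(
            [
                ("d", "t", "R", 1.0, 0.0, 1.0, 1, True, np.nan, np.nan),
                ("d", "t", "R", 1.0, 0.0, 1.0, -1, True, np.nan, np.nan),
            ]
        )
        reps = bootstrap_replicates(terms, 200, seed=3)
        np.testing.assert_allclose(reps.sum(axis=1), 0.0, atol=1e-12)

    def test_bootstrap_se_converges_with_n_boot(self):
        terms = _terms_df([("d", "t", "R", 1.0, 0.1, 1.0, 1, False, 1e-8, 0.0)])
        se1 = bootstrap_se(terms, 1000, seed=4)
        se2 = bootstrap_se(terms, 2000, seed=5)
        # both estimate 0.4; SD-of-SD at n=1000 is ~0.009
        assert abs(se1 - se2) < 5 * 0.4 / np.sqrt(2 * 1000)


class TestAggregate:
    def _random_terms(self, rng, n):
        return pd.DataFrame(
            {
                "drug": rng.choice(["d1", "d2", "d3"], size=n),
                "side_effect": rng.choice(["s1", "s2", "s3", "s4"], size=n),
                "receptor": rng.choice(["DRD2", "HRH1", "HTR2A", "ADRA1A"], size=n),
                "signed_value": rng.normal(0, 2, size=n),
            }
        )

    def test_drug_total_simple(self):
        terms = pd.DataFrame(
            {
                "drug": ["d", "d"],
                "side_effect": ["a", "b"],
                "receptor": ["R1", "R2"],
                "signed_value": [1.5, -2.5],
            }
        )
        views = aggregate(terms)
        assert views["drugs"].loc[0, "abs_score"] == pytest.approx(4.0)
        assert views["drugs"].loc[0, "score"] == pytest.approx(-1.0)

    def test_on_target_classification_rule(self):
        terms = pd.DataFrame(
            {
                "drug": ["d", "d"],
                "side_effect": ["a", "a"],
                "receptor": ["DRD2", "XYZ1"],  # DRD2 is on-target
                "signed_value": [0.6, 0.4],
            }
        )
        cls = aggregate(terms)["classification"]
        assert cls.loc[0, "classification"] == "on_target"
        terms.loc[0, "signed_value"] = 0.4
        cls = aggregate(terms)["classification"]
        assert cls.loc[0, "classification"] == "off_target"

    def test_against_group_sum_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            terms = self._random_terms(rng, int(rng.integers(1, 80)))
            views = aggregate(terms)
            drugs, receptors, entries = naive_aggregate(terms.to_dict("records"))
            for _, row in views["drugs"].iterrows():
                want = drugs[row["drug"]]
                assert row["score"] == pytest.approx(want[0], abs=1e-12)
                assert row["abs_score"] == pytest.approx(want[1], abs=1e-12)
            for _, row in views["per_receptor"].iterrows():
                want = receptors[(row["drug"], row["receptor"])]
                assert row["abs_score"] == pytest.approx(want[1], abs=1e-12)
            for _, row in views["entries"].iterrows():
                want = entries[(row["drug"], row["side_effect"])]
                assert row["score"] == pytest.approx(want[0], abs=1e-12)

    def test_aggregation_conservation(self):
        rng = np.random.default_rng(9)
        terms = self._random_terms(rng, 60)
        views = aggregate(terms)
        total = views["drugs"]["abs_score"].sum()
        assert views["per_receptor"]["abs_score"].sum() == pytest.approx(total, abs=1e-9)
        assert views["entries"]["abs_score"].sum() == pytest.approx(total, abs=1e-9)

    def test_score_linearity_in_beta(self):
        rng = np.random.default_rng(10)
        terms = self._random_terms(rng, 40)
        scaled = terms.copy()
        scaled["signed_value"] = 3.0 * scaled["signed_value"]
        v1 = aggregate(terms)["entries"].set_index(["drug", "side_effect"])["score"]
        v2 = aggregate(scaled)["entries"].set_index(["drug", "side_effect"])["score"]
        np.testing.assert_allclose(v2.to_numpy(), 3.0 * v1.to_numpy(), atol=1e-12)
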