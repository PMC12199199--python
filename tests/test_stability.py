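"""Four stability algorithms and the comprehensive ranking vs brute force."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_cq_table
from evref import (CqTable, ValidationError, bestkeeper, comprehensive_rank,
                   delta_ct_stability, genorm, genorm_v, normfinder,
                   stability_suite)
from oracles import (bestkeeper_oracle, delta_ct_oracle, genorm_oracle,
                     geometric_mean, normfinder_oracle, sample_sd)


def cq_from(rows: dict[str, list[float]]) -> CqTable:
    return CqTable(pd.DataFrame(rows).T.rename(
        columns=lambda j: f"s{j}").astype(float))


def as_dict(cq: CqTable) -> dict[str, list[float]]:
    return {g: list(cq.values.loc[g]) for g in cq.gene_ids}


class TestDeltaCt:
    def test_constant_offset_pair_contributes_zero(self):
        cq = cq_from({"g1": [20.0, 22.0, 21.0, 23.0],
                      "g2": [25.0, 27.0, 26.0, 28.0],      # g1 + 5
                      "g3": [20.0, 25.0, 30.0, 18.0]})
        values = delta_ct_stability(cq)
        # g1's value = mean(SD(g1−g2)=0, SD(g1−g3)) = SD(g1−g3)/2
        diff = cq.values.loc["g1"] - cq.values.loc["g3"]
        assert values.at["g1", "delta_ct_value"] == pytest.approx(
            np.std(diff, ddof=1) / 2)

    def test_per_sample_shift_invariance(self):
        rng = np.random.default_rng(0)
        cq = random_cq_table(rng, 4, 6)
        shifted = CqTable(cq.values + rng.normal(0, 3, size=(1, 6)))
        a = delta_ct_stability(cq)["delta_ct_value"]
        b = delta_ct_stability(shifted)["delta_ct_value"]
        pd.testing.assert_series_equal(a, b, rtol=1e-9)

    def test_matches_exhaustive_pairwise_sd(self):
        rng = np.random.default_rng(1)
        cq = random_cq_table(rng, 3, 4)
        values = delta_ct_stability(cq)["delta_ct_value"]
        expected = delta_ct_oracle(as_dict(cq))
        for g, v in expected.items():
            assert values[g] == pytest.approx(v, rel=1e-12)

    def test_fewer_than_three_genes_is_error(self):
        cq = cq_from({"g1": [20.0, 21.0, 22.0], "g2": [20.0, 21.0, 22.0]})
        with pytest.raises(ValidationError, match="at least 3"):
            delta_ct_stability(cq)


class TestBestKeeper:
    def test_constant_gene_has_zero_sd_and_best_rank(self):
        cq = cq_from({"flat": [20.0] * 5,
                      "wob1": [22.0, 24.0, 23.0, 25.0, 21.0],
                      "wob2": [30.0, 28.0, 32.0, 29.0, 31.0]})
        res = bestkeeper(cq)
        assert res.at["flat", "bestkeeper_sd"] == 0.0
        assert res.at["flat", "bestkeeper_rank"] == 1.0
        assert res.at["flat", "sd_acceptable"]

    def test_single_gene_correlates_perfectly_with_its_own_index(self):
        cq = cq_from({"only": [20.0, 22.0, 24.0, 21.0]})
        res = bestkeeper(cq)
        assert res.at["only", "bestkeeper_r"] == pytest.approx(1.0)

    def test_matches_brute_force_formulas(self, cq_4x5):
        res = bestkeeper(cq_4x5)
        expected = bestkeeper_oracle(as_dict(cq_4x5))
        for g, (sd, cv, r) in expected.items():
            assert res.at[g, "bestkeeper_sd"] == pytest.approx(sd, rel=1e-12)
            assert res.at[g, "bestkeeper_cv"] == pytest.approx(cv, rel=1e-12)
            assert res.at[g, "bestkeeper_r"] == pytest.approx(r, rel=1e-12)


class TestNormFinder:
    def test_pure_sample_effects_give_zero_stability(self):
        base = np.array([20.0, 22.0, 19.0, 25.0, 21.0, 23.0])
        cq = cq_from({f"g{i}": list(base + i) for i in range(4)})
        res = normfinder(cq)
        assert np.allclose(res["normfinder_value"], 0.0, atol=1e-12)

    def test_matches_hand_computed_estimator(self):
        rng = np.random.default_rng(2)
        cq = random_cq_table(rng, 4, 6)
        res = normfinder(cq)["normfinder_value"]
        expected = normfinder_oracle(as_dict(cq))
        for g, v in expected.items():
            assert res[g] == pytest.approx(v, rel=1e-12)
        # ordering identical to the brute-force residual-SD ordering
        assert (res.sort_values().index == pd.Series(expected).sort_values().index).all()

    def test_noise_inflation_is_monotone(self):
        worse = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = random_cq_table(rng, 5, 12)
            noisy = base.values.copy()
            noisy.loc["g0"] += rng.normal(0, 2.0, size=12)
            a = normfinder(base)["normfinder_value"]["g0"]
            b = normfinder(CqTable(noisy))["normfinder_value"]["g0"]
            worse += b > a
        assert worse >= 48  # inflating one gene's noise raises its value

    def test_grouped_mode_penalizes_between_group_bias(self):
        rng = np.random.default_rng(3)
        cq = random_cq_table(rng, 4, 8)
        groups = {f"s{j}": ("g1" if j < 4 else "g2") for j in range(8)}
        biased = cq.values.copy()
        biased.loc["g0", [f"s{j}" for j in range(4)]] += 3.0  # group-level shift
        res_plain = normfinder(CqTable(cq.values, groups=groups))
        res_biased = normfinder(CqTable(biased, groups=groups))
        assert (res_biased.at["g0", "normfinder_value"]
                > res_plain.at["g0", "normfinder_value"])

    def test_single_sample_group_is_error(self):
        rng = np.random.default_rng(4)
        cq = random_cq_table(rng, 3, 3)
        table = CqTable(cq.values, groups={"s0": "a", "s1": "a", "s2": "b"})
        with pytest.raises(ValidationError, match="fewer than 2"):
            normfinder(table)


class TestGenorm:
    def test_constant_log_ratio_pair(self):
        cq = cq_from({"g1": [20.0, 22.0, 21.0, 24.0],
                      "g2": [23.0, 25.0, 24.0, 27.0],     # g1 + 3 → ratio constant
                      "g3": [20.0, 26.0, 22.0, 30.0]})
        res = genorm(cq)
        assert res.final_pair == ("g1", "g2")
        assert res.exclusion_order == ["g3"]

    def test_per_sample_scaling_invariance(self):
        rng = np.random.default_rng(5)
        cq = random_cq_table(rng, 4, 6)
        # a per-sample additive Cq shift is a per-sample multiplicative
        # scaling of the quantities Q = 2^(Cq_min − Cq)
        shifted = CqTable(cq.values + rng.normal(0, 2, size=(1, 6)))
        a, b = genorm(cq), genorm(shifted)
        pd.testing.assert_series_equal(a.m_values, b.m_values, rtol=1e-9)
        assert a.exclusion_order == b.exclusion_order

    def test_matches_exhaustive_recomputation(self, cq_4x5):
        res = genorm(cq_4x5)
        m, exclusion, pair = genorm_oracle(as_dict(cq_4x5))
        for g, v in m.items():
            assert res.m_values[g] == pytest.approx(v, rel=1e-12)
        assert res.exclusion_order == exclusion
        assert res.final_pair == pair

    def test_two_sample_sd_closed_form(self):
        cq = cq_from({"g1": [20.0, 21.0], "g2": [22.0, 26.0], "g3": [25.0, 25.0]})
        res = genorm(cq)
        # V between two genes with 2 samples = |Δ1 − Δ2| / √2
        d12 = abs((20 - 22) - (21 - 26)) / np.sqrt(2)
        d13 = abs((20 - 25) - (21 - 25)) / np.sqrt(2)
        assert res.m_values["g1"] == pytest.approx((d12 + d13) / 2, rel=1e-12)

    def test_final_pair_shares_best_rank(self, cq_4x5):
        res = genorm(cq_4x5)
        assert sorted(res.ranking[list(res.final_pair)]) == [1.5, 1.5]
        assert sorted(res.ranking) == [1.5, 1.5, 3.0, 4.0]

    def test_pairwise_variation_statistic_has_expected_length(self, cq_4x5):
        v = genorm_v(cq_4x5)
        assert list(v.index) == ["V2/3", "V3/4"]
        assert (v >= 0).all()

    def test_nonpositive_quantities_rejected(self):
        table = pd.DataFrame({"s0": [1.0, 0.0, 2.0], "s1": [1.0, 1.0, 2.0]},
                             index=["a", "b", "c"])
        with pytest.raises(ValidationError, match="positive"):
            genorm(CqTable(table), input_scale="expression")


class TestComprehensiveRank:
    def test_unanimous_algorithms_preserve_order(self):
        ranks = pd.DataFrame({a: [1.0, 2.0, 3.0] for a in "wxyz"},
                             index=["g1", "g2", "g3"])
        res = comprehensive_rank(ranks)
        assert list(res.index) == ["g1", "g2", "g3"]
        assert list(res["comprehensive_rank"]) == [1, 2, 3]

    def test_geometric_mean_closed_form(self):
        ranks = pd.DataFrame([[1.0, 2.0, 1.0, 2.0], [2.0, 1.0, 2.0, 1.0]],
                             index=["g1", "g2"], columns=list("wxyz"))
        res = comprehensive_rank(ranks)
        assert res.at["g1", "comprehensive_value"] == pytest.approx(np.sqrt(2))

    def test_random_vectors_match_brute_force_sort(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            ranks = pd.DataFrame(
                {a: rng.permutation(5) + 1.0 for a in "wxyz"},
                index=[f"g{i}" for i in range(5)])
            res = comprehensive_rank(ranks)
            expected = sorted(
                ranks.index,
                key=lambda g: (geometric_mean(list(ranks.loc[g])),
                               np.mean(ranks.loc[g]), g))
            assert list(res.index) == expected

    def test_mismatched_universe_is_error(self):
        ranks = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, 1.0]},
                             index=["g1", "g2"])
        with pytest.raises(ValidationError, match="missing"):
            comprehensive_rank(ranks)


class TestSuite:
    def test_missing_cq_gene_excluded_with_warning(self):
        rng = np.random.default_rng(8)
        cq = random_cq_table(rng, 5, 6)
        holed = cq.values.copy()
        holed.loc["g2", "s3"] = np.nan
        with pytest.warns(UserWarning, match="g2"):
            res = stability_suite(CqTable(holed))
        assert "g2" not in res.index
        assert len(res) == 4

    def test_all_ranks_are_tie_averaged_permutations(self):
        rng = np.random.default_rng(9)
        res = stability_suite(random_cq_table(rng, 5, 12))
        for col in ("delta_ct_rank", "bestkeeper_rank", "normfinder_rank",
                    "genorm_rank"):
            assert res[col].sum() == pytest.approx(15.0)  # 1+2+3+4+5

    def test_efficiency_bounds_enforced(self):
        with pytest.raises(ValidationError, match="efficiencies"):
            CqTable(pd.DataFrame({"s0": [20.0], "s1": [21.0]}, index=["g"]),
                    efficiency=pd.Series({"g": 2.5}))

    def test_long_csv_round_trip(self, tmp_path):
        path = tmp_path / "cq.csv"
        path.write_text("gene,sample,cq,group\n"
                        "g1,s1,20.0,A\ng1,s2,21.0,B\n"
                        "g2,s1,25.0,A\ng2,s2,26.0,B\n")
        cq = CqTable.from_long_csv(path)
        assert cq.values.at["g1", "s2"] == 21.0
        assert cq.groups == {"s1": "A", "s2": "B"}
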