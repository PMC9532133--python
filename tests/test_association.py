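"""Composite scores, correlation screens, trend/ANOVA filters, median split."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirnetprox import association
from mirnetprox.association import (
    anova_groups,
    composite_mean,
    evidence_intersection,
    gene_neighborhood,
    median_split_test,
    monotone_trend,
    pearson_screen,
    pearson_with_p,
    trend_anova_filter,
)

from conftest import make_matrix, random_matrix, two_group_labels


def three_group_labels(n=3):
    out = {}
    for g in ("acute", "chronic", "healthy"):
        for i in range(n):
            out[f"{g}_{i}"] = g
    return out


class TestCompositeScore:
    def test_energy_is_samplewise_mean_of_three(self, rng):
        scores = pd.DataFrame(rng.normal(0, 1, (4, 5)),
                              index=["a", "b", "c", "d"],
                              columns=[f"s{i}" for i in range(5)])
        energy = composite_mean(scores, ["a", "b", "c"], "energy")
        assert np.allclose(energy, (scores.loc["a"] + scores.loc["b"] + scores.loc["c"]) / 3)

    def test_missing_row_raises(self, rng):
        scores = pd.DataFrame(np.ones((1, 2)), index=["a"], columns=["s0", "s1"])
        with pytest.raises(KeyError):
            composite_mean(scores, ["a", "zzz"], "x")


class TestPearsonScreen:
    def test_identity_and_negation(self, rng):
        score = pd.Series(rng.normal(0, 1, 6), index=list("abcdef"), name="sc")
        m = make_matrix(
            {"same": list(score.values), "neg": list(-score.values)},
            {s: "HF" for s in "abcdef"},
        )
        res = pearson_screen(m, score, absolute=True).set_index("gene")
        assert res.loc["same", "r"] == pytest.approx(1.0)
        assert res.loc["neg", "r"] == pytest.approx(-1.0)
        assert bool(res.loc["neg", "significant"])
        signed = pearson_screen(m, score, absolute=False).set_index("gene")
        assert not bool(signed.loc["neg", "significant"])

    def test_p_matches_t_transform(self, rng):
        x = rng.normal(0, 1, 5)
        y = x + rng.normal(0, 0.4, 5)
        r, p = pearson_with_p(x, y)
        t = r * np.sqrt(3 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3))

    def test_matches_naive_covariance_oracle(self, rng):
        groups = {f"s{i}": "HF" for i in range(8)}
        m = random_matrix(rng, 30, groups)
        score = pd.Series(rng.normal(0, 1, 8), index=list(groups), name="sc")
        res = pearson_screen(m, score).set_index("gene")
        y = score.to_numpy()
        for g in m.feature_ids:
            x = m.values.loc[g].to_numpy()
            r_naive = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
            assert abs(res.loc[g, "r"] - r_naive) < 1e-12

    def test_zero_variance_gene_flagged_not_dropped(self):
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"), name="sc")
        m = make_matrix({"flat": [5, 5, 5, 5]}, {s: "HF" for s in "abcd"})
        res = pearson_screen(m, score)
        assert len(res) == 1
        assert bool(res["zero_variance"].iloc[0])
        assert not bool(res["significant"].iloc[0])


class TestEvidenceIntersection:
    def test_simple(self):
        assert evidence_intersection(
            {"h": {"A", "B"}, "e": {"B", "C"}, "i": {"B"}}) == ["B"]

    def test_empty_category(self):
        assert evidence_intersection({"h": {"A"}, "e": set()}) == []


class TestAnova:
    def test_zero_noise_equal_means(self):
        m = make_matrix({"g": [2.0] * 9}, three_group_labels())
        f, p = anova_groups(m, "g", ["acute", "chronic", "healthy"])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        labels = two_group_labels(5, 4)
        m = random_matrix(rng, 3, labels)
        f, p = anova_groups(m, "G0000", ["HF", "healthy"])
        a = m.values.loc["G0000", m.group_samples("HF")]
        b = m.values.loc["G0000", m.group_samples("healthy")]
        t, tp = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(tp)

    def test_hand_decomposition(self):
        # groups of n=3: between/within sums of squares by hand
        m = make_matrix({"g": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]},
                        three_group_labels())
        f, _ = anova_groups(m, "g", ["acute", "chronic", "healthy"])
        # group means 2, 5, 8; grand mean 5; SSB = 3*(9+0+9)=54, SSW = 3*2=6
        # F = (54/2) / (6/6) = 27
        assert f == pytest.approx(27.0)


class TestMonotone:
    @pytest.mark.parametrize(
        "means,expected",
        [((3.0, 2.0, 1.0), "decreasing"),
         ((1.0, 3.0, 2.0), "none"),
         ((1.0, 1.0, 2.0), "none"),
         ((1.0, 2.0, 3.0), "increasing")],
    )
    def test_trend(self, means, expected):
        data = {"g": [means[0]] * 3 + [means[1]] * 3 + [means[2]] * 3}
        m = make_matrix(data, three_group_labels())
        assert monotone_trend(m, "g", ["acute", "chronic", "healthy"]) == expected

    def test_filter_combines_trend_and_anova(self, rng):
        n = 5
        labels = three_group_labels(n)
        strong = [3.0 + e for e in rng.normal(0, 0.1, n)] + \
                 [2.0 + e for e in rng.normal(0, 0.1, n)] + \
                 [1.0 + e for e in rng.normal(0, 0.1, n)]
        flat = list(rng.normal(0, 0.1, 3 * n))
        m = make_matrix({"strong": strong, "flat": flat}, labels)
        res = trend_anova_filter(m, ["strong", "flat"],
                                 ["acute", "chronic", "healthy"]).set_index("gene")
        assert bool(res.loc["strong", "passes"])
        assert not bool(res.loc["flat", "passes"])


class TestNeighborhood:
    def test_anchor_excluded_duplicate_included(self, rng):
        groups = {f"s{i}": "HF" for i in range(10)}
        anchor_vals = list(rng.normal(0, 1, 10))
        m = make_matrix(
            {"anchor": anchor_vals, "twin": anchor_vals,
             "noise": list(rng.normal(0, 1, 10))},
            groups,
        )
        hood = gene_neighborhood(m, "anchor")
        assert "anchor" not in hood
        assert "twin" in hood

    def test_planted_coexpressed_block_recovered(self, rng):
        groups = {f"s{i}": "HF" for i in range(27)}
        latent = rng.normal(0, 1.6, 27)  # r ~ 0.85 vs unit noise
        data = {"anchor": list(latent)}
        for j in range(20):
            data[f"blk{j:02d}"] = list(latent + rng.normal(0, 1, 27))
        for j in range(50):
            data[f"rnd{j:02d}"] = list(rng.normal(0, 1.9, 27))
        m = make_matrix(data, groups)
        hood = gene_neighborhood(m, "anchor", r_min=0.4, p_max=0.001)
        recovered = sum(1 for g in hood if g.startswith("blk"))
        assert recovered >= 18

    def test_missing_anchor_raises(self, rng):
        m = random_matrix(rng, 3, {f"s{i}": "HF" for i in range(5)})
        with pytest.raises(KeyError):
            gene_neighborhood(m, "nope")


class TestMedianSplit:
    def test_constant_score_p_one(self):
        groups = {f"s{i}": "HF" for i in range(6)}
        m = make_matrix({"g": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, groups)
        scores = pd.DataFrame([[7.0] * 6], index=["S"], columns=list(groups))
        res = median_split_test(m, "g", scores)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_score_equal_to_expression(self):
        groups = {f"s{i}": "HF" for i in range(8)}
        expr = [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0]
        m = make_matrix({"g": expr}, groups)
        scores = pd.DataFrame([expr], index=["S"], columns=list(groups))
        res = median_split_test(m, "g", scores)
        assert res["r"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] < 0.01

    def test_ties_go_to_low_group(self):
        groups = {f"s{i}": "HF" for i in range(4)}
        m = make_matrix({"g": [1.0, 2.0, 2.0, 3.0]}, groups)  # median 2
        scores = pd.DataFrame([[0.0, 0.0, 0.0, 1.0]], index=["S"],
                              columns=list(groups))
        res = median_split_test(m, "g", scores)
        # low group = {1,2,2} (ties at the median included), high = {3}
        assert np.isnan(res["t_stat"].iloc[0])  # high group too small for t

    def test_type_one_error_rate(self, rng):
        groups = {f"s{i}": "HF" for i in range(20)}
        m = make_matrix({"g": list(rng.normal(0, 1, 20))}, groups)
        scores = pd.DataFrame(rng.normal(0, 1, (200, 20)),
                              index=[f"S{i}" for i in range(200)],
                              columns=list(groups))
        res = median_split_test(m, "g", scores)
        frac = (res["p_value"] < 0.05).mean()
        assert frac < 0.12
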