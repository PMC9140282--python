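import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from habit.errors import InvalidInputError, RankDeficientError
from habit.stats_engine import (
    classify_fatigue,
    fit_log_ttc_family,
    fit_log_ttc_lm,
    holm_bonferroni,
    holm_sidak,
    island_auc,
    kruskal_wallis_pairwise,
    one_way_anova_tukey,
    rank_sum_test,
    two_sample_t_test,
)


def holm_oracle(pvals, sidak=False):
    """Hand step-down: sort, adjust by remaining count, enforce monotone."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        step = m - rank
        val = 1 - (1 - p[idx]) ** step if sidak else min(1.0, p[idx] * step)
        running = max(running, val)
        adj[idx] = running
    return adj


class TestHolmProcedures:
    def test_holm_hand_example(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_holm_pair_capped_at_one(self):
        np.testing.assert_allclose(holm_bonferroni([0.5, 0.5]), [1.0, 1.0])

    def test_sidak_hand_example(self):
        np.testing.assert_allclose(
            holm_sidak([0.01, 0.03, 0.04]), [0.029701, 0.0591, 0.0591], atol=1e-10
        )

    def test_single_p_unchanged_and_zero_stays_zero(self):
        assert holm_bonferroni([0.2])[0] == pytest.approx(0.2)
        assert holm_sidak([0.2])[0] == pytest.approx(0.2)
        assert holm_sidak([0.0, 0.7, 0.2])[0] == 0.0

    def test_out_of_range_rejected(self):
        for bad in ([1.2], [-0.1], [np.nan]):
            with pytest.raises(InvalidInputError):
                holm_bonferroni(bad)
            with pytest.raises(InvalidInputError):
                holm_sidak(bad)

    @pytest.mark.parametrize("sidak", [False, True])
    def test_matches_step_down_oracle_on_random_vectors(self, sidak, rng):
        fn = holm_sidak if sidak else holm_bonferroni
        for _ in range(200):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(fn(p), holm_oracle(p, sidak=sidak), atol=1e-12)

    def test_adjusted_ge_raw_and_permutation_equivariant(self, rng):
        p = rng.random(8)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p)
        perm = rng.permutation(8)
        np.testing.assert_allclose(holm_bonferroni(p[perm]), adj[perm], atol=1e-12)


def _toy_scores():
    # 8 flies, 2 genotypes crossed with 2 days and 2 systems
    return pd.DataFrame({
        "genotype": ["ctl", "ctl", "ctl", "ctl", "mut", "mut", "mut", "mut"],
        "day": ["d1", "d1", "d2", "d2", "d1", "d1", "d2", "d2"],
        "system": ["s1", "s2", "s1", "s2", "s1", "s2", "s1", "s2"],
        "ttc": [3, 4, 5, 4, 9, 11, 12, 10],
    })


class TestLogTtcLm:
    def test_matches_normal_equations_oracle(self):
        df = _toy_scores()
        cmp = fit_log_ttc_lm(df, "mut", "ctl")
        # independent normal-equations solution with explicit dummy coding
        y = np.log(df["ttc"].to_numpy(float))
        X = np.column_stack([
            np.ones(8),
            (df["genotype"] == "mut").astype(float),
            (df["day"] == "d2").astype(float),
            (df["system"] == "s2").astype(float),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (8 - 4)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert cmp.estimate == pytest.approx(beta[1], abs=1e-10)
        assert cmp.se == pytest.approx(se, abs=1e-10)
        t = beta[1] / se
        assert cmp.p_raw == pytest.approx(2 * sps.t.sf(abs(t), 4), abs=1e-10)

    def test_identical_groups_give_null_estimate(self, rng):
        n = 64
        ttc = rng.integers(2, 12, size=n)
        df = pd.DataFrame({
            "genotype": np.repeat(["a", "b"], n // 2),
            "day": np.tile(["d1", "d2"], n // 2),
            "system": np.tile(["s1", "s1", "s2", "s2"], n // 4),
            "ttc": np.concatenate([ttc[: n // 2], ttc[: n // 2]]),
        })
        cmp = fit_log_ttc_lm(df, "b", "a")
        assert cmp.estimate == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_raw == pytest.approx(1.0, abs=1e-9)

    def test_confounded_design_names_aliased_term(self):
        df = _toy_scores()
        df["day"] = np.where(df["genotype"] == "mut", "d1", "d2")  # aliased
        with pytest.raises(RankDeficientError, match="day"):
            fit_log_ttc_lm(df, "mut", "ctl")

    def test_ttc_below_one_rejected(self):
        df = _toy_scores()
        df.loc[0, "ttc"] = 0
        with pytest.raises(InvalidInputError, match="log"):
            fit_log_ttc_lm(df, "mut", "ctl")

    def test_family_correction_is_holm_of_raw(self):
        df = _toy_scores()
        extra = df[df["genotype"] == "mut"].copy()
        extra["genotype"] = "mut2"
        extra["ttc"] = [4, 5, 3, 5]
        family = fit_log_ttc_family(pd.concat([df, extra]), reference="ctl")
        raw = [c.p_raw for c in family]
        np.testing.assert_allclose(
            [c.p_adj for c in family], holm_oracle(raw), atol=1e-12
        )


class TestAnovaTukey:
    def test_identical_groups_degenerate(self):
        out = one_way_anova_tukey({"a": [2, 2], "b": [2, 2], "c": [2, 2]})
        assert (out["f"], out["p"]) == (0.0, 1.0)
        assert all(p == 1.0 for *_, p in out["pairwise"])

    def test_f_matches_hand_sums_of_squares(self):
        out = one_way_anova_tukey([[1, 2, 3], [2, 3, 4], [10, 11, 12]])
        # SSbetween = 146 on 2 df, SSwithin = 6 on 6 df -> F = 73
        assert out["f"] == pytest.approx(73.0, abs=1e-9)

    def test_two_group_tukey_equals_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        out = one_way_anova_tukey([a, b])
        # with two groups the studentized range collapses to q = t*sqrt(2)
        assert out["pairwise"][0][2] == pytest.approx(two_sample_t_test(a, b), abs=1e-8)

    def test_small_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            one_way_anova_tukey({"a": [1.0], "b": [1, 2]})


class TestRankTests:
    def test_exact_small_sample(self):
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_groups_max_p(self):
        assert rank_sum_test([5, 5, 5], [5, 5]) == 1.0

    def test_exact_and_asymptotic_agree_at_boundary(self, rng):
        for _ in range(50):
            a, b = rng.normal(0, 1, 6), rng.normal(0.3, 1, 6)
            exact = float(sps.mannwhitneyu(a, b, method="exact").pvalue)
            approx = float(sps.mannwhitneyu(a, b, method="asymptotic").pvalue)
            assert abs(exact - approx) < 0.02
            assert rank_sum_test(a, b) == pytest.approx(exact)

    def test_invariant_under_monotone_transform(self, rng):
        a, b = rng.gamma(2, 1, 15), rng.gamma(3, 1, 18)
        assert rank_sum_test(a, b) == pytest.approx(
            rank_sum_test(np.log(a), np.log(b)), abs=1e-12
        )

    def test_kruskal_identical_groups(self):
        out = kruskal_wallis_pairwise([[1, 1], [1, 1], [1, 1]])
        assert out["p"] == 1.0 and out["h"] == 0.0

    def test_kruskal_h_matches_hand_formula(self):
        out = kruskal_wallis_pairwise([[1, 2], [3, 4], [5, 6]])
        # tie-free hand computation gives H = 32/7
        assert out["h"] == pytest.approx(32 / 7, abs=1e-12)

    def test_kruskal_pairwise_is_holm_of_rank_sums(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 2)]
        out = kruskal_wallis_pairwise(groups)
        raw = [
            rank_sum_test(groups[i], groups[j])
            for i in range(3) for j in range(i + 1, 3)
        ]
        np.testing.assert_allclose([p for *_, p in out["pairwise"]], holm_oracle(raw))


class TestTTest:
    def test_identical_groups(self):
        assert two_sample_t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # means 0.5 vs 1.5, pooled var 0.5, t = -sqrt(2), df = 2
        p = two_sample_t_test([0, 1], [1, 2])
        assert p == pytest.approx(2 * sps.t.sf(np.sqrt(2), 2), abs=1e-12)

    def test_location_invariance(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 11)
        assert two_sample_t_test(a, b) == pytest.approx(
            two_sample_t_test(a + 100, b + 100), abs=1e-9
        )

    def test_zero_variance_conventions(self):
        assert two_sample_t_test([2, 2], [2, 2]) == 1.0
        assert two_sample_t_test([2, 2], [3, 3]) == 0.0


class TestIslandAuc:
    def test_rectangle(self):
        assert island_auc([0, 10], [100, 100]) == pytest.approx(1000.0)

    def test_triangle(self):
        assert island_auc([0, 10], [100, 0]) == pytest.approx(500.0)

    def test_matches_refined_riemann_oracle(self, rng):
        t = np.sort(rng.uniform(0, 60, 30))
        t[0], t[-1] = 0.0, 60.0
        y = rng.uniform(0, 100, 30)
        coarse = island_auc(t, y)
        fine_t = np.union1d(np.linspace(0, 60, 200001), t)
        fine_y = np.interp(fine_t, t, y)
        import math
        riemann = math.fsum((fine_y[1:] + fine_y[:-1]) / 2 * np.diff(fine_t))
        assert coarse == pytest.approx(riemann, abs=1e-9)

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            island_auc([0], [50])
        with pytest.raises(InvalidInputError):
            island_auc([0, 0], [50, 50])
        with pytest.raises(InvalidInputError):
            island_auc([0, 1], [50, 150])


class TestFatigueRule:
    def _scores(self, ctl, tst):
        n = len(ctl) + len(tst)
        return pd.DataFrame({
            "genotype": ["ctl"] * len(ctl) + ["tst"] * len(tst),
            "day": ["d1", "d2"] * (n // 2),
            "system": ["s1"] * n,
            "ttc": ctl + tst,
        })

    def test_smaller_ttc_with_significance_is_fatigue(self):
        df = self._scores([40, 42, 44, 41, 43, 45], [10, 11, 12, 10, 13, 11])
        v = classify_fatigue(df, "tst", "ctl")
        assert v.verdict == "fatigue" and v.direction == -1

    def test_larger_ttc_is_never_fatigue_despite_significance(self):
        df = self._scores([10, 11, 12, 10, 13, 11], [40, 42, 44, 41, 43, 45])
        v = classify_fatigue(df, "tst", "ctl")
        assert v.verdict == "no_fatigue" and v.direction == 1
        assert v.p_adj < 0.05  # significant, but wrong direction

    def test_similar_groups_no_fatigue(self):
        df = self._scores([40, 42, 44, 41], [41, 43, 40, 44])
        assert classify_fatigue(df, "tst", "ctl").verdict == "no_fatigue"
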