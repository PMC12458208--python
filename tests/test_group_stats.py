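"""Statistical battery oracles: exact permutation null for Kruskal-Wallis,
direct-formula descriptives, hand-computed two-way ANOVA, Fisher-z
Spearman intervals with empirical coverage, and branch selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from isletrings.group_stats import (
    GroupSample,
    compare_groups,
    descriptive,
    dunn_posthoc,
    kruskal_wallis,
    spearman_with_ci,
    two_way_ring_analysis,
)
from isletrings.synthetic import sample_hla2_fractions


class TestDescriptive:
    def test_hand_arithmetic_example(self):
        d = descriptive([1, 2, 3, 4, 5])
        assert d["mean"] == 3 and d["median"] == 3
        assert d["q1"] == 2 and d["q3"] == 4 and d["iqr"] == 2
        assert d["fence_low"] == -1 and d["fence_high"] == 7

    def test_constant_vector(self):
        d = descriptive([4.2] * 7)
        assert d["sd"] == 0 and d["iqr"] == 0 and d["mode"] == 4.2

    def test_mode_ties_take_smallest(self):
        assert descriptive([3, 3, 1, 1, 2])["mode"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            descriptive([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60))
    def test_matches_direct_formulas(self, values):
        v = np.sort(np.asarray(values, float))
        d = descriptive(values)
        assert d["mean"] == pytest.approx(sum(values) / len(values), abs=1e-12, rel=1e-12)
        mu = sum(values) / len(values)
        sd = math.sqrt(sum((x - mu) ** 2 for x in values) / (len(values) - 1))
        assert d["sd"] == pytest.approx(sd, abs=1e-9, rel=1e-9)
        assert d["min"] == v[0] and d["max"] == v[-1]
        assert d["iqr"] == pytest.approx(d["q3"] - d["q1"], abs=1e-12)


class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        g = np.array([1.0, 5.0, 9.0])
        h, p = kruskal_wallis([g.copy(), g.copy(), g.copy()])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_exact_p_equals_exhaustive_permutation(self):
        groups = [np.array([1.0, 7.0, 3.0]), np.array([4.0, 9.0, 2.0]),
                  np.array([8.0, 5.0, 11.0])]
        h_obs, p_exact = kruskal_wallis(groups, method="exact")
        # independent oracle: permute the pooled rank vector over all 9!
        # assignments (vectorized), recompute H from first principles
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        perms = np.array(list(itertools.permutations(range(9))))
        r = ranks[perms]
        n = 9
        h_all = (12.0 / (n * (n + 1))) * (
            r[:, :3].sum(1) ** 2 / 3 + r[:, 3:6].sum(1) ** 2 / 3 + r[:, 6:].sum(1) ** 2 / 3
        ) - 3 * (n + 1)
        p_oracle = np.mean(h_all >= h_obs - 1e-12)
        assert p_exact == pytest.approx(p_oracle, abs=1e-12)

    def test_two_group_case_tracks_rank_sum_test(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)
        h, p = kruskal_wallis([a, b], method="asymptotic")
        u = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
        assert p == pytest.approx(u.pvalue, rel=0.02)


class TestCompareGroups:
    def test_small_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="tiny"):
            compare_groups({"big": np.arange(10.0), "tiny": np.array([1.0, 2.0])})

    def test_nonnormal_group_routes_to_kruskal(self):
        skewed = np.array([1.0, 1.1, 1.05, 1.02, 30.0, 1.07, 1.01, 40.0])
        res = compare_groups({"a": skewed, "b": skewed + 0.01, "c": skewed - 0.01})
        assert res.test_name == "kruskal_wallis"
        assert all(p.adjusted_p <= 1 for p in res.pairwise)

    def test_normal_groups_route_to_anova_and_tukey_flags_shifted_group(self):
        rng = np.random.default_rng(2)
        groups = {
            "g1": rng.normal(0, 1, 50),
            "g2": rng.normal(0, 1, 50),
            "g3": rng.normal(2, 1, 50),
        }
        res = compare_groups(groups)
        assert res.test_name == "anova_oneway"
        assert res.p_value < 1e-3
        for pair in res.pairwise:
            involved = {pair.group_a, pair.group_b}
            if "g3" in involved:
                assert pair.adjusted_p < 0.05
            else:
                assert pair.adjusted_p > 0.05

    def test_relabelling_permutes_but_preserves_pairwise(self):
        rng = np.random.default_rng(3)
        vals = {k: rng.normal(i, 1, 30) for i, k in enumerate("abc")}
        r1 = compare_groups(vals)
        r2 = compare_groups({"c": vals["c"], "a": vals["a"], "b": vals["b"]})
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
        p1 = {frozenset((p.group_a, p.group_b)): p.adjusted_p for p in r1.pairwise}
        p2 = {frozenset((p.group_a, p.group_b)): p.adjusted_p for p in r2.pairwise}
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], rel=1e-9)

    def test_dunn_adjustment_never_below_raw_p(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 15), rng.normal(0.5, 1, 15), rng.normal(1, 1, 15)]
        pairs = dunn_posthoc(groups, ["a", "b", "c"])
        # raw two-sided z p-values recomputed independently
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        means = [ranks[:15].mean(), ranks[15:30].mean(), ranks[30:].mean()]
        n = 45
        for pair, (i, j) in zip(pairs, itertools.combinations(range(3), 2)):
            var = n * (n + 1) / 12 * (1 / 15 + 1 / 15)
            raw = 2 * sps.norm.sf(abs(means[i] - means[j]) / math.sqrt(var))
            assert pair.adjusted_p >= raw - 1e-12

    def test_shapiro_type_one_error_rate(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            sps.shapiro(rng.normal(0, 1, 25)).pvalue < 0.05 for _ in range(2000)
        )
        assert rejections / 2000 == pytest.approx(0.05, abs=0.02)


class TestTwoWayAnova:
    def test_all_equal_gives_zero_f(self):
        obs = pd.DataFrame({
            "value": 5.0,
            "group": np.repeat(["a", "b"], 8),
            "ring": list(np.tile(np.repeat(["r1", "r2"], 4), 2)),
        })
        res = two_way_ring_analysis(obs)
        assert all(f["F"] == 0.0 for f in res.factors.values())

    def test_balanced_two_by_two_matches_hand_decomposition(self):
        # cell means: a/r1=1, a/r2=3, b/r1=2, b/r2=8; 2 replicates, +-1 noise
        rows = []
        for g, r, mu in (("a", "r1", 1), ("a", "r2", 3), ("b", "r1", 2), ("b", "r2", 8)):
            rows += [(mu - 1.0, g, r), (mu + 1.0, g, r)]
        obs = pd.DataFrame(rows, columns=["value", "group", "ring"])
        res = two_way_ring_analysis(obs)
        # hand ANOVA: SS_A = nb*sum(mean_Ai - grand)^2 etc., MSE = 8 (df 4)
        grand = 3.5
        ss_a = 4 * ((2 - grand) ** 2 + (5 - grand) ** 2)            # 18
        ss_b = 4 * ((1.5 - grand) ** 2 + (5.5 - grand) ** 2)        # 32
        ss_ab = 2 * sum((mu - gm - rm + grand) ** 2 for mu, gm, rm in
                        ((1, 2, 1.5), (3, 2, 5.5), (2, 5, 1.5), (8, 5, 5.5)))  # 8
        mse = 8 * 1.0 / 4
        assert res.factors["group"]["F"] == pytest.approx(ss_a / 1 / mse, rel=1e-9)
        assert res.factors["ring"]["F"] == pytest.approx(ss_b / 1 / mse, rel=1e-9)
        assert res.factors["interaction"]["F"] == pytest.approx(ss_ab / 1 / mse, rel=1e-9)

    def test_empty_design_cell_reported(self):
        obs = pd.DataFrame({"value": [1.0, 2.0, 3.0],
                            "group": ["a", "a", "b"],
                            "ring": ["r1", "r2", "r1"]})
        with pytest.raises(ValueError, match="empty design cells"):
            two_way_ring_analysis(obs)

    def test_simulated_group_effect_detected(self):
        rng = np.random.default_rng(6)
        rows = []
        for g, shift in (("nd", 0.0), ("t1d", 2.0)):
            for ring in range(1, 9):
                base = 10 - 0.5 * ring
                for _ in range(25):
                    rows.append((base + shift + rng.normal(0, 2), g, f"r{ring}"))
        res = two_way_ring_analysis(pd.DataFrame(rows, columns=["value", "group", "ring"]))
        assert res.factors["group"]["p"] < 1e-3


class TestSpearman:
    def test_monotone_relation_gives_rho_one(self):
        x = np.linspace(0, 10, 40)
        r = spearman_with_ci(x, np.exp(x))
        assert r.rho == 1.0
        assert r.ci_high <= 1.0 + 1e-12
        assert r.p_value < 1e-10

    def test_independent_samples_within_null_band(self):
        rng = np.random.default_rng(7)
        r = spearman_with_ci(rng.normal(size=400), rng.normal(size=400))
        assert abs(r.rho) <= 0.10

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_with_ci(np.ones(10), np.arange(10.0))

    def test_copula_target_recovered_with_covering_interval(self):
        rng = np.random.default_rng(8)
        pm, pb = sample_hla2_fractions(500, 0.74, 0.4, 0.15, 20.0, rng)
        r = spearman_with_ci(pm, pb)
        assert r.rho == pytest.approx(0.74, abs=0.05)
        assert r.ci_low <= 0.74 <= r.ci_high

    def test_interval_coverage_at_least_092(self):
        rng = np.random.default_rng(9)
        covered = 0
        for _ in range(1000):
            pm, pb = sample_hla2_fractions(100, 0.5, 0.4, 0.15, 20.0, rng)
            r = spearman_with_ci(pm, pb)
            covered += r.ci_low <= 0.5 <= r.ci_high
        assert covered / 1000 >= 0.92
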