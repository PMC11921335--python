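"""Tests for the rank-based statistics stack.

Each test statistic is cross-checked against an independent route: scipy's
implementations, statsmodels' Holm correction, hand formulas on tiny
samples, or exhaustive permutation enumeration.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import indoorvoc as iv
from indoorvoc.nonparametric import _bm_statistic


def bm_permutation_oracle(x, y):
    """Exhaustive two-sided permutation p of the BM statistic."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    w_obs, _, _ = _bm_statistic(np.asarray(x, float), np.asarray(y, float))
    count, total = 0, 0
    for idx in combinations(range(n), nx):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        try:
            w, _, _ = _bm_statistic(pooled[mask], pooled[~mask])
        except ValueError:
            w = 0.0
        total += 1
        if abs(w) >= abs(w_obs) - 1e-12:
            count += 1
    return count / total


class TestBrunnerMunzel:
    def test_identical_samples_are_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = iv.brunner_munzel(x, list(x))
        assert res.effect == pytest.approx(0.5)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 2, 15)
        fwd = iv.brunner_munzel(x, y)
        rev = iv.brunner_munzel(y, x)
        assert rev.effect == pytest.approx(1.0 - fwd.effect, rel=1e-12)
        assert rev.p_raw == pytest.approx(fwd.p_raw, rel=1e-12)
        assert rev.statistic == pytest.approx(-fwd.statistic, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=rng.integers(5, 25))
        y = rng.normal(0.5, 3, size=rng.integers(5, 25))
        mine = iv.brunner_munzel(x, y)
        ref = sps.brunnermunzel(x, y)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_scipy_with_ties(self):
        x = [1, 2, 2, 3, 4, 4, 4]
        y = [2, 3, 3, 5, 5, 6]
        mine = iv.brunner_munzel(x, y)
        ref = sps.brunnermunzel(x, y)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            iv.brunner_munzel([1.0, 1.0, 1.0], [1.0, 1.0])

    def test_permutation_method_equals_exhaustive_oracle(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(1.0, 2, 6)
        res = iv.brunner_munzel(x, y, method="permutation")
        assert res.p_raw == pytest.approx(bm_permutation_oracle(x, y), abs=1e-12)

    def test_t_approximation_near_permutation_oracle(self, rng):
        """For n <= 8 per group the asymptotic p tracks the exact one."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, 7)
            y = r.normal(0.7, 1.5, 8)
            p_t = iv.brunner_munzel(x, y).p_raw
            p_perm = bm_permutation_oracle(x, y)
            assert abs(p_t - p_perm) < 0.06

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            iv.brunner_munzel([1.0], [2.0, 3.0])


class TestKruskalWallis:
    def test_matches_scipy(self, rng):
        groups = [rng.normal(loc, 1, 15) for loc in (0.0, 0.3, 1.0)]
        mine = iv.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_scipy_with_ties(self):
        groups = [[1, 2, 2, 3], [2, 3, 3, 4, 4], [1, 1, 5, 5]]
        mine = iv.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_hand_formula_oracle_no_ties(self):
        """H from the rank-sum formula computed by hand for 2 groups of 3:
        ranks x={1,2,4}, y={3,5,6}; H = 12/(6*7)*(3*(7/3-3.5)^2+3*(14/3-3.5)^2)."""
        x, y = [10.0, 11.0, 13.0], [12.0, 14.0, 15.0]
        expected_h = 12.0 / (6 * 7) * (
            3 * (7 / 3 - 3.5) ** 2 + 3 * (14 / 3 - 3.5) ** 2
        )
        res = iv.kruskal_wallis([x, y])
        assert res.statistic == pytest.approx(expected_h, rel=1e-12)

    def test_all_equal_defined_as_no_evidence(self):
        res = iv.kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_two_groups_consistent_with_rank_direction(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(2, 1, 40)
        kw = iv.kruskal_wallis([x, y])
        bm = iv.brunner_munzel(x, y)
        assert kw.p_raw < 0.01 and bm.p_raw < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            iv.kruskal_wallis([[1.0, 2.0]])


def dunn_oracle(groups):
    """First-principles Dunn z-statistics via pandas average ranks."""
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    pooled = pd.Series(np.concatenate(groups))
    ranks = pooled.rank(method="average").to_numpy()
    n = len(pooled)
    counts = pooled.value_counts().to_numpy()
    ties = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    out = {}
    for i, j in combinations(range(len(groups)), 2):
        ri = ranks[labels == i].mean()
        rj = ranks[labels == j].mean()
        se = np.sqrt(
            (n * (n + 1) / 12.0 - ties)
            * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        )
        out[(i, j)] = (ri - rj) / se
    return out


class TestDunn:
    def test_identical_groups(self):
        res = iv.dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_pair_count(self, k, rng):
        groups = [rng.normal(i, 1, 6) for i in range(k)]
        assert len(iv.dunn_posthoc(groups)) == k * (k - 1) // 2

    def test_three_group_toy_matches_first_principles(self):
        groups = [
            [2.0, 3.0, 5.0, 7.0, 11.0],
            [1.0, 4.0, 6.0, 8.0, 9.0],
            [10.0, 12.0, 13.0, 14.0, 2.0],
        ]
        oracle = dunn_oracle(groups)
        results = iv.dunn_posthoc(groups, labels=["a", "b", "c"])
        by_pair = {r.groups: r for r in results}
        assert by_pair[("a", "b")].statistic == pytest.approx(oracle[(0, 1)], rel=1e-12)
        assert by_pair[("a", "c")].statistic == pytest.approx(oracle[(0, 2)], rel=1e-12)
        assert by_pair[("b", "c")].statistic == pytest.approx(oracle[(1, 2)], rel=1e-12)

    def test_ties_corrected_toy(self):
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0, 3.0], [3.0, 4.0, 4.0]]
        oracle = dunn_oracle(groups)
        results = iv.dunn_posthoc(groups)
        for r, (pair, z) in zip(results, sorted(oracle.items())):
            assert r.statistic == pytest.approx(z, rel=1e-12)

    def test_holm_adjustment_applied(self, rng):
        groups = [rng.normal(i * 2.0, 1, 10) for i in range(3)]
        results = iv.dunn_posthoc(groups)
        raw = [r.p_raw for r in results]
        adjusted = [r.p_adjusted for r in results]
        np.testing.assert_allclose(adjusted, iv.holm_adjust(raw), atol=1e-15)
        assert all(a >= p for a, p in zip(adjusted, raw))


class TestHolm:
    def test_single_p_unchanged(self):
        assert iv.holm_adjust([0.03]) == [0.03]

    def test_hand_example(self):
        """{0.01, 0.04}: 2*0.01 = 0.02, then max(0.02, 1*0.04) = 0.04."""
        assert iv.holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0, 1, 12)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(iv.holm_adjust(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_permutation_invariance(self, p):
        adj = np.asarray(iv.holm_adjust(p))
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = np.asarray(iv.holm_adjust([p[i] for i in perm]))
        inverse = np.empty_like(perm)
        inverse[perm] = np.arange(len(p))
        np.testing.assert_allclose(adj_perm[inverse], adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            iv.holm_adjust([0.5, 1.5])


class TestBootstrap:
    def test_constant_sample_degenerate_ci(self):
        ci = iv.bootstrap_ci([3.0, 3.0, 3.0], np.mean, seed=1)
        assert ci.lower == ci.upper == ci.point == 3.0

    def test_seed_determinism(self, rng):
        x = rng.normal(0, 1, 50)
        a = iv.bootstrap_ci(x, np.mean, seed=7)
        b = iv.bootstrap_ci(x, np.mean, seed=7)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        c = iv.bootstrap_ci(x, np.mean, seed=8)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_vectorized_and_generic_paths_agree(self, rng):
        x = rng.normal(0, 1, 40)
        fast = iv.bootstrap_ci(x, np.median, seed=3)
        slow = iv.bootstrap_ci(x, lambda v: float(np.median(v)), seed=3)
        assert fast.lower == pytest.approx(slow.lower)
        assert fast.upper == pytest.approx(slow.upper)

    def test_ci_brackets_point(self, rng):
        x = rng.lognormal(0, 1, 80)
        ci = iv.bootstrap_ci(x, np.mean, seed=5)
        assert ci.lower <= ci.point <= ci.upper

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iv.bootstrap_ci([], np.mean)


class TestBoxplotSummary:
    def test_linear_interpolation_oracle_1_to_100(self):
        box = iv.boxplot_summary(np.arange(1.0, 101.0))
        assert box.percentiles[5] == pytest.approx(5.95)
        assert box.percentiles[25] == pytest.approx(25.75)
        assert box.percentiles[50] == pytest.approx(50.5)
        assert box.percentiles[75] == pytest.approx(75.25)
        assert box.percentiles[95] == pytest.approx(95.05)
        assert len(box.lower_outliers) == 5
        assert len(box.upper_outliers) == 5

    def test_single_value(self):
        box = iv.boxplot_summary([4.2])
        assert all(v == 4.2 for v in box.percentiles.values())
        assert len(box.lower_outliers) == 0 and len(box.upper_outliers) == 0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_percentiles_monotone(self, values):
        box = iv.boxplot_summary(values)
        ordered = [box.percentiles[k] for k in (5, 25, 50, 75, 95)]
        assert all(a <= b for a, b in zip(ordered, ordered[1:]))


class TestCompareGroups:
    def test_two_groups_uses_brunner_munzel(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)])
        labels = ["a"] * 10 + ["b"] * 10
        results = iv.compare_groups(vals, labels)
        assert len(results) == 1
        assert results[0].test_name == "brunner-munzel"

    def test_many_groups_omnibus_plus_pairs(self, rng):
        vals = np.concatenate([rng.normal(i, 1, 8) for i in range(4)])
        labels = sum([[s] * 8 for s in "abcd"], [])
        results = iv.compare_groups(vals, labels)
        assert results[0].test_name == "kruskal-wallis"
        assert len(results) == 1 + 6

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            iv.compare_groups([1.0, 2.0], ["a", "a"])
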