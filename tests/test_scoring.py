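import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from driverscan import (
    FeatureMatrix,
    is_improvement,
    ks_skewness_score,
    score_union,
    wilcoxon_skewness_score,
)


def ks_dplus_oracle(ranks, N):
    """Brute-force D+ over the ECDF-difference grid: for each event i (1-based
    among the m sorted ranks), the excess i/m - (r_i - 1)/N."""
    ranks = sorted(ranks)
    m = len(ranks)
    return max(i / m - (r - 1) / N for i, r in enumerate(ranks, 1))


class TestKS:
    @pytest.mark.parametrize(
        "ranks,N,expected",
        [
            (range(1, 6), 100, 0.96),
            ([1], 7, 1.0),
            ([1], 1000, 1.0),
            ([100], 100, 0.01),
        ],
    )
    def test_closed_forms(self, ranks, N, expected):
        s = ks_skewness_score(ranks, N)
        assert s.statistic == pytest.approx(expected, abs=1e-12)
        assert s.statistic == pytest.approx(ks_dplus_oracle(ranks, N), abs=1e-12)

    def test_top_m_closed_form(self):
        # events at ranks 1..m give D+ = 1 - (m-1)/N
        for m, N in [(1, 10), (3, 10), (5, 100), (10, 40)]:
            s = ks_skewness_score(range(1, m + 1), N)
            assert s.statistic == pytest.approx(1 - (m - 1) / N, abs=1e-12)

    def test_agrees_with_oracle_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            N = int(rng.integers(2, 200))
            m = int(rng.integers(1, N + 1))
            ranks = rng.choice(N, size=m, replace=False) + 1
            s = ks_skewness_score(ranks, N)
            assert s.statistic == pytest.approx(
                ks_dplus_oracle(ranks, N), abs=1e-12
            )
            assert s.p_value == pytest.approx(
                min(1.0, np.exp(-2 * m * s.statistic**2)), abs=1e-12
            )

    def test_p_monotone_in_dplus_at_fixed_m(self):
        # better (smaller) ranks -> larger D+, smaller p
        worse = ks_skewness_score([5, 20, 40], 50)
        better = ks_skewness_score([1, 20, 40], 50)
        assert better.statistic >= worse.statistic
        assert better.p_value <= worse.p_value

    def test_top_m_is_optimal_by_enumeration(self):
        # exhaustive check: {1..m} attains the maximal D+ among all rank sets
        for N in (8, 12):
            for m in (1, 2, 3, 4):
                top = ks_skewness_score(range(1, m + 1), N).statistic
                for combo in itertools.combinations(range(1, N + 1), m):
                    assert ks_skewness_score(combo, N).statistic <= top + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError, match="unscorable"):
            ks_skewness_score([], 10)
        with pytest.raises(ValueError, match="1..10"):
            ks_skewness_score([11], 10)
        with pytest.raises(ValueError, match="distinct"):
            ks_skewness_score([3, 3], 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_moving_one_event_left_never_hurts(self, data):
        N = data.draw(st.integers(3, 60))
        m = data.draw(st.integers(1, N - 1))
        ranks = sorted(
            data.draw(
                st.lists(
                    st.integers(1, N), min_size=m, max_size=m, unique=True
                )
            )
        )
        base = ks_skewness_score(ranks, N)
        # move one event to a strictly smaller unoccupied rank
        occupied = set(ranks)
        movable = [
            (i, r2)
            for i, r in enumerate(ranks)
            for r2 in range(1, r)
            if r2 not in occupied
        ]
        if not movable:
            return
        i, r2 = movable[data.draw(st.integers(0, len(movable) - 1))]
        improved = list(ranks)
        improved[i] = r2
        s2 = ks_skewness_score(improved, N)
        assert s2.statistic >= base.statistic - 1e-12
        assert s2.p_value <= base.p_value + 1e-12


class TestWilcoxon:
    def test_minimum_rank_sum(self):
        s = wilcoxon_skewness_score([1, 2, 3], 10)
        # W = 6 is the minimum possible; p is the minimal attainable value
        # for any 3-subset of 1..10 under the same approximation
        others = [
            wilcoxon_skewness_score(c, 10).p_value
            for c in itertools.combinations(range(1, 11), 3)
        ]
        assert s.p_value == pytest.approx(min(others))
        assert s.statistic > 0

    def test_maximum_rank_sum(self):
        s = wilcoxon_skewness_score([8, 9, 10], 10)
        assert s.p_value >= 0.5

    def test_exact_tail_oracle(self):
        # enumerate all C(6,2)=15 rank pairs: P(W <= 5) = 4/15
        exact = np.mean(
            [sum(c) <= 5 for c in itertools.combinations(range(1, 7), 2)]
        )
        assert exact == pytest.approx(4 / 15)
        approx = wilcoxon_skewness_score([1, 4], 6)
        assert approx.p_value == pytest.approx(exact, abs=0.05)
        # scipy's exact Mann-Whitney as an independent cross-check
        ref = stats.mannwhitneyu(
            [1, 4], [2, 3, 5, 6], alternative="less", method="exact"
        ).pvalue
        assert ref == pytest.approx(exact, abs=1e-12)

    def test_one_group_empty_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_skewness_score([1, 2, 3], 3)


class TestScoreUnion:
    def test_or_semantics(self):
        X = np.zeros((2, 20), dtype=np.uint8)
        X[0, [0, 1]] = 1
        X[1, [2, 3]] = 1
        fm = FeatureMatrix(X, ["a", "b"], [f"s{j}" for j in range(20)])
        s = score_union(fm, {0, 1}, "ks")
        assert s == ks_skewness_score([1, 2, 3, 4], 20)

    def test_single_row_identity(self, small_matrix):
        s1 = score_union(small_matrix, {0}, "ks")
        ranks = np.flatnonzero(small_matrix.values[0]) + 1
        assert s1 == ks_skewness_score(ranks, small_matrix.n_samples)

    def test_idempotent_or(self):
        X = np.zeros((2, 10), dtype=np.uint8)
        X[0, [0, 4]] = 1
        X[1, [0, 4]] = 1
        fm = FeatureMatrix(X, ["a", "b"], [f"s{j}" for j in range(10)])
        assert score_union(fm, {0, 1}) == score_union(fm, {0})


class TestIsImprovement:
    def _s(self, p, d, m=5, N=100):
        from driverscan import SkewnessScore

        return SkewnessScore("ks", d, p, m, N)

    def test_smaller_p_wins(self):
        assert is_improvement(self._s(0.001, 0.5), self._s(0.01, 0.5))

    def test_equality_is_not_improvement(self):
        a = self._s(0.01, 0.5)
        assert not is_improvement(a, a)

    def test_statistic_breaks_p_ties(self):
        assert is_improvement(self._s(0.01, 0.9), self._s(0.01, 0.5))

    def test_method_mismatch_errors(self):
        from driverscan import SkewnessScore

        with pytest.raises(ValueError, match="different methods"):
            is_improvement(
                SkewnessScore("wilcoxon", 1.0, 0.01, 5, 100), self._s(0.01, 0.5)
            )
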