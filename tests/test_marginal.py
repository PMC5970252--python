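"""Marginal Wilcoxon/t-test p-values: exactness, ties, shift monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from agcp import TwoSampleMatrix, MarginalMethod, marginal_pvalues, rank_cache
from agcp.marginal import WilcoxonConverter, default_method, ranksum_pvalue_table

from reference import enumerate_exact_pvalue


def make_data(col1, col2):
    return TwoSampleMatrix(np.asarray(col1, float).reshape(-1, 1),
                           np.asarray(col2, float).reshape(-1, 1))


class TestExactWilcoxon:
    def test_fully_separated_two_vs_two(self):
        # enumeration over C(4,2)=6 labellings: rank sum 3 is one of the two
        # extremes, so the two-sided p is 2/6
        data = make_data([1, 2], [3, 4])
        p = marginal_pvalues(data, MarginalMethod("wilcoxon_exact"))
        assert p[0] == pytest.approx(1 / 3, abs=1e-15)

    def test_symmetric_configuration_gives_p_one(self):
        data = make_data([1, 4], [2, 3])  # rank sum equals its null mean
        p = marginal_pvalues(data, MarginalMethod("wilcoxon_exact"))
        assert p[0] == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (4, 7)])
    def test_matches_enumeration_on_random_columns(self, n1, n2, rng):
        for _ in range(20):
            c1 = rng.standard_normal(n1)
            c2 = rng.standard_normal(n2)
            p = marginal_pvalues(make_data(c1, c2),
                                 MarginalMethod("wilcoxon_exact"))[0]
            expected = enumerate_exact_pvalue(list(c1) + list(c2), n1)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_minimum_attainable_p(self):
        # full separation gives the most extreme rank sum; two-sided
        # minimum is 2/C(n, n1) for n1 = n2
        n1 = 5
        data = make_data(np.arange(n1), np.arange(n1) + 100)
        p = marginal_pvalues(data, MarginalMethod("wilcoxon_exact"))[0]
        assert p == pytest.approx(2 / special.comb(2 * n1, n1), rel=1e-12)
        assert p > 0

    def test_pvalues_never_zero_and_table_positive(self):
        table = ranksum_pvalue_table(8, 8)
        w_min, w_max = 8 * 9 // 2, 8 * (32 - 7) // 2
        assert (table[w_min:w_max + 1] > 0).all()

    def test_exact_refused_for_large_groups(self):
        with pytest.raises(ValueError, match="wilcoxon_exact"):
            MarginalMethod("wilcoxon_exact").validate_for(30, 30)

    def test_column_permutation_permutes_output(self, rng):
        x1, x2 = rng.standard_normal((4, 5)), rng.standard_normal((4, 5))
        perm = rng.permutation(5)
        p = marginal_pvalues(TwoSampleMatrix(x1, x2))
        pp = marginal_pvalues(TwoSampleMatrix(x1[:, perm], x2[:, perm]))
        assert np.array_equal(p[perm], pp)


class TestTiesAndFallback:
    def test_tied_columns_fall_back_to_normal(self):
        x1 = np.array([[1.0], [1.0], [2.0]])
        x2 = np.array([[1.0], [3.0], [4.0]])
        data = TwoSampleMatrix(x1, x2)
        conv = WilcoxonConverter(data, MarginalMethod("wilcoxon_exact"))
        assert not conv.exact_cols[0]
        p = marginal_pvalues(data, MarginalMethod("wilcoxon_exact"))
        assert 0 < p[0] <= 1

    def test_constant_column_gives_p_one(self):
        data = make_data([5, 5, 5], [5, 5, 5])
        p = marginal_pvalues(data, MarginalMethod("wilcoxon_normal"))
        assert p[0] == 1.0

    def test_tie_corrected_variance_reduces_sigma(self, rng):
        cont = make_data(rng.standard_normal(6), rng.standard_normal(6))
        tied = make_data([1, 1, 2, 2, 3, 3], [1, 2, 2, 3, 3, 3])
        s_cont = WilcoxonConverter(cont, MarginalMethod("wilcoxon_normal")).sigma[0]
        s_tied = WilcoxonConverter(tied, MarginalMethod("wilcoxon_normal")).sigma[0]
        assert s_tied < s_cont


class TestTTest:
    def test_zero_variance_column_flagged(self):
        x1 = np.column_stack([np.ones(4), np.arange(4.0)])
        x2 = np.column_stack([np.ones(4), np.arange(4.0) + 3])
        with pytest.warns(UserWarning, match="zero pooled variance"):
            p = marginal_pvalues(TwoSampleMatrix(x1, x2),
                                 MarginalMethod("t_test"))
        assert p[0] == 1.0
        assert p[1] < 0.05

    def test_matches_scipy_pooled_ttest(self, rng):
        from scipy import stats
        x1, x2 = rng.standard_normal((7, 4)), rng.standard_normal((9, 4)) + 0.5
        p = marginal_pvalues(TwoSampleMatrix(x1, x2), MarginalMethod("t_test"))
        expected = stats.ttest_ind(x1, x2, equal_var=True).pvalue
        np.testing.assert_allclose(p, expected, rtol=1e-12)


class TestRankCache:
    def test_midrank_example(self):
        data = make_data([3, 1], [2, 2])
        np.testing.assert_array_equal(rank_cache(data)[:, 0], [4, 1, 2.5, 2.5])

    def test_rank_sum_identity_without_ties(self, small_data):
        n = small_data.n
        np.testing.assert_allclose(rank_cache(small_data).sum(axis=0),
                                   n * (n + 1) / 2)

    def test_rank_cache_reproduces_relabelled_statistic(self, rng):
        data = TwoSampleMatrix(rng.standard_normal((5, 6)),
                               rng.standard_normal((7, 6)))
        ranks = rank_cache(data)
        pooled = data.pooled()
        for _ in range(100):
            subset = rng.choice(data.n, size=data.n1, replace=False)
            w_cached = ranks[subset].sum(axis=0)
            rest = [i for i in range(data.n) if i not in set(subset)]
            relabelled = TwoSampleMatrix(pooled[subset], pooled[rest])
            w_direct = rank_cache(relabelled)[: data.n1].sum(axis=0)
            np.testing.assert_allclose(w_cached, w_direct)


class TestDistributionalProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.5, 5.0))
    def test_monotone_shift_weakly_decreases_two_sided_p_at_separation(
        self, seed, delta
    ):
        # a large positive shift drives the two-sided p to its attainable
        # minimum; p is weakly smaller than for the unshifted column
        r = np.random.default_rng(seed)
        c1, c2 = r.standard_normal(5), r.standard_normal(5)
        p0 = marginal_pvalues(make_data(c1, c2))[0]
        p_shift = marginal_pvalues(make_data(c1 + 100 + delta, c2))[0]
        assert p_shift <= p0 or p0 == p_shift
        assert p_shift == pytest.approx(2 / special.comb(10, 5), rel=1e-12)

    def test_exact_pvalues_stochastically_conservative_under_null(self, rng):
        # discrete null: P(p <= 0.05) <= 0.05 up to Monte-Carlo error
        m = 4000
        data = TwoSampleMatrix(rng.standard_normal((5, m)),
                               rng.standard_normal((5, m)))
        p = marginal_pvalues(data, MarginalMethod("wilcoxon_exact"))
        frac = (p <= 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / m)

    def test_default_method_switches_on_group_size(self):
        assert default_method(10, 10).name == "wilcoxon_exact"
        assert default_method(25, 25).name == "wilcoxon_exact"
        assert default_method(26, 26).name == "wilcoxon_normal"
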