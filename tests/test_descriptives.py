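import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from evanomaly.descriptives import (TIER_MARGINAL, TIER_NS, TIER_SIGNIFICANT,
                                    abs_var_diff, coefficient_of_variation,
                                    p_value_tier, protein_ttest,
                                    quadratic_fit, venn_regions,
                                    within_group_variance)

vals3 = st.lists(st.floats(min_value=-100, max_value=100), min_size=3,
                 max_size=3)


def pooled_t_pvalue(a, b):
    """Textbook pooled two-sample t-test, written out from the formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * sps.t.sf(abs(t), na + nb - 2)


class TestProteinTtest:
    def test_identical_groups(self):
        p, tier = protein_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0) and tier == TIER_NS

    def test_extreme_separation(self):
        p, tier = protein_ttest([0.0, 0.001, -0.001], [10.0, 10.001, 9.999])
        assert p < 0.05 and tier == TIER_SIGNIFICANT

    def test_zero_variance_conventions(self):
        assert protein_ttest([5.0, 5.0], [5.0, 5.0]) == (1.0, TIER_NS)
        p, tier = protein_ttest([5.0, 5.0], [7.0, 7.0])
        assert p == 0.0 and tier == TIER_SIGNIFICANT

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(vals3, vals3)
    def test_matches_closed_form_pooled_formula(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        p, _ = protein_ttest(a, b, variant="student")
        assert p == pytest.approx(pooled_t_pvalue(a, b), abs=1e-12)

    def test_symmetry(self):
        a, b = [1.0, 4.0, 2.5], [3.0, 6.0, 5.5]
        assert protein_ttest(a, b) == protein_ttest(b, a)

    def test_welch_variant(self):
        a, b = [1.0, 4.0, 2.5], [3.0, 6.0, 15.5]
        p, _ = protein_ttest(a, b, variant="welch")
        assert p == pytest.approx(
            sps.ttest_ind(a, b, equal_var=False).pvalue)

    def test_tier_boundaries_half_open(self):
        assert p_value_tier(0.05) == TIER_MARGINAL
        assert p_value_tier(0.1) == TIER_NS
        assert p_value_tier(0.049999) == TIER_SIGNIFICANT


class TestVarianceAndCV:
    def test_textbook_values(self):
        assert within_group_variance([1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert within_group_variance([4.0, 4.0, 4.0]) == 0.0

    @pytest.mark.parametrize("v1,v2,expected", [
        (13.0, 0.72, 12.28),   # largest published ctrl-vs-doped variance gap
        (8.47, 2.79, 5.68),
        (3.3, 3.3, 0.0),
    ])
    def test_abs_var_diff(self, v1, v2, expected):
        assert abs_var_diff(v1, v2) == pytest.approx(expected)
        assert abs_var_diff(v2, v1) == abs_var_diff(v1, v2)

    def test_cv_values(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)
        assert math.isnan(coefficient_of_variation([-1.0, 0.0, 1.0]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1, max_value=100), min_size=2,
                    max_size=8))
    def test_cv_oracle(self, v):
        arr = np.asarray(v)
        assert coefficient_of_variation(v) == pytest.approx(
            arr.std(ddof=1) / arr.mean())


class TestQuadraticFit:
    def test_exact_parabola(self):
        x = np.linspace(-3, 3, 7)
        fit = quadratic_fit(x, x ** 2)
        assert (fit.a, fit.b, fit.c) == pytest.approx((1.0, 0.0, 0.0),
                                                      abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        fit = quadratic_fit([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert (fit.a, fit.b) == pytest.approx((0.0, 0.0), abs=1e-9)
        assert fit.c == pytest.approx(5.0)
        assert fit.r_squared == 0.0

    def test_all_x_identical_raises(self):
        with pytest.raises(ValueError, match="identical"):
            quadratic_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0, 2, 25)
            y = rng.normal(0, 1, 25) + 0.7 * x ** 2 - 1.2 * x + 3
            V = np.vander(x, 3, increasing=True)          # [1, x, x^2]
            beta = np.linalg.solve(V.T @ V, V.T @ y)
            fit = quadratic_fit(x, y)
            np.testing.assert_allclose([fit.c, fit.b, fit.a], beta,
                                       atol=1e-8)


class TestVennRegions:
    def test_disjoint_sets(self):
        regions = venn_regions({"a": {"P1"}, "b": {"P2"}, "c": {"P3"}})
        assert regions["a&b"] == regions["a&c"] == regions["b&c"] == 0
        assert regions["a&b&c"] == 0
        assert regions["a"] == regions["b"] == regions["c"] == 1

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(5)
        universe = [f"P{i}" for i in range(30)]
        sets = {n: set(rng.choice(universe, rng.integers(1, 25),
                                  replace=False)) for n in "abc"}
        regions = venn_regions(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_isoforms_are_distinct(self):
        regions = venn_regions({"a": {"P24821"}, "b": {"P24821-4"}})
        assert regions["a&b"] == 0

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            venn_regions({"a": set()})
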