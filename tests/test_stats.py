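"""Group-comparison statistics: hand oracles, scipy cross-checks, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from iivd.errors import DegenerateStatisticError
from iivd.stats import (
    benjamini_hochberg,
    bh_adjust,
    chi_square,
    cohens_d_pooled,
    compare_continuous,
    compare_groups,
    pearson_r,
    pooled_t,
    variance_f_test,
    welch_t,
)

summary = st.tuples(
    st.floats(-5, 5), st.floats(0.5, 4.0), st.integers(5, 200),
    st.floats(-5, 5), st.floats(0.5, 4.0), st.integers(5, 200),
)


class TestTTests:
    def test_identical_summaries_give_zero(self):
        t, df = pooled_t(1.0, 2.0, 10, 1.0, 2.0, 10)
        assert t == 0.0 and df == 18

    def test_pooled_hand_arithmetic_three_vs_three(self):
        # x1=(1,2,3), x2=(2,4,6): sp^2 = 2.5, t = -2/sqrt(2.5 * 2/3)
        t, df = pooled_t(2.0, 1.0, 3, 4.0, 2.0, 3)
        assert t == pytest.approx(-2.0 / np.sqrt(2.5 * (2 / 3)), abs=1e-12)
        assert df == 4

    def test_zero_pooled_variance_unequal_means_is_error(self):
        with pytest.raises(DegenerateStatisticError):
            pooled_t(1.0, 0.0, 5, 2.0, 0.0, 5)

    @given(st.floats(-3, 3), st.floats(0.5, 3), st.integers(5, 50))
    def test_welch_equals_pooled_at_equal_variance_and_n(self, m1, s, n):
        tw, dfw = welch_t(m1, s, n, 0.0, s, n)
        tp, dfp = pooled_t(m1, s, n, 0.0, s, n)
        assert tw == pytest.approx(tp, abs=1e-12)
        assert dfw == pytest.approx(dfp, abs=1e-9)

    @given(summary)
    def test_sign_reverses_when_groups_swap(self, s):
        m1, s1, n1, m2, s2, n2 = s
        t12, _ = welch_t(m1, s1, n1, m2, s2, n2)
        t21, _ = welch_t(m2, s2, n2, m1, s1, n1)
        assert t12 == pytest.approx(-t21, abs=1e-9)

    @given(summary)
    def test_t_equals_d_times_sqrt_n_ratio(self, s):
        """Algebraic identity: t = d * sqrt(n1*n2/(n1+n2)) for the pooled test."""
        m1, s1, n1, m2, s2, n2 = s
        t, _ = pooled_t(m1, s1, n1, m2, s2, n2)
        d = cohens_d_pooled(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(d * np.sqrt(n1 * n2 / (n1 + n2)), abs=1e-9)


class TestVarianceGate:
    def test_equal_variances_equal_n_give_p_one(self):
        assert variance_f_test(2.0, 11, 2.0, 11) == 1.0

    def test_matches_f_distribution_cdf(self):
        # s1^2=4 (n=11) vs s2^2=1 (n=11): F=4 with (10, 10) df
        p = variance_f_test(2.0, 11, 1.0, 11)
        assert p == pytest.approx(2 * sps.f.sf(4.0, 10, 10), abs=1e-12)

    def test_monotone_decreasing_in_variance_ratio(self):
        ps = [variance_f_test(s1, 20, 1.0, 20) for s1 in (1.0, 1.5, 2.0, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_zero_variance_forces_welch(self):
        assert variance_f_test(0.0, 10, 1.0, 10) == 0.0
        kind, _, _, _ = compare_continuous(1.0, 0.0, 10, 2.0, 1.0, 10)
        assert kind == "welch-t"


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        stat, df, p = chi_square([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_expected_count_oracle(self):
        """[[10,20],[20,10]]: every expected count is 15 by symmetry."""
        obs = np.array([[10, 20], [20, 10]], dtype=float)
        expected = 15.0
        oracle = ((obs - expected) ** 2 / expected).sum()
        stat, df, p = chi_square(obs)
        assert stat == pytest.approx(oracle, abs=1e-12)
        assert df == 1

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            obs = rng.integers(1, 40, size=(2, 3))
            stat, df, p = chi_square(obs)
            ref = sps.chi2_contingency(obs, correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_margin_is_error(self):
        with pytest.raises(DegenerateStatisticError):
            chi_square([[0, 0], [5, 10]])


def direct_bh_rule(pvals, q):
    """Independent oracle: literal evaluation of the step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / m:
            k_star = rank
    if k_star == 0:
        return [False] * m
    threshold = pvals[order[k_star - 1]]
    return [p <= threshold for p in pvals]


class TestBenjaminiHochberg:
    def test_all_ones_nothing_flagged(self):
        assert not benjamini_hochberg([1.0] * 5).any()

    def test_boundary_family_all_flagged(self):
        # p(5) = 0.05 <= 5 * 0.05/5, so the whole family is significant
        flags = benjamini_hochberg([0.001, 0.01, 0.02, 0.04, 0.05], q=0.05)
        assert flags.all()

    def test_single_p_reduces_to_raw_threshold(self):
        assert benjamini_hochberg([0.049], q=0.05).all()
        assert not benjamini_hochberg([0.051], q=0.05).any()

    def test_empty_input(self):
        assert benjamini_hochberg([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.randoms())
    def test_permutation_invariance(self, pvals, rnd):
        flags = benjamini_hochberg(pvals)
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        flags_perm = benjamini_hochberg([pvals[i] for i in perm])
        assert [flags[i] for i in perm] == list(flags_perm)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bonferroni_subset_bh_subset_raw(self, pvals):
        q = 0.05
        m = len(pvals)
        bh = benjamini_hochberg(pvals, q)
        bonf = np.array([p <= q / m for p in pvals])
        raw = np.array([p <= q for p in pvals])
        assert (bh | ~bonf).all()  # bonferroni implies BH
        assert (raw | ~bh).all()  # BH implies raw

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_matches_direct_rule_evaluation(self, pvals):
        assert list(benjamini_hochberg(pvals)) == direct_bh_rule(pvals, 0.05)

    def test_adjusted_p_consistent_with_flags(self):
        rng = np.random.default_rng(4)
        p = rng.random(15) ** 2
        adj = bh_adjust(p)
        flags = benjamini_hochberg(p, q=0.05)
        assert ((adj <= 0.05) == flags).all()


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == 1.0
        assert pearson_r(x, -2 * x + 3)[0] == -1.0

    def test_hand_sum_formula_five_points(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 7.0]
        # sum dx*dy = 12, sum dx^2 = 10, sum dy^2 = 21.2
        r, p = pearson_r(x, y)
        assert r == pytest.approx(12.0 / np.sqrt(10.0 * 21.2), abs=1e-12)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_is_error(self):
        with pytest.raises(DegenerateStatisticError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareGroups:
    def _toy(self, rng, n=60):
        g = np.repeat(["a", "b"], n)
        return pd.DataFrame(
            {
                "group": g,
                "x": rng.standard_normal(2 * n),
                "y": np.where(g == "b", 1.0, 0.0) + rng.standard_normal(2 * n),
                "cat": rng.choice(["u", "v"], 2 * n),
            }
        )

    def test_identical_groups_have_unit_p(self):
        df = pd.DataFrame(
            {"group": ["a"] * 4 + ["b"] * 4, "x": [1.0, 2, 3, 4] * 2}
        )
        rep = compare_groups(df, "group", ["x"])
        assert rep["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert rep["p_raw"].iloc[0] == pytest.approx(1.0)
        assert not rep["significant"].any()

    def test_composition_matches_unit_operations(self):
        rng = np.random.default_rng(7)
        df = self._toy(rng)
        rep = compare_groups(df, "group", ["x", "y", "cat"]).set_index("variable")
        a, b = df[df.group == "a"], df[df.group == "b"]
        for var in ("x", "y"):
            kind, t, dof, p = compare_continuous(
                a[var].mean(), a[var].std(ddof=1), len(a),
                b[var].mean(), b[var].std(ddof=1), len(b),
            )
            assert rep.loc[var, "test"] == kind
            assert rep.loc[var, "statistic"] == pytest.approx(t, abs=1e-12)
            assert rep.loc[var, "p_raw"] == pytest.approx(p, rel=1e-9)
        counts = pd.crosstab(df["group"], df["cat"]).to_numpy()
        stat, _, _ = chi_square(counts)
        assert rep.loc["cat", "statistic"] == pytest.approx(stat, rel=1e-12)
        assert np.isnan(rep.loc["cat", "cohens_d"])

    def test_absent_variable_skipped(self):
        rng = np.random.default_rng(8)
        rep = compare_groups(self._toy(rng), "group", ["x", "nope"])
        assert list(rep["variable"]) == ["x"]
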