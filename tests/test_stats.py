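"""Statistical battery: summaries, t procedures, Dunnett, Pearson, Bland–Altman."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gcxquant import (
    anova_dunnett,
    bland_altman,
    group_summary,
    paired_t_ci,
    pearson_correlation,
    unpaired_t_test,
)

from conftest import scaled_differences

finite_floats = st.floats(-1e3, 1e3, allow_nan=False)


class TestGroupSummary:
    def test_hand_arithmetic(self):
        s = group_summary([1.0, 2.0, 3.0])
        assert s.mean == 2.0
        assert s.sem == pytest.approx(1.0 / np.sqrt(3))

    def test_constant_vector_zero_sem(self):
        assert group_summary([5.0] * 10).sem == 0.0

    def test_large_sample_sem_approaches_sigma_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, 20000)
        s = group_summary(x)
        assert s.sem == pytest.approx(2.0 / np.sqrt(20000), rel=0.05)

    def test_n1_rejected(self):
        with pytest.raises(ValueError):
            group_summary([1.0])


class TestUnpairedT:
    def test_identical_groups(self):
        t, df, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_pair_matches_direct_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        t, df, p = unpaired_t_test(a, b)
        # brute-force evaluation of the pooled formula
        sp2 = ((2) * a.var(ddof=1) + (2) * b.var(ddof=1)) / 4
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        assert t == pytest.approx(t_ref)
        assert df == 4
        assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), 4))

    def test_sign_flips_when_groups_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        t1, _, p1 = unpaired_t_test(a, b)
        t2, _, p2 = unpaired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            unpaired_t_test([1.0, 1.0], [2.0, 2.0])

    def test_welch_option(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 5, 20)
        t, df, p = unpaired_t_test(a, b, equal_var=False)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestPairedT:
    def test_worked_example_statistics(self):
        d = scaled_differences(0.027, 0.203, 20)
        mean, ci, t, df, p = paired_t_ci(d)
        assert t == pytest.approx(0.5948, abs=1e-3)
        assert df == 19
        assert ci[1] == pytest.approx(0.122, abs=1e-3)
        assert ci[0] == pytest.approx(-0.068, abs=1e-3)
        assert p == pytest.approx(0.56, abs=0.01)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        _, _, t, df, p = paired_t_ci(a - b)
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_all_zero_differences(self):
        mean, ci, t, df, p = paired_t_ci(np.zeros(10))
        assert (mean, t, p) == (0.0, 0.0, 1.0)
        assert ci == (0.0, 0.0)


class TestBlandAltman:
    def test_identical_vectors(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.loa == (0.0, 0.0)

    def test_matches_spreadsheet_formulas(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(5, 1, 30), rng.normal(5, 1, 30)
        res = bland_altman(a, b)
        d = a - b
        assert res.bias == pytest.approx(d.mean())
        assert res.sd == pytest.approx(d.std(ddof=1))
        assert res.loa[0] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert res.loa[1] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_agrees_with_paired_t_on_bias_and_sd(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        res = bland_altman(a, b)
        mean, ci, t, df, p = paired_t_ci(a - b)
        assert res.bias == pytest.approx(mean)
        assert res.t == pytest.approx(t)
        assert res.ci95 == pytest.approx(ci)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_loa_symmetric_about_bias(self):
        rng = np.random.default_rng(8)
        res = bland_altman(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        assert res.loa[0] + res.loa[1] == pytest.approx(2 * res.bias)


class TestAnovaDunnett:
    def test_k2_equals_pooled_t(self):
        rng = np.random.default_rng(9)
        ctrl, trt = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        _, _, p_pooled = unpaired_t_test(trt, ctrl)
        res = anova_dunnett([ctrl, trt], labels=["c", "t"], control_index=0, seed=1)
        assert res.comparisons[0][2] == pytest.approx(p_pooled, abs=2e-3)

    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = anova_dunnett([g, g, g], seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        for _, _, p in res.comparisons:
            assert p == pytest.approx(1.0, abs=1e-6)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(10)
        for rep in range(20):
            groups = [rng.normal(0, 1, 6) for _ in range(4)]
            res = anova_dunnett(groups, seed=rep)
            nu = 4 * 6 - 4
            for _, stat, p_adj in res.comparisons:
                p_raw = 2 * sps.t.sf(abs(stat), nu)
                assert p_adj >= p_raw - 1e-12

    def test_control_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            anova_dunnett([[1.0, 2.0], [2.0, 3.0]], control_index=5)

    def test_seed_recorded_and_reproducible(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(0, 1, 6) for _ in range(3)]
        r1 = anova_dunnett(groups, seed=42)
        r2 = anova_dunnett(groups, seed=42)
        assert r1.seed == 42
        assert r1.comparisons == r2.comparisons


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_small_set_matches_direct_formula(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 4.0])
        r, p = pearson_correlation(x, y)
        r_ref = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(r_ref)
        t_ref = r_ref * np.sqrt((3 - 2) / (1 - r_ref**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), 1))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPValueProperties:
    @settings(deadline=None, max_examples=30)
    @given(st.lists(finite_floats, min_size=3, max_size=15),
           st.lists(finite_floats, min_size=3, max_size=15))
    def test_unpaired_p_in_unit_interval(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        _, _, p = unpaired_t_test(a, b)
        assert 0.0 <= p <= 1.0

    @settings(deadline=None, max_examples=30)
    @given(st.lists(finite_floats, min_size=2, max_size=20))
    def test_paired_ci_contains_point_estimate(self, d):
        mean, ci, t, df, p = paired_t_ci(d)
        assert ci[0] - 1e-9 <= mean <= ci[1] + 1e-9
        assert 0.0 <= p <= 1.0
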