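"""Statistical battery: t tests, Cohen's d, Levene, ANOVA, regression, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st_h
from scipy import stats as sps

from motoriiv import (
    SummaryStats,
    anova_group_by_sex,
    chi_square_counts,
    cohens_d_from_summaries,
    compare_groups,
    fdr_adjust,
    levene_test,
    multiple_regression,
    relative_strength_pct,
    t_test_from_summaries,
)
from motoriiv.reference import GROUP_SUMMARIES
from motoriiv.stats import pooled_sd, welch_df


class TestTTests:
    def test_equal_means_give_zero_t(self):
        s1 = SummaryStats("a", 20, 5.0, 1.0)
        s2 = SummaryStats("b", 25, 5.0, 2.0)
        for variant in ("pooled", "welch"):
            res = t_test_from_summaries(s1, s2, variant)
            assert res.value == pytest.approx(0.0)
            assert res.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "var,variant,expected_t",
        [
            ("iiv", "welch", -3.91),
            ("visuospatial", "pooled", 3.89),
            ("processing_speed", "welch", -3.00),
            ("executive_function", "welch", -3.30),
        ],
    )
    def test_published_summary_t_values(self, var, variant, expected_t):
        """t statistics recomputed from the published group means/SDs/n."""
        s_stroke, s_healthy = GROUP_SUMMARIES[var]
        res = t_test_from_summaries(s_stroke, s_healthy, variant)
        assert res.value == pytest.approx(expected_t, abs=0.005)

    def test_welch_equals_pooled_for_equal_n_and_sd(self):
        s1 = SummaryStats("a", 20, 4.0, 2.5)
        s2 = SummaryStats("b", 20, 6.0, 2.5)
        tp = t_test_from_summaries(s1, s2, "pooled")
        tw = t_test_from_summaries(s1, s2, "welch")
        assert tw.value == pytest.approx(tp.value, rel=1e-12)
        assert tw.df == pytest.approx(tp.df)

    def test_round_trip_matches_raw_data_test(self):
        rng = np.random.default_rng(8)
        x1, x2 = rng.normal(5, 2, 30), rng.normal(6, 3, 20)
        s1 = SummaryStats.from_values("a", x1)
        s2 = SummaryStats.from_values("b", x2)
        for variant, equal_var in (("pooled", True), ("welch", False)):
            res = t_test_from_summaries(s1, s2, variant)
            ref = sps.ttest_ind(x2, x1, equal_var=equal_var)
            assert res.value == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_zero_variance_rejected(self):
        s = SummaryStats("a", 10, 5.0, 0.0)
        with pytest.raises(ValueError):
            t_test_from_summaries(s, s, "pooled")


class TestCohensD:
    def test_identical_groups_give_zero(self):
        s = SummaryStats("a", 10, 5.0, 1.0)
        assert cohens_d_from_summaries(s, s) == 0.0

    @pytest.mark.parametrize(
        "var,expected_d",
        [
            ("iiv", 0.63), ("visuospatial", 0.84), ("processing_speed", 0.46),
            ("executive_function", 0.58), ("drs2", 0.96),
            ("education_years", 0.36),
        ],
    )
    def test_published_summary_d_values(self, var, expected_d):
        s_stroke, s_healthy = GROUP_SUMMARIES[var]
        d = cohens_d_from_summaries(s_stroke, s_healthy)
        assert d == pytest.approx(expected_d, abs=0.005)

    def test_d_from_raw_equals_d_from_summaries(self):
        rng = np.random.default_rng(9)
        x1, x2 = rng.normal(5, 2, 40), rng.normal(7, 2, 25)
        s1 = SummaryStats.from_values("a", x1)
        s2 = SummaryStats.from_values("b", x2)
        sp = pooled_sd(s1, s2)
        assert cohens_d_from_summaries(s1, s2) == pytest.approx(
            abs(x1.mean() - x2.mean()) / sp)


class TestLevene:
    def test_identical_groups_give_zero_w(self):
        res = levene_test({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res.value == pytest.approx(0.0)

    def test_shift_invariance(self):
        res = levene_test({"a": [1, 2, 3, 4], "b": [11, 12, 13, 14]})
        assert res.value == pytest.approx(0.0)

    def test_hand_computed_w_on_small_fixture(self):
        """Definitional formula on 2 x 5 values: W = 8 * 3.6 / 14."""
        res = levene_test({"a": [1, 2, 3, 4, 5], "b": [10, 12, 14, 16, 18]})
        assert res.value == pytest.approx(2.0571428571, abs=1e-9)
        assert res.df == (1, 8)

    def test_constant_groups_rejected(self):
        with pytest.raises(ValueError):
            levene_test({"a": [2.0, 2.0, 2.0], "b": [5.0, 5.0, 5.0]})


class TestAnova:
    @staticmethod
    def _frame(y, g, s):
        return pd.DataFrame({"iiv": y, "group": g, "sex": s})

    def test_hand_worked_2x2_decomposition(self):
        """Balanced 2 obs/cell toy table: SS and F match hand computation
        (SS_group 10.125, SS_sex 21.125, SS_int 1.125, SSE 6.5 on 4 df)."""
        y = [1, 2, 3, 5, 2, 4, 6, 8]
        g = ["a"] * 4 + ["b"] * 4
        s = ["F", "F", "M", "M"] * 2
        res = anova_group_by_sex(self._frame(y, g, s))
        assert res["group"].value == pytest.approx(10.125 / 1.625, abs=1e-9)
        assert res["sex"].value == pytest.approx(21.125 / 1.625, abs=1e-9)
        assert res["interaction"].value == pytest.approx(1.125 / 1.625, abs=1e-9)
        assert res["group"].effect_size == pytest.approx(10.125 / 16.625, abs=1e-9)
        assert res["group"].df == (1, 4)

    def test_matches_statsmodels_type3_on_unbalanced_data(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(12)
        n1, n2 = 66, 32
        df = self._frame(
            rng.normal(5, 2, n1 + n2),
            ["stroke"] * n1 + ["healthy"] * n2,
            rng.choice(["F", "M"], n1 + n2),
        )
        ours = anova_group_by_sex(df)
        fit = smf.ols("iiv ~ C(group, Sum) * C(sex, Sum)", data=df).fit()
        ref = anova_lm(fit, typ=3)
        assert ours["group"].value == pytest.approx(
            ref.loc["C(group, Sum)", "F"], rel=1e-8)
        assert ours["sex"].value == pytest.approx(
            ref.loc["C(sex, Sum)", "F"], rel=1e-8)
        assert ours["interaction"].value == pytest.approx(
            ref.loc["C(group, Sum):C(sex, Sum)", "F"], rel=1e-8)

    def test_planted_group_effect_raises_group_f_only(self):
        rng = np.random.default_rng(13)
        n = 200
        g = rng.choice(["a", "b"], n)
        s = rng.choice(["F", "M"], n)
        y = rng.normal(0, 1, n) + 1.5 * (g == "b")
        res = anova_group_by_sex(self._frame(y, g, s))
        assert res["group"].p_raw < 1e-6
        assert res["interaction"].p_raw > 0.01

    def test_partial_eta_squared_in_unit_interval(self):
        rng = np.random.default_rng(14)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 40
            df = self._frame(rng.normal(size=n), rng.choice(["a", "b"], n),
                             rng.choice(["F", "M"], n))
            for t in anova_group_by_sex(df).values():
                assert 0.0 <= t.effect_size <= 1.0

    def test_empty_cell_rejected(self):
        df = self._frame([1, 2, 3, 4], ["a", "a", "b", "b"],
                         ["F", "M", "F", "F"])
        with pytest.raises(ValueError, match="cell"):
            anova_group_by_sex(df)


class TestRegression:
    def test_single_predictor_beta_is_pearson_r(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=50)
        y = 2.0 * x + rng.normal(size=50)
        res = multiple_regression(y, pd.DataFrame({"x": x}))
        r = np.corrcoef(x, y)[0, 1]
        assert res.coef.loc["x", "beta"] == pytest.approx(r, rel=1e-9)

    def test_exact_linear_function_gives_r2_one(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = 1.0 + 2.0 * X.a - 3.0 * X.b + 0.5 * X.c
        res = multiple_regression(y, X)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_on_printed_fixture(self):
        """8-row fixture: coefficients, SEs and t equal a brute-force
        normal-equations solve."""
        X = pd.DataFrame({
            "memory": [5.0, 7.0, 4.0, 8.0, 6.0, 3.0, 9.0, 5.5],
            "speed": [31.0, 45.0, 52.0, 28.0, 39.0, 61.0, 25.0, 44.0],
        })
        y = np.array([4.2, 6.8, 7.9, 3.1, 5.5, 9.4, 2.8, 6.1])
        res = multiple_regression(y, X)
        M = np.column_stack([np.ones(8), X.to_numpy()])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        resid = y - M @ beta
        sigma2 = resid @ resid / (8 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(M.T @ M)))
        assert np.allclose(res.coef["b"], beta, atol=1e-9)
        assert np.allclose(res.coef["se_b"], se, atol=1e-9)
        assert np.allclose(res.coef["t"], beta / se, atol=1e-9)

    def test_beta_invariant_to_affine_predictor_rescaling(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["u", "v"])
        y = X.u - 0.5 * X.v + rng.normal(size=40)
        r1 = multiple_regression(y, X)
        X2 = X.copy()
        X2["u"] = 100.0 * X2["u"] + 7.0
        r2 = multiple_regression(y, X2)
        assert np.allclose(r1.coef["beta"].drop("const"),
                           r2.coef["beta"].drop("const"), atol=1e-9)
        assert r1.r_squared == pytest.approx(r2.r_squared, rel=1e-12)

    def test_collinear_design_rejected_naming_columns(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=20)
        X = pd.DataFrame({"x": x, "x_copy": 2.0 * x})
        with pytest.raises(ValueError, match="x_copy"):
            multiple_regression(rng.normal(size=20), X)

    def test_incomplete_cases_dropped_with_warning(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame({"x": rng.normal(size=20)})
        X.loc[3, "x"] = np.nan
        with pytest.warns(UserWarning, match="1 incomplete"):
            res = multiple_regression(rng.normal(size=20), X)
        assert res.n == 19


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_step_up_hand_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(st_h.lists(st_h.floats(0.0, 1.0), min_size=2, max_size=20))
    def test_monotone_and_bounded(self, ps):
        adj = fdr_adjust(ps)
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCovariatesAndCounts:
    def test_equal_limbs_give_100pct(self):
        assert relative_strength_pct(24.0, 24.0) == pytest.approx(100.0)

    def test_ratio_example(self):
        assert relative_strength_pct(18.0, 24.0) == pytest.approx(75.0)

    def test_missing_or_zero_denominator_gives_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(relative_strength_pct(18.0, 0.0))
        with pytest.warns(UserWarning):
            assert np.isnan(relative_strength_pct(np.nan, 24.0))

    def test_chi_square_independent_table_is_zero(self):
        res = chi_square_counts([[10, 10], [20, 20]])
        assert res.value == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)


class TestGating:
    def test_levene_gating_selects_welch_under_heteroscedasticity(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame({
            "group": ["stroke"] * 60 + ["healthy"] * 60,
            "y": np.r_[rng.normal(5, 8, 60), rng.normal(5, 1, 60)],
            "z": np.r_[rng.normal(5, 2, 60), rng.normal(7, 2, 60)],
        })
        table = compare_groups(df, ["y", "z"]).set_index("variable")
        assert table.loc["y", "variant"] == "welch"
        assert table.loc["z", "variant"] == "pooled"

    def test_forced_variant_override(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame({
            "group": ["stroke"] * 30 + ["healthy"] * 30,
            "y": rng.normal(5, 2, 60),
        })
        pooled = compare_groups(df, ["y"], gating="pooled")
        welch = compare_groups(df, ["y"], gating="welch")
        assert pooled["variant"].iloc[0] == "pooled"
        assert welch["variant"].iloc[0] == "welch"
        assert pooled["df"].iloc[0] == 58
        assert welch["df"].iloc[0] <= 58

    def test_welch_df_between_min_and_pooled(self):
        s1 = SummaryStats("a", 66, 6.61, 5.39)
        s2 = SummaryStats("b", 32, 3.74, 1.78)
        df = welch_df(s1, s2)
        assert min(s1.n, s2.n) - 1 <= df <= s1.n + s2.n - 2
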