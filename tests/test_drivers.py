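"""CVs, collinearity screening, model fitting, AICc selection, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor
import statsmodels.api as sm

from tempbeta.drivers import (
    akaike_weights,
    aicc_from_loglik,
    backward_stepwise,
    breusch_pagan,
    coefficient_of_variation,
    exhaustive_ranking,
    fit_glm,
    predictor_summary,
    spearman_screen,
    vif,
)
from tempbeta.errors import InsufficientDataError, ValidationError

from _oracles import brute_aicc, brute_ols


def _design(rng, n, p, names=None):
    names = names or [f"x{j}" for j in range(p)]
    return pd.DataFrame(rng.normal(size=(n, p)), columns=names)


class TestCV:
    def test_zero_variance(self):
        assert coefficient_of_variation([10, 10, 10]) == 0.0

    def test_hand_value(self):
        # sd = √2, mean = 3 → 47.14%
        assert coefficient_of_variation([2, 4]) == pytest.approx(47.14, abs=0.01)

    def test_zero_mean_is_undefined(self):
        with pytest.raises(ValidationError):
            coefficient_of_variation([0, 0, 0])

    def test_single_value_insufficient(self):
        with pytest.raises(InsufficientDataError):
            coefficient_of_variation([3.0])

    def test_predictor_summary_shapes_the_design(self):
        long = pd.DataFrame({
            "meadow": ["A"] * 3 + ["B"] * 3, "time": [1, 2, 3] * 2,
            "leaf_biomass": [10, 12, 14, 20, 20, 20],
            "cover": [50, 60, 70, 40, 45, 50],
            "shoot_density": [600] * 6, "epiphytic_load": [0.2, 0.3, 0.4] * 2,
            "sst": [18, 20, 22, 21, 23, 25], "par": [30] * 6,
        })
        out = predictor_summary(long)
        assert list(out.index) == ["A", "B"]
        assert out.loc["B", "cv_leaf_biomass"] == 0.0
        assert out.loc["A", "mean_sst"] == pytest.approx(20.0)


class TestScreen:
    def test_identical_columns_keep_higher_priority(self):
        df = pd.DataFrame({"p1": [1, 2, 3, 4], "p2": [2, 4, 6, 8]})
        retained, rho = spearman_screen(df, priority=("p1", "p2"))
        assert retained == ["p1"]
        assert rho.loc["p1", "p2"] == pytest.approx(1.0)

    def test_uncorrelated_pair_both_kept(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"p1": rng.normal(size=30), "p2": rng.normal(size=30)})
        retained, rho = spearman_screen(df, priority=("p1", "p2"))
        assert retained == ["p1", "p2"]
        assert rho.loc["p1", "p2"] ** 2 <= 0.6

    def test_correlated_pair_with_independent_third(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=40)
        df = pd.DataFrame({
            "p1": base,
            "p2": base + rng.normal(scale=0.1, size=40),   # ρ² > 0.6 with p1
            "p3": rng.normal(size=40),
        })
        from scipy.stats import spearmanr
        assert spearmanr(df.p1, df.p2).statistic ** 2 > 0.6
        retained, _ = spearman_screen(df, priority=("p1", "p2", "p3"))
        assert retained == ["p1", "p3"]

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"p1": [1, 2, 3, 4], "p2": [7, 7, 7, 7]})
        with pytest.warns(UserWarning, match="constant"):
            retained, _ = spearman_screen(df, priority=("p1", "p2"))
        assert retained == ["p1"]


class TestVIF:
    def test_orthogonal_design_all_one(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]})
        assert vif(df).max() == pytest.approx(1.0)

    def test_duplicated_column_infinite(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        with pytest.warns(UserWarning, match="collinear"):
            assert np.isinf(vif(df)).all()

    def test_closed_form_and_statsmodels_agree(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=60)
        x2 = 0.6 * x1 + rng.normal(scale=0.8, size=60)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        got = vif(df)
        r = np.corrcoef(x1, x2)[0, 1]
        assert got["x1"] == pytest.approx(1 / (1 - r ** 2))
        X = sm.add_constant(df.to_numpy())
        assert got["x1"] == pytest.approx(variance_inflation_factor(X, 1))
        assert got["x2"] == pytest.approx(variance_inflation_factor(X, 2))


class TestFitGLM:
    def test_exact_linear_relation_recovered(self):
        x = pd.DataFrame({"x": np.arange(9, dtype=float)})
        y = pd.Series(0.8 - 0.003 * x["x"], name="beta_sor")
        fit = fit_glm(y, x)
        assert fit.coefficients.loc["x", "estimate"] == pytest.approx(-0.003)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_intercept_only_loglik_matches_gaussian_mle(self):
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(5, 2, size=25))
        fit = fit_glm(y, pd.DataFrame(index=y.index))
        assert fit.coefficients.loc["intercept", "estimate"] == pytest.approx(y.mean())
        _, _, ll = brute_ols(y.to_numpy(), np.empty((25, 0)))
        assert fit.loglik == pytest.approx(ll)

    def test_aicc_correction_at_n9_k3(self):
        rng = np.random.default_rng(1)
        x = _design(rng, 9, 1)
        y = pd.Series(rng.normal(size=9))
        fit = fit_glm(y, x)
        assert fit.k == 3
        assert fit.aicc - fit.aic == pytest.approx(4.8)
        assert aicc_from_loglik(fit.loglik, 9, 3) == pytest.approx(
            brute_aicc(fit.loglik, 9, 3))

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n, p = int(rng.integers(8, 20)), int(rng.integers(1, 4))
            X = _design(rng, n, p)
            y = pd.Series(rng.normal(size=n))
            fit = fit_glm(y, X)
            beta, _, ll = brute_ols(y.to_numpy(), X.to_numpy())
            np.testing.assert_allclose(fit.coefficients["estimate"].to_numpy(),
                                       beta, atol=1e-8)
            assert fit.loglik == pytest.approx(ll)

    def test_singular_design_raises(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 4, 6, 8, 10, 12]})
        y = pd.Series(np.arange(6.0))
        with pytest.raises(ValidationError, match="aliased"):
            fit_glm(y, df)


class TestSelection:
    def test_akaike_weights_closed_form_and_shift_invariance(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=5e-5)
        assert akaike_weights([0.0, 2.0]) == pytest.approx(w)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_candidate_count_for_three_predictors(self):
        rng = np.random.default_rng(2)
        X = _design(rng, 30, 3)
        y = pd.Series(rng.normal(size=30))
        ranking = exhaustive_ranking(y, X, max_size=3)
        assert len(ranking.table) == 8          # 2³ subsets incl. intercept-only
        assert ranking.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert ranking.table["delta_aicc"].iloc[0] == 0.0

    def test_importance_of_absent_predictor_is_zero(self):
        rng = np.random.default_rng(2)
        X = _design(rng, 30, 3)
        y = pd.Series(rng.normal(size=30))
        ranking = exhaustive_ranking(y, X, max_size=1)
        sub = ranking.table[ranking.table["predictors"].map(len) > 1]
        assert sub.empty
        # a predictor never entering any candidate model gets importance 0
        ranking2 = exhaustive_ranking(y, X[["x0"]], max_size=1)
        assert "x1" not in ranking2.importance

    def test_stepwise_recovers_single_signal(self):
        rng = np.random.default_rng(4)
        X = _design(rng, 40, 2, names=["x1", "x2"])
        y = pd.Series(2.0 + 1.5 * X["x1"] + rng.normal(scale=0.5, size=40))
        fit = backward_stepwise(y, X)
        assert fit.predictors == ("x1",)
        ranking = exhaustive_ranking(y, X, max_size=2)
        assert fit.aicc == pytest.approx(ranking.table["aicc"].min())

    def test_stepwise_drops_everything_under_pure_noise(self):
        rng = np.random.default_rng(6)
        X = _design(rng, 40, 3)
        y = pd.Series(rng.normal(size=40))
        fit = backward_stepwise(y, X)
        assert fit.predictors == ()

    def test_perfect_single_predictor_retained(self):
        x = pd.DataFrame({"x": np.linspace(0, 1, 12)})
        y = pd.Series(3.0 + 2.0 * x["x"])
        fit = backward_stepwise(y, x)
        assert fit.predictors == ("x",)

    def test_stepwise_never_beats_exhaustive_minimum(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = _design(rng, 25, 4)
            y = pd.Series(rng.normal(size=25) + X["x0"])
            step = backward_stepwise(y, X)
            best = exhaustive_ranking(y, X, max_size=4).table["aicc"].min()
            assert step.aicc >= best - 1e-9


class TestBreuschPagan:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(12)
        X = _design(rng, 80, 2)
        y = pd.Series(X["x0"] + rng.normal(size=80) * (1 + 0.5 * X["x1"].abs()))
        fit = fit_glm(y, X)
        stat, df, p = breusch_pagan(fit)
        lm, lm_p, _, _ = het_breuschpagan(
            fit.resid, sm.add_constant(X.to_numpy()))
        assert df == 2
        assert stat == pytest.approx(lm)
        assert p == pytest.approx(lm_p)

    def test_one_predictor_reports_df_1(self):
        rng = np.random.default_rng(13)
        X = _design(rng, 9, 1)
        y = pd.Series(rng.normal(size=9))
        _, df, _ = breusch_pagan(fit_glm(y, X))
        assert df == 1

    def test_power_under_variance_proportional_to_x(self):
        rng = np.random.default_rng(14)
        rejections = 0
        for _ in range(60):
            x = rng.uniform(0.5, 3.0, 200)
            y = pd.Series(1.0 + x + rng.normal(size=200) * x * 1.5)  # sd ∝ x
            fit = fit_glm(y, pd.DataFrame({"x": x}))
            _, _, p = breusch_pagan(fit)
            rejections += p < 0.01
        assert rejections >= 57     # ≥ 95% power at this effect size
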