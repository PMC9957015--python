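"""Second-order surface fitting and factorial AUC effect analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import residuechain as rc
from residuechain.errors import DesignError, FitError, RankError, ValidationError
from residuechain.models import COEFFICIENT_NAMES
from residuechain.rsm import QuadraticSurfaceRegressor, effect_anova


class TestDesignMatrix:
    def test_canonical_monomials(self):
        rows = rc.build_design_matrix([(0, 0, 0), (1, 1, 1), (2, 3, 5)])
        np.testing.assert_array_equal(rows[0], [1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        np.testing.assert_array_equal(rows[1], np.ones(10))
        np.testing.assert_array_equal(rows[2], [1, 2, 3, 5, 4, 9, 25, 6, 10, 15])

    def test_nonfinite_points_rejected(self):
        with pytest.raises(ValidationError):
            rc.build_design_matrix([(np.nan, 0, 0)])


class TestQuadraticSurfaceFit:
    def test_noiseless_recovery_of_registry_model(self, carbendazim_wheat, factorial_points):
        y = [rc.evaluate(carbendazim_wheat, *p) for p in factorial_points]
        res = rc.fit_quadratic_surface(factorial_points, y, "carbendazim", "wheat")
        true = np.array(carbendazim_wheat.coefficients)
        rel = np.abs(np.array(res.model.coefficients) - true) / np.abs(true)
        assert rel.max() <= 1e-6
        assert abs(res.r2 - 1.0) <= 1e-9
        assert res.residual_df == res.n_obs - 10

    def test_predictions_reproduce_fitted_values(self, factorial_points, rng):
        y = 0.5 + 0.01 * factorial_points[:, 0] + rng.normal(0, 0.02, len(factorial_points))
        est = QuadraticSurfaceRegressor().fit(factorial_points, y)
        D = rc.build_design_matrix(factorial_points)
        np.testing.assert_allclose(est.predict(factorial_points), D @ est.coef_, rtol=1e-12)

    def test_residuals_orthogonal_to_design(self, factorial_points, rng):
        y = rng.normal(0, 1, len(factorial_points))
        est = QuadraticSurfaceRegressor().fit(factorial_points, y)
        resid = y - est.predict(factorial_points)
        D = rc.build_design_matrix(factorial_points)
        norms = np.linalg.norm(D, axis=0)
        assert np.max(np.abs(D.T @ resid) / norms) < 1e-8

    def test_matches_statsmodels_ols(self, factorial_points, rng):
        """Coefficients, SEs, p-values and R^2 agree with an independent OLS."""
        sm = pytest.importorskip("statsmodels.api")
        y = 0.8 - 0.005 * factorial_points[:, 0] + rng.normal(0, 0.03, len(factorial_points))
        est = QuadraticSurfaceRegressor().fit(factorial_points, y)
        ref = sm.OLS(y, rc.build_design_matrix(factorial_points)).fit()
        np.testing.assert_allclose(est.coef_, ref.params, rtol=1e-7, atol=1e-12)
        np.testing.assert_allclose(est.se_, ref.bse, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(est.pvalues_, ref.pvalues, rtol=1e-5, atol=1e-12)
        assert est.r2_ == pytest.approx(ref.rsquared, rel=1e-10)
        assert est.r2_adj_ == pytest.approx(ref.rsquared_adj, rel=1e-10)

    def test_r2_invariant_under_response_rescaling(self, factorial_points, rng):
        y = 0.5 + rng.normal(0, 0.05, len(factorial_points))
        r2a = QuadraticSurfaceRegressor().fit(factorial_points, y).r2_
        r2b = QuadraticSurfaceRegressor().fit(factorial_points, 37.5 * y).r2_
        assert r2a == pytest.approx(r2b, rel=1e-12)

    def test_single_condition_design_is_rank_deficient(self):
        points = [(t, 20.0, 60.0) for t in range(12)]
        with pytest.raises(RankError, match="aliased"):
            QuadraticSurfaceRegressor().fit(points, np.ones(12))

    def test_too_few_observations(self):
        points = [(t, 20.0 + t, 60.0 - t) for t in range(10)]
        with pytest.raises(FitError):
            QuadraticSurfaceRegressor().fit(points, np.ones(10))

    def test_estimator_params_roundtrip(self):
        est = QuadraticSurfaceRegressor(scale=False)
        assert est.get_params() == {"scale": False}
        assert est.set_params(scale=True).scale is True


@settings(max_examples=25, derandomize=True, deadline=None)
@given(coeffs=st.lists(st.floats(-1.0, 1.0), min_size=10, max_size=10))
def test_noiseless_recovery_of_random_coefficients(coeffs):
    """Any surface generated on a full-rank design is recovered to 1e-8."""
    pts = np.array(
        [
            (t, T, RH)
            for T in (20.0, 30.0, 40.0, 50.0)
            for RH in (50.0, 60.0, 70.0, 80.0)
            for t in np.linspace(0.0, 90.0, 4)
        ]
    )
    y = rc.build_design_matrix(pts) @ np.array(coeffs)
    est = QuadraticSurfaceRegressor().fit(pts, y)
    np.testing.assert_allclose(est.coef_, coeffs, rtol=1e-8, atol=1e-8)


def _auc_frame(values, temperatures=(20, 30, 40, 50), humidities=(50, 60, 70, 80), reps=1):
    rows = []
    it = iter(np.asarray(values, dtype=float).ravel())
    for T in temperatures:
        for RH in humidities:
            for r in range(reps):
                rows.append({"temperature_C": T, "rh_pct": RH, "replicate": r, "auc": next(it)})
    return pd.DataFrame(rows)


class TestEffectAnova:
    def test_identical_cells_give_unit_pvalues(self):
        table = _auc_frame(np.full(16, 3.0))
        res = effect_anova(table)
        assert res.p_T == 1.0 and res.p_RH == 1.0 and res.p_TxRH == 1.0

    def test_matches_statsmodels_two_way_anova(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        df = _auc_frame(rng.normal(10, 1, 48), reps=3)
        df["auc"] += 0.3 * (df["temperature_C"] - 35) / 10
        ours = effect_anova(df)
        fit = smf.ols("auc ~ C(temperature_C) * C(rh_pct)", data=df).fit()
        ref = anova_lm(fit)
        assert ours.p_T == pytest.approx(ref.loc["C(temperature_C)", "PR(>F)"], rel=1e-8)
        assert ours.p_RH == pytest.approx(ref.loc["C(rh_pct)", "PR(>F)"], rel=1e-8)
        assert ours.p_TxRH == pytest.approx(
            ref.loc["C(temperature_C):C(rh_pct)", "PR(>F)"], rel=1e-8
        )

    def test_strong_temperature_effect_detected_noise_humidity_not(self, rng):
        rejects_rh = 0
        for _ in range(40):
            df = _auc_frame(rng.normal(0, 1, 48), reps=3)
            df["auc"] += 2.0 * (df["temperature_C"] - 35) / 10  # ~2 SD per level step
            res = effect_anova(df)
            assert res.p_T < 0.05
            rejects_rh += res.p_RH < 0.05
        assert rejects_rh <= 8  # humidity is pure noise; near-nominal rejection

    def test_tukey_nonadditivity_used_without_replicates(self, rng):
        df = _auc_frame(rng.normal(5, 1, 16))
        res = effect_anova(df)
        assert "Tukey" in res.method
        assert res.table.loc[res.table["term"] == "T:RH", "df"].iloc[0] == 1
        assert 0 <= res.p_TxRH <= 1

    def test_tukey_detects_multiplicative_interaction(self):
        T = np.array([20, 30, 40, 50], dtype=float)
        RH = np.array([50, 60, 70, 80], dtype=float)
        y = np.outer(T - 35, RH - 65) * 0.05 + T[:, None] * 0.1 + RH[None, :] * 0.1
        res = effect_anova(_auc_frame(y))
        assert res.p_TxRH < 0.01

    def test_single_factor_level_raises(self, rng):
        df = _auc_frame(rng.normal(0, 1, 4), temperatures=(20,), humidities=(50, 60, 70, 80))
        with pytest.raises(DesignError):
            effect_anova(df)

    def test_unbalanced_table_raises(self, rng):
        df = _auc_frame(rng.normal(0, 1, 16)).iloc[:-1]
        with pytest.raises(DesignError):
            effect_anova(df)


def test_surface_fit_result_summary_has_ten_terms(carbendazim_wheat, factorial_points):
    y = [rc.evaluate(carbendazim_wheat, *p) for p in factorial_points]
    res = rc.fit_quadratic_surface(factorial_points, y)
    summary = res.summary()
    assert list(summary.columns) == ["term", "coef", "se", "p_value"]
    assert len(summary) == len(COEFFICIENT_NAMES) == 10
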