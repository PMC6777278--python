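"""Count-regression engine: spline, dispersion, ARMA selection, IRRs."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import poisson_series
from nof1ema import models, synth


class TestCyclicBasis:
    def test_basis_is_periodic_including_derivative_continuity(self):
        b = models.build_cyclic_basis(np.arange(7.0), k=5)
        np.testing.assert_allclose(b.design_raw([0.0]), b.design_raw([7.0]),
                                   atol=1e-12)
        eps = 1e-5  # first derivative matches across the wrap-around
        d_left = (b.design_raw([7.0 - eps]) - b.design_raw([7.0 - 2 * eps])) / eps
        d_right = (b.design_raw([eps]) - b.design_raw([0.0])) / eps
        np.testing.assert_allclose(d_left, d_right, atol=1e-3)

    def test_constant_is_penalty_free_and_exactly_representable(self):
        b = models.build_cyclic_basis(np.arange(7.0), k=5)
        const = np.ones(5)
        np.testing.assert_allclose(b.S @ const, 0, atol=1e-10)
        x = np.linspace(0, 6.99, 40)
        np.testing.assert_allclose(b.design_raw(x) @ const, 1.0, atol=1e-10)

    @pytest.mark.parametrize("k", [2, 8])
    def test_basis_dimension_out_of_range_rejected(self, k):
        with pytest.raises(ValueError):
            models.build_cyclic_basis(np.arange(7.0), k=k)

    def test_smooth_recovers_weekly_sinusoid(self):
        rng = np.random.default_rng(3)
        dow = (np.arange(560) // 2) % 7
        y = rng.poisson(np.exp(3.0 + 0.5 * np.sin(2 * np.pi * dow / 7)))
        df = pd.DataFrame({"frequency": y.astype(float), "dow": dow.astype(float)})
        fit = models.fit_count_gam(
            models.ModelSpec(predictors=(), family="poisson"), df)
        sv = fit.smooth_values(np.arange(7.0))
        truth = 0.5 * np.sin(2 * np.pi * np.arange(7) / 7)
        r = np.corrcoef(sv - sv.mean(), truth - truth.mean())[0, 1]
        assert r > 0.99

    def test_fitted_smooth_agrees_at_period_endpoints(self):
        df = poisson_series(200, 0.0, seed=5, dow_amp=0.4)
        fit = models.fit_count_gam(
            models.ModelSpec(predictors=(), family="poisson"), df)
        assert fit.smooth_values([0.0])[0] == pytest.approx(
            fit.smooth_values([7.0])[0], abs=1e-10)


class TestGlmOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_textbook_poisson_irls(self, seed):
        # p = q = 0, no smooth, Poisson family must equal an unpenalized
        # log-link Poisson GLM fitted independently
        rng = np.random.default_rng(seed)
        n = 150
        x1 = rng.normal(3, 1, n)
        x2 = rng.binomial(1, 0.5, n).astype(float)
        y = rng.poisson(np.exp(0.4 + 0.3 * (x1 - 3) + 0.5 * x2)).astype(float)
        df = pd.DataFrame({"frequency": y, "motivation": x1, "reminder": x2})
        spec = models.ModelSpec(predictors=("motivation", "reminder"),
                                seasonal_smooth=False, family="poisson")
        fit = models.fit_count_gam(spec, df)
        oracle = sm.GLM(y, sm.add_constant(np.column_stack([x1, x2])),
                        family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), oracle.params,
                                   atol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(), oracle.bse, atol=1e-6)
        assert fit.aic == pytest.approx(oracle.aic, abs=1e-4)

    def test_null_model_intercept_is_log_sample_mean(self):
        y = np.array([2.0, 5, 3, 4, 1, 7, 2, 3, 4, 5] * 3)
        df = pd.DataFrame({"frequency": y})
        fit = models.fit_count_gam(
            models.ModelSpec(predictors=(), seasonal_smooth=False,
                             family="poisson"), df)
        assert fit.params["intercept"] == pytest.approx(math.log(y.mean()),
                                                        abs=1e-10)

    def test_aic_matches_hand_formula(self):
        df = poisson_series(60, 0.2, seed=9)
        fit = models.fit_count_gam(
            models.ModelSpec(predictors=("usefulness",),
                             seasonal_smooth=False, family="poisson"), df)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.edf)


class TestDispersion:
    def test_poisson_data_give_unit_dispersion(self):
        df = poisson_series(500, 0.3, seed=21)
        fit = models.fit_count_gam(
            models.ModelSpec(predictors=("usefulness",),
                             seasonal_smooth=False, family="auto"), df)
        phi, family = models.estimate_dispersion(fit)
        assert phi == pytest.approx(1.0, abs=0.25)
        assert family == "poisson"

    def test_overdispersed_data_recover_the_factor_and_promote_family(self):
        rng = np.random.default_rng(22)
        n, d = 500, 3.0
        mu = np.full(n, 8.0)
        y = rng.poisson(rng.gamma(mu / (d - 1), d - 1)).astype(float)
        df = pd.DataFrame({"frequency": y})
        fit = models.fit_count_gam(
            models.ModelSpec(predictors=(), seasonal_smooth=False,
                             family="auto"), df)
        phi, family = models.estimate_dispersion(fit)
        assert phi == pytest.approx(3.0, abs=0.6)
        assert family == "quasipoisson"
        assert fit.family_used == "quasipoisson"

    def test_threshold_keeps_family_poisson_below_cutoff(self):
        df = poisson_series(300, 0.0, seed=23)
        fit = models.fit_count_gam(
            models.ModelSpec(predictors=(), seasonal_smooth=False,
                             family="auto"), df)
        phi, family = models.estimate_dispersion(fit, threshold=1.5)
        assert family == "poisson"
        # quasi-Poisson SEs scale by sqrt(phi) relative to Poisson
        quasi = models.fit_count_gam(
            models.ModelSpec(predictors=(), seasonal_smooth=False,
                             family="quasipoisson"), df)
        np.testing.assert_allclose(quasi.se.to_numpy(),
                                   fit.se.to_numpy() * math.sqrt(phi),
                                   rtol=1e-8)


class TestAcfPacf:
    def test_lag_zero_is_one_and_white_noise_stays_in_bands(self):
        rng = np.random.default_rng(30)
        rep = models.acf_pacf(rng.normal(0, 1, 500), max_lag=20)
        assert rep["acf"][0] == pytest.approx(1.0)
        outside = np.sum(np.abs(rep["acf"][1:]) > rep["band"])
        assert outside <= 3  # ~5% nominal false-positive rate

    def test_ar1_signature_lag1_high_pacf_cuts_off(self):
        spec = synth.PredictorSpec("e", 0, 1, 0.6, kind="continuous")
        z = synth.generate_predictor_series(spec, 2000, seed=31)
        rep = models.acf_pacf(z, max_lag=5)
        assert rep["acf"][1] == pytest.approx(0.6, abs=0.07)
        assert abs(rep["pacf"][2]) < rep["band"] * 2
        assert rep["lag1_significant"]

    def test_constant_residuals_reported_undefined(self):
        rep = models.acf_pacf(np.ones(100), max_lag=5)
        assert not rep["defined"]
        assert np.isnan(rep["acf"][1])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            models.acf_pacf(np.arange(10.0), max_lag=8)


class TestParameterRecovery:
    def test_effect_recovered_within_three_ses_at_large_n(self):
        beta = math.log(1.8)
        df = poisson_series(2000, beta, seed=40)
        fit = models.fit_count_gam(
            models.ModelSpec(predictors=("usefulness",),
                             seasonal_smooth=False, family="poisson"), df)
        est, se = fit.params["usefulness"], fit.se["usefulness"]
        assert abs(est - beta) < 3 * se

    @pytest.mark.parametrize("n, reps", [(56, 120), (2000, 40)])
    def test_ci_coverage_near_nominal(self, n, reps):
        beta = math.log(1.3)
        hits = 0
        for r in range(reps):
            df = poisson_series(n, beta, seed=5000 + r)
            fit = models.fit_count_gam(
                models.ModelSpec(predictors=("usefulness",),
                                 seasonal_smooth=False, family="poisson"), df)
            est, se = fit.params["usefulness"], fit.se["usefulness"]
            hits += abs(est - beta) < 1.96 * se
        assert hits / reps >= 0.86

    def test_predictor_order_does_not_change_irrs(self):
        rng = np.random.default_rng(41)
        n = 200
        df = pd.DataFrame({
            "motivation": rng.normal(4, 1, n),
            "usefulness": rng.normal(3, 1, n),
        })
        df["frequency"] = rng.poisson(
            np.exp(0.5 + 0.2 * (df.motivation - 4) - 0.3 * (df.usefulness - 3))
        ).astype(float)
        a = models.fit_count_gam(models.ModelSpec(
            predictors=("motivation", "usefulness"), seasonal_smooth=False,
            family="poisson"), df)
        b = models.fit_count_gam(models.ModelSpec(
            predictors=("usefulness", "motivation"), seasonal_smooth=False,
            family="poisson"), df)
        assert a.params["motivation"] == pytest.approx(b.params["motivation"],
                                                       abs=1e-9)

    def test_constant_predictor_rejected(self):
        df = poisson_series(56, 0.0, seed=42)
        df["reminder"] = 1.0
        with pytest.raises(ValueError, match="no within-person variance"):
            models.fit_count_gam(models.ModelSpec(
                predictors=("reminder",), seasonal_smooth=False), df)


def _latent_noise_series(n, rho, seed, beta=0.2):
    """Counts whose log-mean carries an AR(1) latent error process."""
    rng = np.random.default_rng(seed)
    x = synth.generate_predictor_series(
        synth.PredictorSpec("u", 3.18, 0.93, 0.5, kind="continuous"), n, rng)
    if rho > 0:
        z = synth.generate_predictor_series(
            synth.PredictorSpec("e", 0, 0.5, rho, kind="continuous"), n, rng)
    else:
        z = np.zeros(n)
    y = rng.poisson(np.exp(1.0 + beta * (x - 3.18) + z)).astype(float)
    return pd.DataFrame({"usefulness": x, "frequency": y})


class TestStructureSelection:
    GRID = ((0, 0), (1, 0), (0, 1), (1, 1), (2, 0))
    SPEC = models.ModelSpec(predictors=("usefulness",), seasonal_smooth=False,
                            family="auto", arma_method="auto")

    def test_independent_errors_select_no_correlation_in_majority(self):
        picks = []
        for s in range(6):
            best, _ = models.select_structure(
                _latent_noise_series(300, 0.0, 100 + s), self.SPEC, self.GRID)
            picks.append((best.ar_order, best.ma_order))
        assert sum(p == (0, 0) for p in picks) >= 4

    def test_strong_ar_errors_select_serial_structure_in_majority(self):
        picks = []
        for s in range(6):
            best, _ = models.select_structure(
                _latent_noise_series(300, 0.7, 200 + s), self.SPEC, self.GRID)
            picks.append(best.ar_order + best.ma_order)
        assert sum(p >= 1 for p in picks) >= 5

    def test_selection_table_covers_grid(self):
        best, table = models.select_structure(
            _latent_noise_series(100, 0.0, 7), self.SPEC,
            grid=((0, 0), (1, 0)))
        assert set(zip(table["p"], table["q"])) == {(0, 0), (1, 0)}


class TestBackwardSelection:
    @staticmethod
    def _multi(n, betas, seed):
        rng = np.random.default_rng(seed)
        X = {f"x{j}": rng.normal(0, 1, n) for j in range(4)}
        eta = 1.0 + sum(b * X[f"x{j}"] for j, b in enumerate(betas))
        df = pd.DataFrame(X)
        df["frequency"] = rng.poisson(np.exp(eta)).astype(float)
        return df

    def test_null_predictors_mostly_eliminated(self):
        # with an AIC criterion each null predictor survives elimination
        # with probability ~0.16, so almost all of the 4x6 null terms
        # should be dropped and no dataset should keep more than half
        kept = []
        for s in range(6):
            df = self._multi(500, [0, 0, 0, 0], 300 + s)
            fit, _ = models.backward_select(df, models.ModelSpec(
                predictors=("x0", "x1", "x2", "x3"), seasonal_smooth=False,
                family="poisson"))
            kept.append(len(fit.spec.predictors))
        assert sum(kept) <= 6
        assert max(kept) <= 2

    def test_strong_effect_retained(self):
        retained = 0
        for s in range(6):
            df = self._multi(2000, [math.log(2.0), 0, 0, 0], 400 + s)
            fit, trace = models.backward_select(df, models.ModelSpec(
                predictors=("x0", "x1", "x2", "x3"), seasonal_smooth=False,
                family="poisson"))
            retained += "x0" in fit.spec.predictors
        assert retained >= 6 * 0.9

    def test_single_predictor_reduces_to_univariable(self):
        df = poisson_series(200, 0.4, seed=50)
        spec = models.ModelSpec(predictors=("usefulness",),
                                seasonal_smooth=False, family="poisson")
        fit, trace = models.backward_select(df, spec)
        uni = models.fit_univariable(df, "usefulness", spec)
        if fit.spec.predictors:  # retained: identical to the univariable fit
            assert fit.params["usefulness"] == pytest.approx(
                uni.params["usefulness"], abs=1e-10)
        assert trace[0]["predictors"] == ("usefulness",)

    def test_univariable_matches_multivariable_for_orthogonal_design(self):
        df = self._multi(3000, [0.3, -0.2, 0, 0], 60)
        spec = models.ModelSpec(predictors=("x0", "x1", "x2", "x3"),
                                seasonal_smooth=False, family="poisson")
        multi = models.fit_count_gam(spec, df)
        uni = models.fit_univariable(df, "x0", spec)
        joint_se = math.hypot(multi.se["x0"], uni.se["x0"])
        assert abs(uni.params["x0"] - multi.params["x0"]) < 3 * joint_se


class TestIrrReporting:
    def test_zero_coefficient_is_unit_irr(self):
        assert models.percent_change(1.0) == 0.0
        assert models.percent_change_label(1.0) == "0% change"

    @pytest.mark.parametrize("irr, label", [
        (3.88, "288% increase"),
        (137.32, "13632% increase"),
        (0.52, "48% reduction"),
        (1.8, "80% increase"),
    ])
    def test_printed_percent_change_conventions(self, irr, label):
        assert models.percent_change_label(irr) == label

    def test_report_columns_and_ci_ordering(self):
        df = poisson_series(200, 0.3, seed=70)
        fit = models.fit_count_gam(models.ModelSpec(
            predictors=("usefulness",), seasonal_smooth=False,
            family="poisson"), df)
        rep = models.irr_report(fit)
        row = rep.iloc[0]
        assert row["ci_low"] < row["irr"] < row["ci_high"]
        assert row["irr"] > 0
        assert row["ar_ma"] == "0,0"
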