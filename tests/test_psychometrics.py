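"""NLME psychometric model: prediction, fitting, inference, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from itdcode import (DesignSpec, FixedEffects, GenerativeTruth,
                     ParameterError, criterion_correlation, fisher_power,
                     fit_nlme, generate_dataset, load_trials,
                     monte_carlo_power, normalize_predictors,
                     predict_laterality, variance_explained, wald_table)
from itdcode.psychometrics import FIXED_NAMES, residual_df


class TestNormalizePredictors:
    def test_zero_mean_unit_variance(self, full_dataset):
        trials, _, _ = full_dataset
        out, spec = normalize_predictors(trials)
        for col in ("itd_norm", "intensity_norm"):
            assert abs(out[col].mean()) < 1e-9
            assert abs(out[col].to_numpy().var() - 1.0) < 1e-9

    def test_balanced_design_means(self, full_dataset):
        trials, _, _ = full_dataset
        _, spec = normalize_predictors(trials)
        assert spec.itd_mean == pytest.approx(0.0, abs=1e-9)
        assert spec.intensity_mean == pytest.approx(15.0)

    def test_roundtrip(self, full_dataset):
        trials, _, _ = full_dataset
        out, spec = normalize_predictors(trials)
        np.testing.assert_allclose(
            spec.denormalize_itd(out["itd_norm"]), trials["itd_us"],
            atol=1e-9)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"itd_us": [0.0] * 4, "sl_db": [5, 10, 15, 20],
                           "response": 0.0})
        with pytest.raises(ParameterError):
            normalize_predictors(df)


class TestPredictLaterality:
    def test_midline_value(self):
        fx = FixedEffects(ax0=0.0, ax1=2.0, ax2=0.0, ay1=0.0, ay2=0.0)
        val = predict_laterality(fx, 0.0, 1.2, 0.0, 0.0, 0.0)
        assert val == pytest.approx(1.2 / 2 - 0.5)

    def test_asymptotes(self):
        fx = FixedEffects(ax1=2.0)
        hi = predict_laterality(fx, 0.0, 1.0, 0.0, 50.0, 0.0)
        lo = predict_laterality(fx, 0.0, 1.0, 0.0, -50.0, 0.0)
        assert hi == pytest.approx(0.5, abs=1e-9)
        assert lo == pytest.approx(-0.5, abs=1e-9)

    def test_overflow_safe(self):
        fx = FixedEffects(ax1=100.0)
        assert np.isfinite(predict_laterality(fx, 0.0, 1.0, 0.0, 1e4, 0.0))

    @given(eta=st.floats(-30, 30))
    def test_antisymmetric_about_midline_with_unit_amplitude(self, eta):
        fx = FixedEffects(ax0=0.0, ax1=1.0, ax2=0.0, ay1=0.0, ay2=0.0)
        plus = predict_laterality(fx, 0.0, 1.0, 0.0, eta, 0.0)
        minus = predict_laterality(fx, 0.0, 1.0, 0.0, -eta, 0.0)
        assert plus + minus == pytest.approx(0.0, abs=1e-12)

    def test_scaled_form_antisymmetric_for_any_amplitude(self):
        fx = FixedEffects(ax1=2.0)
        plus = predict_laterality(fx, 0.0, 1.7, 0.0, 1.0, 0.0, form="scaled")
        minus = predict_laterality(fx, 0.0, 1.7, 0.0, -1.0, 0.0, form="scaled")
        assert plus + minus == pytest.approx(0.0, abs=1e-12)

    def test_unknown_form_rejected(self):
        with pytest.raises(ParameterError):
            predict_laterality(FixedEffects(), 0, 1, 0, 0, 0, form="bogus")


class TestFitNlme:
    def test_noiseless_identifiability(self):
        truth = GenerativeTruth(sigma_x0=0.0, sigma_y0=0.0, sigma_resid=0.0,
                                seed=1)
        trials, _ = generate_dataset(DesignSpec(), truth)
        fit = fit_nlme(trials)
        np.testing.assert_allclose(fit.fixed.as_array(),
                                   truth.fixed.as_array(), atol=1e-6)
        assert fit.amplitude_mean == pytest.approx(truth.amplitude_mean,
                                                   abs=1e-6)

    def test_refit_on_own_predictions_is_fixed_point(self, full_dataset):
        trials, _, _ = full_dataset
        fit = fit_nlme(trials)
        clean = trials.copy()
        clean["response"] = fit.predict(trials)
        refit = fit_nlme(clean)
        np.testing.assert_allclose(refit.fixed.as_array(),
                                   fit.fixed.as_array(), atol=1e-4)

    def test_recovery_within_3se(self, full_dataset):
        trials, _, truth = full_dataset
        fit = fit_nlme(trials)
        z = np.abs(fit.fixed.as_array() - truth.fixed.as_array()) / fit.se
        assert np.all(z < 3.0)

    def test_deterministic_given_data(self, full_dataset):
        trials, _, _ = full_dataset
        a = fit_nlme(trials)
        b = fit_nlme(trials)
        np.testing.assert_array_equal(a.fixed.as_array(), b.fixed.as_array())

    def test_too_few_listeners_rejected(self, full_dataset):
        trials, _, _ = full_dataset
        one = trials[trials.listener_id == "L00"]
        with pytest.raises(ParameterError):
            fit_nlme(one)


class TestInference:
    def test_df_matches_design_formula(self, full_dataset):
        trials, _, _ = full_dataset
        fit = fit_nlme(trials)
        assert fit.df == residual_df(len(trials), 10) == 10986

    def test_df_depends_only_on_design(self):
        # same design, different data values -> same df
        t1, _ = generate_dataset(DesignSpec(n_listeners=3, n_blocks=2),
                                 GenerativeTruth(seed=5))
        t2, _ = generate_dataset(DesignSpec(n_listeners=3, n_blocks=2),
                                 GenerativeTruth(seed=6, sigma_resid=0.3))
        assert fit_nlme(t1).df == fit_nlme(t2).df == 3 * 110 - 3 - 4

    def test_wald_table_layout(self, full_dataset):
        trials, _, _ = full_dataset
        table = wald_table(fit_nlme(trials))
        assert list(table.index) == list(FIXED_NAMES)
        assert {"estimate", "se", "t", "p", "df"} <= set(table.columns)
        np.testing.assert_allclose(table["t"],
                                   table["estimate"] / table["se"])
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()


class TestVarianceExplained:
    def test_perfect_and_mean_only(self, full_dataset):
        trials, _, _ = full_dataset
        fit = fit_nlme(trials)
        clean = trials.copy()
        clean["response"] = fit.predict(trials)
        assert variance_explained(fit, clean) == pytest.approx(1.0, abs=1e-9)

    def test_matches_analytic_noise_share(self, full_dataset):
        trials, _, truth = full_dataset
        fit = fit_nlme(trials)
        analytic = 1 - truth.sigma_resid**2 / trials["response"].var()
        assert variance_explained(fit, trials) == pytest.approx(analytic,
                                                                abs=0.02)


class TestCriterionCorrelation:
    def test_reproduces_published_criterion(self):
        assert criterion_correlation(11, 0.01, 0.95) == pytest.approx(
            0.90, abs=0.01)

    def test_monte_carlo_cross_check(self):
        r = criterion_correlation(11, 0.01, 0.95)
        power = monte_carlo_power(r, 11, 0.01, n_sim=10_000, seed=3)
        assert power == pytest.approx(0.95, abs=0.02)

    def test_monotone_in_n(self):
        rs = [criterion_correlation(n, 0.01, 0.95) for n in
              (8, 11, 20, 50, 200, 1000)]
        assert np.all(np.diff(rs) < 0)
        assert rs[-1] < 0.15

    def test_power_increases_with_r(self):
        assert fisher_power(0.95, 11) > fisher_power(0.6, 11)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            criterion_correlation(3, 0.01, 0.95)
        with pytest.raises(ParameterError):
            criterion_correlation(11, 0.0, 0.95)


class TestLoadTrials:
    def test_column_mapping_adapter(self, tmp_path, full_dataset):
        trials, _, _ = full_dataset
        foreign = trials.rename(columns={
            "listener_id": "subject", "itd_us": "itd",
            "sl_db": "level", "pta_db": "pta", "response": "score"})
        path = tmp_path / "foreign.csv"
        foreign.to_csv(path, index=False)
        mapping = {"listener_id": "subject", "itd_us": "itd",
                   "sl_db": "level", "pta_db": "pta", "response": "score",
                   "experiment": "experiment"}
        loaded = load_trials(path, mapping)
        assert list(loaded.columns[:6]) == [
            "listener_id", "experiment", "itd_us", "sl_db", "pta_db",
            "response"]
        assert len(loaded) == len(trials)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(path, index=False)
        with pytest.raises(ParameterError):
            load_trials(path)
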