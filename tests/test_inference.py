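"""Fitting, AICc ranking, multimodel averaging, bootstrap and sensitivity."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

import radstress as rs
from radstress.data import ChemostatObservation
from radstress.growth import ChemostatCondition
from radstress.inference import observation_sd, profile_g, negative_log_likelihood
from radstress.refvalues import (
    COMPETITION_EFFECT_MODELS,
    DILUTION_RADIATION_INTERACTION_MODELS,
    YEAST_MODEL_RANKING,
)


def obs(kind, dose, dilution, value, **kw):
    return ChemostatObservation(kind, ChemostatCondition(dose, dilution), value, **kw)


class TestObservationSd:
    def test_from_ci(self):
        o = obs("equilibrium", 10, 0.1, 100.0, ci_low=80.4, ci_high=119.6)
        sd = observation_sd(o, rs.FitConfig(error_model="from_ci"))
        assert sd == pytest.approx(10.0, rel=1e-3)

    def test_relative_cv(self):
        o = obs("equilibrium", 10, 0.1, 50.0)
        sd = observation_sd(o, rs.FitConfig(error_model="relative_cv", cv=0.1))
        assert sd == pytest.approx(5.0)

    def test_degenerate_ci_raises(self):
        o = obs("equilibrium", 10, 0.1, 50.0, ci_low=50.0, ci_high=50.0)
        with pytest.raises(rs.ConfigurationError, match="zero-variance"):
            observation_sd(o, rs.FitConfig(error_model="from_ci"))

    def test_missing_ci_falls_back_with_warning(self, caplog):
        o = obs("equilibrium", 10, 0.1, 50.0)
        with caplog.at_level(logging.WARNING, logger="radstress.inference"):
            sd = observation_sd(o, rs.FitConfig(error_model="from_ci", cv=0.1))
        assert sd == pytest.approx(5.0)
        assert "falling back" in caplog.text


class TestProfileG:
    def test_inverts_the_critical_dose_example(self):
        """g solving a(59.7, 0.1) = 0 for M1 must recover g = 0.1."""
        dataset = rs.ChemostatDataset([
            obs("equilibrium", 0, 0.1, 300.0),
            obs("critical_dose", 0, 0.1, 59.707),
        ])
        partial = rs.ParameterSet(m=2.11e-3, q=0.599, k=5.78e-4, delta=4.78e-2)
        g = profile_g(rs.get_model("M1"), partial, dataset, rs.FitConfig())
        assert g == pytest.approx(0.1, rel=1e-3)

    def test_fixed_convention_ignores_data(self):
        dataset = rs.ChemostatDataset([obs("equilibrium", 0, 0.1, 300.0)])
        partial = rs.ParameterSet(m=1e-3, q=0.5, k=1e-4, delta=0.05)
        config = rs.FitConfig(g_convention="fixed", g_value=0.25)
        assert profile_g(rs.get_model("M1"), partial, dataset, config) == 0.25

    def test_inapplicable_for_model_without_g(self):
        dataset = rs.ChemostatDataset([
            obs("equilibrium", 0, 0.1, 300.0),
            obs("critical_dose", 0, 0.1, 59.7),
        ])
        partial = rs.ParameterSet(m=1e-3, q=0.5, k=1e-4, delta=0.05)
        assert profile_g(rs.get_model("M18"), partial, dataset, rs.FitConfig()) is None

    def test_requires_critical_dose_observation(self):
        dataset = rs.ChemostatDataset([obs("equilibrium", 0, 0.1, 300.0)])
        partial = rs.ParameterSet(m=1e-3, q=0.5, k=1e-4, delta=0.05)
        with pytest.raises(rs.ConfigurationError, match="critical_dose"):
            profile_g(rs.get_model("M1"), partial, dataset, rs.FitConfig())

    def test_uses_lowest_dilution_observation(self, m1_params):
        model = rs.get_model("M1")
        r1 = model.critical_dose_rate(m1_params, 0.05).r_crit
        r2 = model.critical_dose_rate(m1_params.replace(g=0.3), 0.2).r_crit
        dataset = rs.ChemostatDataset([
            obs("equilibrium", 0, 0.1, 300.0),
            obs("critical_dose", 0, 0.2, r2),
            obs("critical_dose", 0, 0.05, r1),
        ])
        partial = m1_params.replace(g=None)
        g = profile_g(model, partial, dataset, rs.FitConfig())
        assert g == pytest.approx(0.1, rel=1e-6)  # from the d=0.05 row


class TestObjective:
    def test_zero_at_truth_on_noiseless_data(self, noiseless_dataset, m1_params):
        dataset, _ = noiseless_dataset
        config = rs.FitConfig(error_model="relative_cv", cv=0.05)
        value = negative_log_likelihood(rs.get_model("M1"), m1_params, dataset, config)
        assert value == pytest.approx(0.0, abs=1e-10)

    def test_single_two_sigma_residual_scores_four(self):
        dataset = rs.ChemostatDataset([
            obs("equilibrium", 0, 0.1, 0.0, sd=1.0),
        ])
        # choose params whose prediction is exactly 2: a/b = 2
        params = rs.ParameterSet(m=0.1, g=0.0, q=0.3, k=0.0, delta=0.0)
        value = negative_log_likelihood(rs.get_model("M1"), params, dataset,
                                        rs.FitConfig())
        assert value == pytest.approx(4.0)

    def test_infinite_sd_observation_leaves_objective_unchanged(
            self, noiseless_dataset, m1_params):
        dataset, _ = noiseless_dataset
        config = rs.FitConfig(error_model="relative_cv", cv=0.05)
        base = negative_log_likelihood(rs.get_model("M1"), m1_params, dataset, config)
        padded = rs.ChemostatDataset(
            dataset.observations
            + [obs("equilibrium", 3.21, 0.11, 1234.5, sd=math.inf)],
            label=dataset.label,
        )
        value = negative_log_likelihood(rs.get_model("M1"), m1_params, padded, config)
        assert value == base


class TestAicc:
    def test_worked_example(self):
        assert rs.aicc(10.0, 4, 14) == pytest.approx(10 + 8 + 40 / 9)

    def test_reduces_to_neg2loglik_at_zero_parameters(self):
        assert rs.aicc(7.3, 0, 10) == 7.3

    def test_correction_identity(self):
        p, n = 3, 12
        assert rs.aicc(5.0, p, n) - (5.0 + 2 * p) == pytest.approx(
            2 * p * (p + 1) / (n - p - 1))

    def test_small_sample_guard(self):
        with pytest.raises(ValueError, match="n_obs > p_free"):
            rs.aicc(1.0, 5, 6)


class TestSelectionTable:
    def test_two_model_weights_closed_form(self):
        table = rs.SelectionTable.from_delta_aicc({"A": 0.0, "B": 2.0})
        e = math.exp(-1.0)
        assert table.weight("A") == pytest.approx(1 / (1 + e))
        assert table.weight("B") == pytest.approx(e / (1 + e))

    def test_single_model_has_weight_one(self):
        table = rs.SelectionTable.from_delta_aicc({"A": 0.0})
        assert table.weight("A") == 1.0

    def test_weights_sum_to_one_and_order_inverts_delta(self):
        table = rs.SelectionTable.from_delta_aicc(
            {f"M{i}": float(i) for i in range(1, 8)})
        assert table.df["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (table.df["weight"].diff().dropna() <= 0).all()
        assert table.df["delta_aicc"].min() == 0.0

    def test_evidence_sum_of_everything_is_one(self):
        table = rs.SelectionTable.from_weights(YEAST_MODEL_RANKING)
        assert table.evidence_sum(list(YEAST_MODEL_RANKING)) == pytest.approx(1.0)

    def test_published_evidence_sums(self):
        table = rs.SelectionTable.from_weights(YEAST_MODEL_RANKING)
        assert round(table.evidence_sum(COMPETITION_EFFECT_MODELS), 3) == 0.163
        assert round(
            table.evidence_sum(DILUTION_RADIATION_INTERACTION_MODELS), 3) == 0.162

    def test_unknown_model_rejected(self):
        table = rs.SelectionTable.from_delta_aicc({"A": 0.0})
        with pytest.raises(KeyError):
            table.evidence_sum(["Z"])

    def test_confidence_set_thresholds(self):
        table = rs.SelectionTable.from_weights(YEAST_MODEL_RANKING)
        assert table.confidence_set(0.5) == ["M1"]
        assert set(table.confidence_set(math.inf)) == set(YEAST_MODEL_RANKING)
        assert table.confidence_set(6.0) == [f"M{i}" for i in range(1, 10)]


class TestFit:
    def test_small_sample_precondition(self):
        observations = [obs("equilibrium", r, 0.1, 100.0 - r, sd=5.0)
                        for r in (0, 10, 20, 30)]
        observations.append(obs("critical_dose", 0, 0.1, 60.0, sd=3.0))
        dataset = rs.ChemostatDataset(observations)
        with pytest.raises(ValueError, match="n_obs > p_free"):
            rs.ChemostatGrowthModel(dataset, "M1")  # 4 free params, 4 eq rows

    def test_fit_is_deterministic_given_seed(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        config = rs.FitConfig(error_model="relative_cv", cv=0.05, n_starts=4)
        fit1 = rs.ChemostatGrowthModel(dataset, "M1", config).fit(seed=7)
        fit2 = rs.ChemostatGrowthModel(dataset, "M1", config).fit(seed=7)
        assert np.array_equal(fit1.theta, fit2.theta)

    def test_recovers_truth_noiselessly(self, noiseless_fit, m1_params):
        for name in ("k", "delta", "q", "m"):
            assert getattr(noiseless_fit.params, name) == pytest.approx(
                getattr(m1_params, name), rel=1e-3)
        assert noiseless_fit.g_value == pytest.approx(m1_params.g, rel=1e-3)
        assert noiseless_fit.neg2loglik == pytest.approx(0.0, abs=1e-8)

    def test_summary_mentions_profiled_g(self, noiseless_fit):
        text = noiseless_fit.summary()
        assert "M1" in text and "profiled" in text and "AICc" in text


@pytest.fixture(scope="module")
def selection(noiseless_dataset):
    dataset, _ = noiseless_dataset
    config = rs.FitConfig(error_model="relative_cv", cv=0.05)
    return rs.fit_all_models(dataset, ["M1", "M17", "M20"], config,
                             seed=2, n_starts=6)


@pytest.fixture(scope="module")
def noisy_fit():
    dataset, _ = rs.generate_chemostat_dataset(
        rs.ChemostatDesign(noise_cv=0.05, seed=11))
    return rs.ChemostatGrowthModel(dataset, "M1", rs.FitConfig()).fit(
        seed=1, n_starts=6)


class TestMmiPredict:
    def test_singleton_confidence_set_equals_best_model(self, selection):
        d_grid = [0.05, 0.1, 0.2]
        mmi = selection.mmi_predict("critical_dose", d_grid, delta_threshold=1e-6)
        best = selection.best.predict_rcrit(d_grid)
        assert np.allclose(mmi, best)

    def test_equal_weights_average_is_arithmetic_mean(self, noiseless_fit):
        table = rs.SelectionTable.from_delta_aicc({"M1": 0.0, "M17": 0.0})
        other = rs.ChemostatGrowthModel(
            noiseless_fit.dataset, "M17",
            rs.FitConfig(error_model="relative_cv", cv=0.05)).fit(seed=3)
        results = rs.ModelSelectionResults(
            fits={"M1": noiseless_fit, "M17": other}, table=table, failed={})
        grid = [0.0, 10.0, 20.0]
        mean_eq = results.mmi_predict("equilibrium", grid, dilution_rate=0.1)
        expected = 0.5 * (noiseless_fit.predict_equilibrium(grid, 0.1)
                          + other.predict_equilibrium(grid, 0.1))
        assert np.allclose(mean_eq, expected)

    def test_no_extinction_sentinel_enters_average_as_ceiling(self, noiseless_fit):
        """M17 never goes extinct below its profiled g; its sentinel must be
        replaced by the dose-rate ceiling (with a warning), not propagate inf."""
        table = rs.SelectionTable.from_delta_aicc({"M1": 0.0, "M17": 0.0})
        other = rs.ChemostatGrowthModel(
            noiseless_fit.dataset, "M17",
            rs.FitConfig(error_model="relative_cv", cv=0.05)).fit(seed=3)
        results = rs.ModelSelectionResults(
            fits={"M1": noiseless_fit, "M17": other}, table=table, failed={})
        assert other.rcrit(0.001).no_extinction  # profiled g exceeds d
        with pytest.warns(UserWarning, match="no extinction"):
            mmi = results.mmi_predict("critical_dose", [0.001], delta_threshold=6)
        assert np.isfinite(mmi).all()

    def test_rcrit_non_increasing_in_dilution(self, selection):
        d_grid = np.linspace(0.01, 0.4, 9)
        mmi = selection.mmi_predict("critical_dose", d_grid)
        assert (np.diff(mmi) <= 1e-9).all()


class TestBootstrap:
    def test_same_seed_reproduces_summary(self, noisy_fit):
        s1 = noisy_fit.bootstrap(n_replicates=20, seed=5)
        s2 = noisy_fit.bootstrap(n_replicates=20, seed=5)
        pd.testing.assert_frame_equal(s1.draws, s2.draws)
        pd.testing.assert_frame_equal(s1.param_ci, s2.param_ci)

    def test_zero_redraw_scale_gives_zero_width_intervals(self, noisy_fit):
        summary = noisy_fit.bootstrap(n_replicates=8, seed=2, redraw_scales=0.0)
        widths = summary.param_ci["ci_high"] - summary.param_ci["ci_low"]
        assert (widths.abs() < 1e-9).all()

    def test_intervals_widen_monotonically_with_noise(self):
        widths = []
        for cv in (0.02, 0.05, 0.10):
            dataset, _ = rs.generate_chemostat_dataset(
                rs.ChemostatDesign(noise_cv=cv, seed=21))
            fit = rs.ChemostatGrowthModel(dataset, "M1", rs.FitConfig()).fit(
                seed=1, n_starts=6)
            summary = fit.bootstrap(n_replicates=60, seed=3)
            ci = summary.param_ci.loc["k"]
            widths.append(ci["ci_high"] - ci["ci_low"])
        assert widths[0] < widths[1] < widths[2]

    def test_prediction_grids_bracket_the_estimate(self, noisy_fit):
        summary = noisy_fit.bootstrap(
            n_replicates=30, seed=4,
            equilibrium_grid=[0.0, 10.0, 30.0], equilibrium_dilution=0.05,
            rcrit_grid=[0.05, 0.2])
        for key in ("equilibrium", "critical_dose"):
            tab = summary.prediction_ci[key]
            assert (tab["ci_low"] <= tab["estimate"] + 1e-9).all()
            assert (tab["estimate"] <= tab["ci_high"] + 1e-9).all()

    def test_parameter_correlations_are_a_correlation_matrix(self, noisy_fit):
        summary = noisy_fit.bootstrap(n_replicates=40, seed=6)
        corr = summary.param_correlations()
        assert np.allclose(np.diag(corr), 1.0)
        assert (corr.abs() <= 1.0 + 1e-12).to_numpy().all()


class TestSensitivity:
    def test_zero_perturbation_gives_unit_ratios(self, m1_params):
        table = rs.sensitivity_rcrit(rs.get_model("M1"), m1_params,
                                     [0.01, 0.1], perturbation=0.0)
        assert np.allclose(table.to_numpy(), 1.0)

    def test_kill_coefficient_dominates_at_low_dilution(self, m1_params):
        """At near-zero dilution R_crit ~ g/k, so a 10% increase in k divides
        it by 1.1."""
        table = rs.sensitivity_rcrit(rs.get_model("M1"), m1_params, [0.001])
        assert table.loc[0.001, "k"] == pytest.approx(1 / 1.1, abs=5e-3)

    def test_proliferation_parameters_dominate_at_high_dilution(self, m1_params):
        table = rs.sensitivity_rcrit(rs.get_model("M1"), m1_params, [0.001, 0.35])
        # killing matters less as dilution grows; proliferation matters more
        assert table.loc[0.35, "k"] > table.loc[0.001, "k"]
        assert abs(table.loc[0.35, "q"] - 1) > abs(table.loc[0.001, "q"] - 1)
        assert abs(table.loc[0.35, "delta"] - 1) > abs(table.loc[0.001, "delta"] - 1)

    def test_washout_points_are_flagged_nan(self, m1_params):
        d_washout = m1_params.g + m1_params.q + 0.1
        table = rs.sensitivity_rcrit(rs.get_model("M1"), m1_params, [d_washout])
        assert table.isna().all().all()


class TestRcritFoldDrop:
    def test_reference_dilution_halves_the_equilibrium(self, m1_params):
        res = rs.rcrit_fold_drop(rs.get_model("M1"), m1_params)
        assert res.d_reference == pytest.approx((m1_params.g + m1_params.q) / 2,
                                                rel=1e-8)

    def test_fold_matches_direct_threshold_ratio(self, m1_params):
        model = rs.get_model("M1")
        res = rs.rcrit_fold_drop(model, m1_params)
        direct = (model.critical_dose_rate(m1_params, 0.0).r_crit
                  / model.critical_dose_rate(m1_params, res.d_reference).r_crit)
        assert res.fold == pytest.approx(direct, rel=1e-9)
        assert res.fold > 1.0
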