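"""Coupled EWS trajectory simulation: closed forms, oracles, scenarios."""

import numpy as np
import pandas as pd
import pytest

from circashift.simulate import (
    DEPRESSION_THRESHOLD,
    INSOMNIA_THRESHOLD,
    PHQ9_RANGE,
    PSQI_RANGE,
    SimulationConfig,
    adaptability_labels,
    classify_adaptability,
    crossing_day,
    ews_update,
    predictive_function,
    scenario_run,
    simulate_individual,
    simulate_population,
)
from circashift.synthetic import BASELINE_DEMAND

from conftest import make_affine_fit


@pytest.fixture(scope="module")
def affine_fits():
    """Coupled affine system: pred_psqi = 5 + 0.3*phq9, pred_phq9 = 4 + 0.3*psqi."""
    return (make_affine_fit("psqi", "phq9", 5.0, 0.3),
            make_affine_fit("phq9", "psqi", 4.0, 0.3))


class TestEWS:
    def test_arithmetic(self):
        assert ews_update(1.0, 8.0, 0.2) == pytest.approx(2.4)

    def test_fixed_point(self):
        assert ews_update(6.0, 6.0, 0.35) == pytest.approx(6.0)

    def test_closed_form_constant_prediction(self):
        """Constant prediction P from start s0: day-t value is
        P + (s0 - P)(1 - alpha)^t, to within 1e-12."""
        psqi_fit = make_affine_fit("psqi", "phq9", 8.0, 0.0)
        phq9_fit = make_affine_fit("phq9", "psqi", 5.0, 0.0)
        cfg = SimulationConfig(alpha=0.2, horizon=60, init_psqi=1.0,
                               init_phq9=0.0)
        psqi_path, phq9_path = simulate_individual({}, psqi_fit, phq9_fit, cfg)
        t = np.arange(1, 61)
        np.testing.assert_allclose(psqi_path, 8.0 + (1.0 - 8.0) * 0.8 ** t,
                                   atol=1e-12)
        np.testing.assert_allclose(phq9_path, 5.0 + (0.0 - 5.0) * 0.8 ** t,
                                   atol=1e-12)

    def test_alpha_one_jumps_to_fixed_point(self):
        psqi_fit = make_affine_fit("psqi", "phq9", 8.0, 0.0)
        phq9_fit = make_affine_fit("phq9", "psqi", 5.0, 0.0)
        cfg = SimulationConfig(alpha=1.0, horizon=5)
        psqi_path, phq9_path = simulate_individual({}, psqi_fit, phq9_fit, cfg)
        assert psqi_path[0] == pytest.approx(8.0)
        assert np.allclose(psqi_path, 8.0) and np.allclose(phq9_path, 5.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(alpha=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(horizon=0)
        with pytest.raises(ValueError):
            SimulationConfig(init_psqi=25.0)


class TestCrossingDay:
    def test_closed_form_day_nine(self):
        """P=8, s0=1, alpha=0.2, threshold >7 crosses on day
        ceil(log(1/7)/log(0.8)) = 9."""
        psqi_fit = make_affine_fit("psqi", "phq9", 8.0, 0.0)
        phq9_fit = make_affine_fit("phq9", "psqi", 0.0, 0.0)
        cfg = SimulationConfig(alpha=0.2, horizon=30, init_psqi=1.0)
        psqi_path, _ = simulate_individual({}, psqi_fit, phq9_fit, cfg)
        analytic = int(np.ceil(np.log(1.0 / 7.0) / np.log(0.8)))
        assert analytic == 9
        assert crossing_day(psqi_path, INSOMNIA_THRESHOLD, ">") == 9

    def test_never_crossing_is_none(self):
        assert crossing_day([1.0, 2.0, 3.0], 7.0, ">") is None

    def test_direction_conventions(self):
        path = [8.0, 9.0, 10.0, 11.0]
        assert crossing_day(path, DEPRESSION_THRESHOLD, ">=") == 3
        assert crossing_day(path, 10.0, ">") == 4


class TestCoupledSystem:
    def test_matches_affine_recursion_oracle(self, affine_fits):
        """Noise-off coupled paths equal the 2-D affine matrix iteration."""
        psqi_fit, phq9_fit = affine_fits
        cfg = SimulationConfig(alpha=0.2, horizon=80, init_psqi=1.0,
                               init_phq9=0.0)
        psqi_path, phq9_path = simulate_individual({}, psqi_fit, phq9_fit, cfg)

        a = cfg.alpha
        s = np.array([1.0, 0.0])
        A = np.array([[1 - a, a * 0.3], [a * 0.3, 1 - a]])
        b = np.array([a * 5.0, a * 4.0])
        oracle = []
        for _ in range(cfg.horizon):
            s = A @ s + b
            oracle.append(s.copy())
        oracle = np.array(oracle)
        np.testing.assert_allclose(psqi_path, oracle[:, 0], atol=1e-9)
        np.testing.assert_allclose(phq9_path, oracle[:, 1], atol=1e-9)

    def test_monotone_rise_from_below_fixed_point(self, affine_fits):
        psqi_fit, phq9_fit = affine_fits
        cfg = SimulationConfig(horizon=100, init_psqi=1.0, init_phq9=0.0)
        psqi_path, phq9_path = simulate_individual({}, psqi_fit, phq9_fit, cfg)
        assert np.all(np.diff(psqi_path) >= -1e-12)
        assert np.all(np.diff(phq9_path) >= -1e-12)


class TestPredictiveFunction:
    def test_mean_covariates_give_inverse_link_of_intercept(self, affine_fits):
        psqi_fit, _ = affine_fits
        pred = predictive_function(psqi_fit, dynamic_var="phq9")
        pred.prepare(pd.DataFrame(index=range(1)))
        # identity recipe, gaussian link: raw 0 -> z 0 -> eta = intercept
        assert pred.predict(np.array([0.0]))[0] == pytest.approx(5.0)

    def test_manual_chain_on_worked_row(self, planted_fits):
        """Prediction equals the hand computation recipe -> eta -> exp."""
        psqi_fit, _ = planted_fits
        pred = predictive_function(psqi_fit, dynamic_var="phq9")
        row = {"gender": 1.0, "age": 33.0, "bmi": 22.0, "fr": 13.0, "lv": 18.0,
               "night_count": 4.0, "shift_work_hours": 44.0,
               "shift_workload_exposure": 147.0,
               "day_workload_exposure": 120.0}
        pred.prepare(pd.DataFrame([row]))
        phq9_value = 7.0
        out = float(pred.predict(np.array([phq9_value]))[0])

        recipe = psqi_fit.recipe
        z = {k: float(recipe.transform_value(k, v))
             for k, v in row.items() if k != "gender"}
        z["gender"] = 1.0
        z["phq9"] = float(recipe.transform_value("phq9", phq9_value))
        eta = 0.0
        for term, beta in psqi_fit.coef.items():
            if term == "intercept":
                eta += beta
            elif ":" in term:
                a, b = term.split(":")
                eta += beta * z[a] * z[b]
            else:
                eta += beta * z[term]
        assert out == pytest.approx(
            float(np.clip(np.exp(eta), *PSQI_RANGE)), abs=1e-9)

    def test_monotone_in_depression_when_beta_positive(self, planted_fits):
        psqi_fit, _ = planted_fits
        assert psqi_fit.coef["phq9"] > 0
        pred = predictive_function(psqi_fit, dynamic_var="phq9")
        row = {"gender": 1.0, "age": 33.0, "bmi": 22.0, "fr": 13.0, "lv": 18.0,
               "night_count": 4.0, "shift_work_hours": 44.0,
               "shift_workload_exposure": 147.0,
               "day_workload_exposure": 120.0}
        pred.prepare(pd.DataFrame([row]))
        low = float(pred.predict(np.array([3.0]))[0])
        high = float(pred.predict(np.array([15.0]))[0])
        assert high > low


class TestPopulation:
    def test_single_nurse_cohort_zero_sd(self, planted_fits):
        psqi_fit, phq9_fit = planted_fits
        cohort = pd.DataFrame([{
            "gender": 1.0, "age": 30.0, "bmi": 21.0, "fr": 12.0, "lv": 19.0,
            "psqi": 8.0, "phq9": 7.0, "night_count": 4.0,
            "shift_work_hours": 44.0, "shift_workload_exposure": 147.0,
            "day_workload_exposure": 120.0}])
        cfg = SimulationConfig(horizon=20, n_individuals=50, seed=3)
        ts = simulate_population(cohort, psqi_fit, phq9_fit, cfg)
        assert np.allclose(ts.sd_psqi, 0.0) and np.allclose(ts.sd_phq9, 0.0)

    def test_values_within_instrument_bounds(self, cohort, planted_fits):
        psqi_fit, phq9_fit = planted_fits
        cfg = SimulationConfig(horizon=40, n_individuals=150, seed=5,
                               demand=BASELINE_DEMAND, demand_multiplier=2.0)
        ts = simulate_population(cohort, psqi_fit, phq9_fit, cfg)
        assert (ts.mean_psqi >= PSQI_RANGE[0]).all()
        assert (ts.mean_psqi + ts.sd_psqi <= PSQI_RANGE[1] + 1e-9).all()
        assert (ts.mean_phq9 >= PHQ9_RANGE[0]).all()

    def test_seed_determinism(self, cohort, planted_fits):
        psqi_fit, phq9_fit = planted_fits
        cfg = SimulationConfig(horizon=15, n_individuals=80, seed=7)
        t1 = simulate_population(cohort, psqi_fit, phq9_fit, cfg)
        t2 = simulate_population(cohort, psqi_fit, phq9_fit, cfg)
        np.testing.assert_array_equal(t1.mean_psqi, t2.mean_psqi)
        np.testing.assert_array_equal(t1.sd_phq9, t2.sd_phq9)

    def test_bootstrap_monte_carlo_error_scaling(self, cohort, planted_fits):
        """Quadrupling the bootstrap size roughly halves the Monte-Carlo SE
        of the mean trajectory."""
        psqi_fit, phq9_fit = planted_fits

        def mc_sd(n_ind):
            finals = []
            for seed in range(40):
                cfg = SimulationConfig(horizon=25, n_individuals=n_ind,
                                       seed=100 + seed)
                ts = simulate_population(cohort, psqi_fit, phq9_fit, cfg)
                finals.append(ts.mean_psqi[-1])
            return np.std(finals)

        ratio = mc_sd(60) / mc_sd(240)
        assert 1.35 < ratio < 3.0         # expected ~2, +/- 2 SD of the ratio

    def test_empty_cohort_rejected(self, planted_fits):
        with pytest.raises(ValueError):
            simulate_population(pd.DataFrame(), *planted_fits,
                                SimulationConfig())


class TestAdaptability:
    def test_rule_table(self):
        fr_q, lv_q = (10.0, 20.0), (12.0, 24.0)
        assert classify_adaptability(22.0, 8.0, fr_q, lv_q) == "H"
        assert classify_adaptability(15.0, 18.0, fr_q, lv_q) == "M"
        assert classify_adaptability(8.0, 26.0, fr_q, lv_q) == "L"
        assert classify_adaptability(8.0, 8.0, fr_q, lv_q) == "UNCLASSIFIED"

    def test_cohort_labels_partition(self, cohort):
        labels = adaptability_labels(cohort)
        assert set(labels.unique()) <= {"M", "H", "L", "UNCLASSIFIED"}
        assert (labels == "M").sum() > 0


class TestScenarioRun:
    def test_grid_and_determinism(self, cohort, planted_fits):
        psqi_fit, phq9_fit = planted_fits
        cfg = SimulationConfig(horizon=30, n_individuals=100, seed=13)
        res1, summary1 = scenario_run(cohort, psqi_fit, phq9_fit, cfg,
                                      multipliers=(1.0, 2.0))
        res2, summary2 = scenario_run(cohort, psqi_fit, phq9_fit, cfg,
                                      multipliers=(1.0, 2.0))
        assert set(res1) == {(g, m) for g in "MHL" for m in (1.0, 2.0)}
        pd.testing.assert_frame_equal(summary1, summary2)
        for key in res1:
            np.testing.assert_array_equal(res1[key].mean_psqi,
                                          res2[key].mean_psqi)

    def test_steady_state_non_decreasing_in_multiplier(self, cohort,
                                                       planted_fits):
        """With a positive shift-hours coefficient, scaling the demand bundle
        up cannot lower the long-run mean sleep-quality score."""
        psqi_fit, phq9_fit = planted_fits
        assert psqi_fit.coef["shift_work_hours"] > 0
        cfg = SimulationConfig(horizon=60, n_individuals=200, seed=17)
        res, _ = scenario_run(cohort, psqi_fit, phq9_fit, cfg,
                              multipliers=(0.25, 1.0, 1.5, 2.0), groups=("M",))
        finals = [res[("M", m)].mean_psqi[-1] for m in (0.25, 1.0, 1.5, 2.0)]
        assert all(b >= a - 0.05 for a, b in zip(finals, finals[1:]))
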