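"""Digital-twin dynamics: fixed point, forcing responses, solver accuracy,
and the synthetic scenario generator."""

import numpy as np
import pytest

from glucotwin import signals, twin
from glucotwin.signals import EventRecord, UniformSeries
from glucotwin.twin import (ForcingSet, PatientParams, ScenarioConfig,
                            basal_state, derivative, ground_truth_table,
                            load_ground_truth, make_scenario, simulate,
                            synthesize_cgm)


def _forcing(u1, u2, u3, dt=1.0):
    return ForcingSet(UniformSeries(0.0, dt, u1, "mU/min"),
                      UniformSeries(0.0, dt, u2, "g/min"),
                      UniformSeries(0.0, dt, u3, "%VO2max"))


class TestDerivative:
    def test_basal_state_is_fixed_point(self, default_params, basal_forcing):
        d = derivative(basal_state(default_params), 0.0, default_params,
                       basal_forcing)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_basal_insulin_formula(self):
        p = PatientParams(n=0.1, p4=0.01, u1b=10.0)
        assert p.ib == pytest.approx(0.01 / 0.1 * 10.0)

    def test_meal_forcing_only_enters_glucose_equation(self, default_params):
        n = 100
        f0 = _forcing(np.full(n, default_params.u1b), np.zeros(n), np.zeros(n))
        f1 = _forcing(np.full(n, default_params.u1b), np.full(n, 0.5),
                      np.zeros(n))
        s = basal_state(default_params)
        d0 = derivative(s, 0.0, default_params, f0)
        d1 = derivative(s, 0.0, default_params, f1)
        delta = d1 - d0
        expected_dg = 0.5 * twin.CARB_MG_PER_G / default_params.vol_g
        assert delta[2] == pytest.approx(expected_dg)
        mask = np.ones(6, dtype=bool)
        mask[2] = False
        assert np.allclose(delta[mask], 0.0)

    def test_nan_state_rejected(self, default_params, basal_forcing):
        s = basal_state(default_params)
        s[0] = np.nan
        with pytest.raises(ValueError):
            derivative(s, 0.0, default_params, basal_forcing)


class TestSimulate:
    def test_basal_scenario_stays_at_fixed_point(self, default_params,
                                                 basal_forcing):
        traj = simulate(default_params, basal_forcing)
        assert np.abs(traj["G"] - default_params.gb).max() < 1e-6
        assert np.abs(traj["I"] - default_params.ib).max() < 1e-6

    def test_meal_raises_glucose_then_relaxes(self, default_params):
        n = 1440
        u2 = signals.meals_to_u2([EventRecord("meal", 60.0, 50.0)],
                                 UniformSeries(0.0, 1.0, np.zeros(n)))
        f = _forcing(np.full(n, default_params.u1b), u2.values, np.zeros(n))
        traj = simulate(default_params, f)
        g = traj["G"].to_numpy()
        assert g.max() > default_params.gb + 30
        assert traj["t"][g.argmax()] > 60.0
        assert g[-1] < g.max() - 20   # relaxing back toward basal

    def test_rk4_matches_adaptive_stiff_solver(self, default_params):
        n = 720
        u2 = signals.meals_to_u2([EventRecord("meal", 30.0, 40.0)],
                                 UniformSeries(0.0, 1.0, np.zeros(n)))
        u3 = np.zeros(n)
        u3[300:360] = 15.0
        f = _forcing(np.full(n, default_params.u1b), u2.values, u3)
        rk4 = simulate(default_params, f, method="rk4")
        lsoda = simulate(default_params, f, method="lsoda",
                         rtol=1e-10, atol=1e-10)
        assert np.abs(rk4["G"] - lsoda["G"]).max() < 1e-3

    def test_step_halving_convergence(self, default_params):
        n = 360
        u2 = signals.meals_to_u2([EventRecord("meal", 10.0, 60.0)],
                                 UniformSeries(0.0, 1.0, np.zeros(n)))
        f = _forcing(np.full(n, default_params.u1b), u2.values, np.zeros(n))
        g1 = simulate(default_params, f, substeps=1)["G"].iloc[-1]
        g2 = simulate(default_params, f, substeps=2)["G"].iloc[-1]
        assert abs(g1 - g2) < 1e-6

    def test_exercise_states_decay_exponentially_after_bout(self,
                                                            default_params):
        n = 600
        u3 = np.zeros(n)
        u3[60:120] = 20.0
        f = _forcing(np.full(n, default_params.u1b), np.zeros(n), u3)
        traj = simulate(default_params, f)
        t = traj["t"].to_numpy()
        sel = t >= 180.0
        dt_since = t[sel] - 180.0
        for state, rate in [("Gprod", default_params.value("a2", 0)),
                            ("Gup", default_params.value("a4", 0)),
                            ("Ie", default_params.value("a6", 0))]:
            x = traj[state].to_numpy()[sel]
            expected = x[0] * np.exp(-rate * dt_since)
            assert np.allclose(x, expected, rtol=1e-6)
        assert traj["Gprod"].max() > 0 and traj["Gup"].max() > 0

    def test_larger_bolus_never_raises_minimum_glucose(self, default_params):
        n = 1440
        grid = UniformSeries(0.0, 1.0, np.zeros(n))
        u2 = signals.meals_to_u2([EventRecord("meal", 60.0, 50.0)], grid)
        mins = []
        for dose in (0.0, 2000.0, 4000.0, 8000.0):
            boluses = ([EventRecord("bolus", 60.0, dose, mode="normal")]
                       if dose else [])
            u1 = signals.total_insulin_rate(
                [EventRecord("basal", 0.0, default_params.u1b)], [], boluses,
                grid)
            f = ForcingSet(u1, u2, grid.zeros_like())
            mins.append(simulate(default_params, f)["G"].min())
        assert np.all(np.diff(mins) <= 1e-9)

    def test_time_varying_parameter_series_is_used(self, default_params):
        # a p1 that doubles halfway through must change the meal response
        # relative to the constant-p1 patient, and a constant series must not
        n = 720
        grid = UniformSeries(0.0, 1.0, np.zeros(n))
        u2 = signals.meals_to_u2([EventRecord("meal", 30.0, 50.0)], grid)
        f = _forcing(np.full(n, default_params.u1b), u2.values, np.zeros(n))
        p1_const = default_params.value("p1", 0.0)
        const_series = PatientParams(p1=UniformSeries(0.0, 1.0,
                                                      np.full(n, p1_const)))
        varying = PatientParams(p1=UniformSeries(
            0.0, 1.0, np.where(np.arange(n) < n // 2, p1_const,
                               2 * p1_const)))
        g_const = simulate(PatientParams(p1=p1_const), f)["G"]
        assert np.allclose(simulate(const_series, f)["G"], g_const, atol=1e-9)
        g_var = simulate(varying, f)["G"]
        assert np.allclose(g_var[: n // 2], g_const[: n // 2], atol=1e-9)
        assert np.abs(g_var[n // 2 + 60:] - g_const[n // 2 + 60:]).max() > 1.0


class TestScenario:
    def test_same_seed_reproduces_scenario(self):
        a = make_scenario(5, ScenarioConfig(duration_days=2))
        b = make_scenario(5, ScenarioConfig(duration_days=2))
        assert np.array_equal(a.forcing.u1.values, b.forcing.u1.values)
        assert np.array_equal(a.hr.values, b.hr.values)
        assert len(a.events) == len(b.events)

    def test_meal_count_within_configured_bounds(self):
        cfg = ScenarioConfig(duration_days=7)
        sc = make_scenario(9, cfg)
        meals = [e for e in sc.events if e.kind == "meal"]
        assert 2 * 7 <= len(meals) <= 4 * 7
        assert all(cfg.carb_bounds[0] <= m.value <= cfg.carb_bounds[1]
                   for m in meals)

    def test_underdosing_produces_hyperglycemia(self, default_params):
        sc = make_scenario(1, ScenarioConfig(duration_days=3, dose_factor=0.5))
        _, traj = synthesize_cgm(default_params, sc, seed=2)
        assert (traj["G"] > 180.0).mean() > 0.05

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(duration_days=0)
        with pytest.raises(ValueError):
            ScenarioConfig(dose_factor=-1.0)

    def test_cgm_gaps_are_nan_spans(self, default_params):
        sc = make_scenario(3, ScenarioConfig(duration_days=3))
        cgm, _ = synthesize_cgm(default_params, sc, gaps_per_day=2.0, seed=4)
        assert np.isnan(cgm.values).any()


class TestGroundTruthTable:
    def test_constant_params_round_trip(self):
        p = PatientParams.from_multipliers({"n": 1.2, "a3": 0.4}, u1b=12.0)
        q = load_ground_truth(ground_truth_table(p))
        for name in twin.PARAM_NAMES:
            assert q.value(name, 0.0) == p.value(name, 0.0)
        assert (q.w, q.u1b, q.gb) == (p.w, p.u1b, p.gb)

    def test_time_varying_and_boundary_values_preserved(self):
        series = UniformSeries(0.0, 60.0, np.array([0.2, 1.8, 0.2]) * 0.035)
        p = PatientParams(p1=series)
        q = load_ground_truth(ground_truth_table(p))
        assert isinstance(q.p1, UniformSeries)
        assert np.array_equal(q.p1.values, series.values)

    def test_parameter_box_validated_in_multipliers(self):
        with pytest.raises(ValueError, match=r"\[0.2, 1.8\]"):
            PatientParams.from_multipliers({"n": 2.5})
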