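"""Event-to-forcing conversion: bolus release, insulin summation, meal
appearance, heart-rate conversion, and imputation/alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucotwin import signals
from glucotwin.signals import (EventRecord, UniformSeries, bolus_to_rate,
                               coarse_grain, heart_rate_to_u3,
                               impute_and_align, meals_to_u2,
                               total_insulin_rate)


@pytest.fixture
def grid():
    return UniformSeries(0.0, 1.0, np.zeros(240))


class TestBolusRelease:
    def test_normal_mode_releases_dose_over_ten_minutes(self, grid):
        rec = EventRecord("bolus", 0.0, 500.0, mode="normal")
        rate = bolus_to_rate(rec, grid)
        assert np.allclose(rate.values[:10], 50.0)
        assert np.allclose(rate.values[10:], 0.0)

    def test_square_mode_spreads_dose_uniformly(self, grid):
        rec = EventRecord("bolus", 0.0, 600.0, t_end=60.0, mode="square")
        rate = bolus_to_rate(rec, grid)
        assert np.allclose(rate.values[:60], 10.0)
        assert np.allclose(rate.values[60:], 0.0)

    def test_zero_dose_is_identically_zero(self, grid):
        for mode, t_end in [("normal", None), ("square", 30.0),
                            ("normal_dual", 30.0), ("square_dual", 30.0)]:
            rec = EventRecord("bolus", 0.0, 0.0, t_end=t_end, mode=mode)
            assert not bolus_to_rate(rec, grid).values.any()

    @pytest.mark.parametrize("mode,t_end", [
        ("normal", None), ("square", 45.0),
        ("normal_dual", 30.0), ("normal_dual", 120.0),
        ("square_dual", 30.0), ("square_dual", 120.0)])
    def test_dose_conservation(self, grid, mode, t_end):
        rec = EventRecord("bolus", 3.0, 750.0, t_end=t_end, mode=mode)
        rate = bolus_to_rate(rec, grid)
        assert rate.values.sum() * grid.dt == pytest.approx(750.0, rel=1e-9)

    def test_dual_release_order_follows_mode_name(self, grid):
        nd = bolus_to_rate(EventRecord("bolus", 0.0, 400.0, t_end=60.0,
                                       mode="normal_dual"), grid)
        # normal half: 200 mU over 10 min from t=0; square half on [30, 60)
        assert np.allclose(nd.values[:10], 20.0)
        assert np.allclose(nd.values[10:30], 0.0)
        assert np.allclose(nd.values[30:60], 200.0 / 30.0)
        sd = bolus_to_rate(EventRecord("bolus", 0.0, 400.0, t_end=60.0,
                                       mode="square_dual"), grid)
        assert np.allclose(sd.values[:30], 200.0 / 30.0)
        assert np.allclose(sd.values[30:40], 20.0)
        assert np.allclose(sd.values[40:60], 0.0)

    def test_strict_literal_dual_mode_loses_dose_on_long_intervals(self, grid):
        rec = EventRecord("bolus", 0.0, 400.0, t_end=120.0, mode="normal_dual")
        strict = bolus_to_rate(rec, grid, strict_eq2=True)
        # literal reading: normal half released at x/2/10 over the whole
        # 60-min half-interval -> delivers 6x the intended half dose
        assert strict.values.sum() * grid.dt == pytest.approx(
            0.5 * 400.0 / 10.0 * 60.0 + 200.0, rel=1e-9)
        conserving = bolus_to_rate(rec, grid)
        assert conserving.values.sum() * grid.dt == pytest.approx(400.0, rel=1e-9)

    def test_invalid_interval_and_negative_dose_are_rejected(self):
        with pytest.raises(ValueError):
            EventRecord("bolus", 10.0, 100.0, t_end=5.0, mode="square")
        with pytest.raises(ValueError):
            EventRecord("bolus", 0.0, -1.0, mode="normal")


class TestTotalInsulin:
    def test_basal_only_is_constant(self, grid):
        u1 = total_insulin_rate([EventRecord("basal", 0.0, 10.0)], [], [], grid)
        assert np.allclose(u1.values, 10.0)

    def test_basal_plus_normal_bolus(self, grid):
        u1 = total_insulin_rate(
            [EventRecord("basal", 0.0, 10.0)], [],
            [EventRecord("bolus", 0.0, 500.0, mode="normal")], grid)
        assert np.allclose(u1.values[:10], 60.0)
        assert np.allclose(u1.values[10:], 10.0)

    def test_temp_basal_overrides_bolus_but_not_basal(self, grid):
        u1 = total_insulin_rate(
            [EventRecord("basal", 0.0, 10.0)],
            [EventRecord("temp_basal", 0.0, 5.0, t_end=30.0)],
            [EventRecord("bolus", 5.0, 500.0, mode="normal")], grid)
        assert np.allclose(u1.values[:30], 15.0)   # basal 10 + temp 5
        assert np.allclose(u1.values[30:], 10.0)   # bolus fully suppressed

    def test_overlapping_temp_basal_windows_rejected(self, grid):
        with pytest.raises(ValueError, match="overlap"):
            total_insulin_rate([], [
                EventRecord("temp_basal", 0.0, 5.0, t_end=60.0),
                EventRecord("temp_basal", 30.0, 8.0, t_end=90.0)], [], grid)


class TestMealAppearance:
    def test_no_meals_gives_zero(self, grid):
        assert not meals_to_u2([], grid).values.any()

    def test_initial_rate_and_decay_constant(self):
        grid = UniformSeries(0.0, 1.0, np.zeros(1440))
        u2 = meals_to_u2([EventRecord("meal", 0.0, 50.0)], grid)
        assert u2.values[0] == pytest.approx(0.0083 * 50.0)
        slope = np.polyfit(u2.times[:200], np.log(u2.values[:200]), 1)[0]
        assert -slope == pytest.approx(0.0083, rel=1e-9)

    def test_carbohydrate_mass_conservation(self):
        horizon = int(10 / 0.0083)
        grid = UniformSeries(0.0, 1.0, np.zeros(horizon))
        meals = [EventRecord("meal", 7.0, 60.0), EventRecord("meal", 200.0, 35.0)]
        u2 = meals_to_u2(meals, grid)
        assert u2.values.sum() * grid.dt == pytest.approx(95.0, rel=0.01)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            EventRecord("meal", 0.0, -5.0)


class TestHeartRate:
    @pytest.mark.parametrize("hr,pvo,u3", [
        (90.0, 8.01, 0.01), (60.0, -18.63, 0.0), (100.0, 16.89, 8.89)])
    def test_conversion_and_clamp(self, hr, pvo, u3):
        series = UniformSeries(0.0, 5.0, np.array([hr]))
        p, u = heart_rate_to_u3(series)
        assert p.values[0] == pytest.approx(pvo)
        assert u.values[0] == pytest.approx(u3, abs=1e-9)

    @given(st.lists(st.floats(30, 220), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_heart_rate(self, hrs):
        hrs = np.sort(np.asarray(hrs))
        _, u3 = heart_rate_to_u3(UniformSeries(0.0, 5.0, hrs))
        assert np.all(np.diff(u3.values) >= -1e-12)
        assert np.all(u3.values >= 0.0)


class TestImputeAndAlign:
    def test_identical_grids_unchanged(self):
        s = UniformSeries(0.0, 5.0, np.arange(10.0))
        out = impute_and_align({"a": s}, 5.0)
        assert np.allclose(out["a"].values, s.values)

    def test_interior_gap_linear_fill(self):
        v = np.array([80.0, np.nan, np.nan, 90.0])
        out = impute_and_align({"hr": UniformSeries(0.0, 5.0, v)}, 5.0)
        assert np.allclose(out["hr"].values, [80, 80 + 10 / 3, 80 + 20 / 3, 90])
        assert out["hr"].mask.all()   # 10-min gap is below the flag threshold

    def test_long_gap_is_filled_but_flagged(self):
        v = np.full(50, 100.0)
        v[10:40] = np.nan   # 150-min gap at 5-min sampling
        out = impute_and_align({"G": UniformSeries(0.0, 5.0, v)}, 5.0)
        assert not np.isnan(out["G"].values).any()
        assert not out["G"].mask[15:35].any()
        assert out["G"].mask[:10].all() and out["G"].mask[40:].all()

    def test_offset_series_trimmed_to_intersection(self):
        a = UniformSeries(0.0, 5.0, np.arange(20.0))
        b = UniformSeries(30.0, 5.0, np.arange(20.0))
        out = impute_and_align({"a": a, "b": b}, 5.0)
        assert out["a"].t0 == 30.0
        assert out["a"].times[-1] <= a.times[-1]
        assert len(out["a"]) == len(out["b"])

    def test_empty_overlap_raises(self):
        a = UniformSeries(0.0, 5.0, np.arange(5.0))
        b = UniformSeries(1000.0, 5.0, np.arange(5.0))
        with pytest.raises(ValueError, match="overlap"):
            impute_and_align({"a": a, "b": b}, 5.0)

    def test_coarse_grain_block_average(self):
        s = UniformSeries(0.0, 15.0, np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        c = coarse_grain(s, 60.0)
        assert np.allclose(c.values, [2.5])
        assert c.dt == 60.0


@given(seed=st.integers(0, 2 ** 16))
@settings(max_examples=20, deadline=None)
def test_forcings_are_nonnegative(seed):
    from glucotwin import twin

    sc = twin.make_scenario(seed, twin.ScenarioConfig(duration_days=1))
    for name in ("u1", "u2", "u3"):
        assert np.all(getattr(sc.forcing, name).values >= 0.0)
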