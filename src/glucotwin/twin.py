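"""Glucose-insulin digital twin: the modified Roy-Parker ODE and a synthetic
patient-scenario generator.

State vector (6 components):

* ``I``     plasma insulin (uU/ml)
* ``X``     remote-compartment insulin action (1/min)
* ``G``     plasma glucose (mg/dl)
* ``Gprod`` exercise-induced hepatic glucose production (mg/kg/min)
* ``Gup``   exercise-induced glucose uptake (mg/kg/min)
* ``Ie``    exercise-induced insulin removal (uU/ml/min)

Dynamics, with forcings u1 (insulin infusion, mU/min), u2 (meal glucose
appearance, converted to mg/min), and exercise intensity E:

    dI/dt     = -n I + p4 u1 - Ie
    dX/dt     = -p2 X + p3 (I - Ib)
    dG/dt     = -p1 (G - Gb) - X G + (W/VolG)(Gprod - Gup) + u2/VolG
    dGprod/dt = a1 E - a2 Gprod
    dGup/dt   = a3 E - a4 Gup
    dIe/dt    = a5 E - a6 Ie

The basal state (Ib, 0, Gb, 0, 0, 0) with u1 = u1b, u2 = E = 0 is a fixed
point, where Ib = (p4/n) u1b.  By default E is the above-basal exercise
intensity u3 (so rest means E = 0); the literal absolute-%VO2max reading is
available via ``exercise_offset=8``.  The glycogenolysis-decline term of the
original prolonged-exercise model is deliberately absent: the target wear-data
regime contains only sporadic, light activity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .signals import (EventRecord, UniformSeries, heart_rate_to_u3,
                      meals_to_u2, total_insulin_rate)

__all__ = [
    "REFERENCE_PARAMS", "DEFAULT_PATIENT_MULTIPLIERS", "PARAM_NAMES",
    "CARB_MG_PER_G", "STATE_NAMES",
    "PatientParams", "ForcingSet", "basal_state", "derivative", "simulate",
    "ScenarioConfig", "Scenario", "make_scenario", "synthesize_cgm",
    "ground_truth_table", "load_ground_truth",
]

#: mg of glucose per gram of carbohydrate in the meal channel (u2 is carried
#: in g/min by the preprocessing layer and converted here)
CARB_MG_PER_G = 1000.0

PARAM_NAMES = ("n", "vol_g", "p1", "p2", "p3", "p4",
               "a1", "a2", "a3", "a4", "a5", "a6")
STATE_NAMES = ("I", "X", "G", "Gprod", "Gup", "Ie")

#: nominal reference values (xref) from the published exercise-extended
#: minimal model; per-patient values live in [0.2, 1.8] * xref
REFERENCE_PARAMS: dict[str, float] = {
    "n": 0.142,        # 1/min, plasma insulin clearance
    "vol_g": 117.0,    # dl, glucose distribution volume
    "p1": 0.035,       # 1/min, insulin-independent glucose clearance
    "p2": 0.05,        # 1/min, remote-insulin decay
    "p3": 2.8e-5,      # ml/(uU min^2), remote-insulin activation
    "p4": 0.0884,      # (uU/ml)/(mU), exogenous insulin appearance
    "a1": 0.00158,     # hepatic production gain per unit intensity
    "a2": 0.056,       # 1/min, hepatic production decay
    "a3": 0.00195,     # glucose uptake gain per unit intensity
    "a4": 0.0485,      # 1/min, glucose uptake decay
    "a5": 0.00125,     # insulin-removal gain per unit intensity
    "a6": 0.075,       # 1/min, insulin-removal decay
}

#: default synthetic study patient, as multipliers of the reference values:
#: insulin-independent glucose clearance is reduced to 40% of the reference,
#: giving realistic T1DM meal excursions (adequate bolusing holds glucose
#: mostly in range; half-dosing produces frequent readings above 180 mg/dl)
DEFAULT_PATIENT_MULTIPLIERS: dict[str, float] = {"p1": 0.4}


def _as_func(v):
    """Accept a constant, a UniformSeries (zero-order hold), or a callable."""
    if callable(v):
        return v
    if isinstance(v, UniformSeries):
        return v.value_at
    x = float(v)
    return lambda t, _x=x: _x


@dataclass
class PatientParams:
    """Roy-Parker parameter set plus the basal constants.

    Rate parameters may be constants, :class:`UniformSeries`, or callables of
    time (minutes).  ``ib`` is derived: Ib = (p4(0)/n(0)) * u1b.
    """

    n: object = REFERENCE_PARAMS["n"]
    vol_g: object = REFERENCE_PARAMS["vol_g"]
    p1: object = REFERENCE_PARAMS["p1"]
    p2: object = REFERENCE_PARAMS["p2"]
    p3: object = REFERENCE_PARAMS["p3"]
    p4: object = REFERENCE_PARAMS["p4"]
    a1: object = REFERENCE_PARAMS["a1"]
    a2: object = REFERENCE_PARAMS["a2"]
    a3: object = REFERENCE_PARAMS["a3"]
    a4: object = REFERENCE_PARAMS["a4"]
    a5: object = REFERENCE_PARAMS["a5"]
    a6: object = REFERENCE_PARAMS["a6"]
    w: float = 60.0      # kg, body weight
    u1b: float = 16.7    # mU/min, basal infusion (~1 U/h)
    gb: float = 130.0    # mg/dl, basal glucose

    def __post_init__(self):
        for name in ("w", "u1b", "gb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not callable(v) and not isinstance(v, UniformSeries):
                if float(v) <= 0:
                    raise ValueError(f"parameter {name} must be positive")

    @classmethod
    def from_multipliers(cls, multipliers: dict[str, float] | None = None,
                         xref: dict[str, float] | None = None, **kwargs
                         ) -> "PatientParams":
        """Build a patient as ``multiplier * xref`` per parameter; multipliers
        must lie in the admissible box [0.2, 1.8]."""
        xref = dict(REFERENCE_PARAMS if xref is None else xref)
        multipliers = multipliers or {}
        vals = {}
        for name in PARAM_NAMES:
            m = float(multipliers.get(name, 1.0))
            if not 0.2 <= m <= 1.8:
                raise ValueError(f"multiplier for {name} outside [0.2, 1.8]")
            vals[name] = m * xref[name]
        return cls(**vals, **kwargs)

    def value(self, name: str, t: float) -> float:
        return float(_as_func(getattr(self, name))(t))

    @property
    def ib(self) -> float:
        """Basal plasma insulin consistent with the basal infusion rate."""
        return self.value("p4", 0.0) / self.value("n", 0.0) * self.u1b

    def values_at(self, t: float) -> tuple:
        return tuple(self.value(name, t) for name in PARAM_NAMES)

    def is_constant(self) -> bool:
        return all(not callable(getattr(self, k))
                   and not isinstance(getattr(self, k), UniformSeries)
                   for k in PARAM_NAMES)


@dataclass
class ForcingSet:
    """The three forcing signals on a shared grid."""

    u1: UniformSeries
    u2: UniformSeries
    u3: UniformSeries

    def __post_init__(self):
        for s in (self.u2, self.u3):
            if (s.t0 != self.u1.t0 or s.dt != self.u1.dt
                    or len(s) != len(self.u1)):
                raise ValueError("forcing series must share a grid")
        for name in ("u1", "u2", "u3"):
            if np.any(getattr(self, name).values < -1e-12):
                raise ValueError(f"{name} must be non-negative")

    @property
    def t0(self):
        return self.u1.t0

    @property
    def dt(self):
        return self.u1.dt

    def __len__(self):
        return len(self.u1)


def basal_state(params: PatientParams) -> np.ndarray:
    """Default initial condition (Ib, 0, Gb, 0, 0, 0)."""
    return np.array([params.ib, 0.0, params.gb, 0.0, 0.0, 0.0])


def derivative(state, t: float, params: PatientParams, forcing: ForcingSet,
               exercise_offset: float = 0.0) -> np.ndarray:
    """Right-hand side of the twin ODE at time ``t`` (minutes).

    ``exercise_offset`` is added to u3 to form the exercise forcing E; the
    default 0 uses the above-basal intensity (rest => E = 0).
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    u1 = float(forcing.u1.value_at(t))
    u2 = float(forcing.u2.value_at(t)) * CARB_MG_PER_G
    e = float(forcing.u3.value_at(t)) + exercise_offset
    pv = params.values_at(t)
    return np.array(_deriv(tuple(state), pv, u1, u2, e, params.ib,
                           params.gb, params.w))


def _deriv(s, pv, u1, u2_mg, e, ib, gb, w):
    """Scalar-arithmetic RHS (fast path for the fixed-step integrator)."""
    n, vol_g, p1, p2, p3, p4, a1, a2, a3, a4, a5, a6 = pv
    i, x, g, gprod, gup, ie = s
    return (
        -n * i + p4 * u1 - ie,
        -p2 * x + p3 * (i - ib),
        -p1 * (g - gb) - x * g + (w / vol_g) * (gprod - gup) + u2_mg / vol_g,
        a1 * e - a2 * gprod,
        a3 * e - a4 * gup,
        a5 * e - a6 * ie,
    )


def simulate(params: PatientParams, forcing: ForcingSet,
             s0: np.ndarray | None = None, method: str = "rk4",
             substeps: int | None = None, exercise_offset: float = 0.0,
             rtol: float = 1e-8, atol: float = 1e-8) -> pd.DataFrame:
    """Integrate the twin over the forcing span; returns a DataFrame with
    columns ``t, I, X, G, Gprod, Gup, Ie`` on the forcing grid (cell left
    edges, plus the final edge).

    ``method="rk4"`` (default): classical Runge-Kutta with ``substeps`` steps
    per forcing cell (forcing and parameters held constant within a cell —
    they are step functions by construction).  ``method="lsoda"``: scipy's
    adaptive stiff-capable solver, used as the cross-checking integrator.
    """
    if s0 is None:
        s0 = basal_state(params)
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != (6,):
        raise ValueError("initial state must have 6 components")

    t_grid = np.append(forcing.u1.times, forcing.u1.t_end)
    ib, gb, w = params.ib, params.gb, params.w
    u1v = forcing.u1.values
    u2v = forcing.u2.values * CARB_MG_PER_G
    ev = forcing.u3.values + exercise_offset

    if method == "lsoda":
        from scipy.integrate import solve_ivp

        def rhs(t, s):
            return derivative(s, min(t, t_grid[-1] - 1e-9), params, forcing,
                              exercise_offset)

        sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), s0, method="LSODA",
                        t_eval=t_grid, rtol=rtol, atol=atol, max_step=forcing.dt)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        traj = sol.y.T
    elif method == "rk4":
        if substeps is None:
            substeps = max(1, int(round(forcing.dt)))  # ~1-min substeps
        h = forcing.dt / substeps
        const = params.is_constant()
        pv = params.values_at(0.0) if const else None
        s = tuple(s0)
        traj = np.empty((t_grid.size, 6))
        traj[0] = s
        for k in range(len(forcing)):
            t = t_grid[k]
            if not const:
                pv = params.values_at(t)
            u1, u2, e = u1v[k], u2v[k], ev[k]
            for _ in range(substeps):
                k1 = _deriv(s, pv, u1, u2, e, ib, gb, w)
                s2 = tuple(si + 0.5 * h * ki for si, ki in zip(s, k1))
                k2 = _deriv(s2, pv, u1, u2, e, ib, gb, w)
                s3 = tuple(si + 0.5 * h * ki for si, ki in zip(s, k2))
                k3 = _deriv(s3, pv, u1, u2, e, ib, gb, w)
                s4 = tuple(si + h * ki for si, ki in zip(s, k3))
                k4 = _deriv(s4, pv, u1, u2, e, ib, gb, w)
                s = tuple(si + h / 6.0 * (a + 2 * b + 2 * c + d)
                          for si, a, b, c, d in zip(s, k1, k2, k3, k4))
            traj[k + 1] = s
            if not all(np.isfinite(traj[k + 1])):
                raise RuntimeError(f"non-finite state at t={t_grid[k + 1]:.1f} min")
    else:
        raise ValueError(f"unknown method {method!r}")

    out = pd.DataFrame(traj, columns=list(STATE_NAMES))
    out.insert(0, "t", t_grid)
    return out


# ---------------------------------------------------------------------------
# Synthetic scenario generation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Daily-life schedule emulating pump/diary/fitness-band records.

    Defaults describe a free-living week: 2-4 self-reported meals per day with
    lognormal carbohydrate mass around ~50 g, meal boluses dosed at
    ``icr_mU_per_g * dose_factor`` mU per gram with pump modes drawn at random,
    a piecewise-constant basal rate around the patient's u1b, and at most one
    exercise bout per day raising heart rate to a plateau.  ``dose_factor=0.5``
    produces the chronically underdosed (hyperglycemia-prone) behavior policy.
    """

    duration_days: int = 7
    grid_dt: float = 1.0                 # min, rasterization grid
    meals_per_day: tuple[int, int] = (2, 4)
    carb_log_mean: float = float(np.log(50.0))   # lognormal location (grams)
    carb_log_sd: float = 0.35
    carb_bounds: tuple[float, float] = (10.0, 120.0)
    icr_mU_per_g: float = 120.0          # insulin-to-carb dosing gain
    dose_factor: float = 1.0             # 1.0 adequate, <1 underdosing
    bolus_mode_probs: tuple[float, ...] = (0.7, 0.1, 0.1, 0.1)  # normal, square, nd, sd
    extended_bolus_minutes: tuple[float, float] = (30.0, 90.0)
    basal_rel_jitter: float = 0.15       # piecewise-constant basal, 2 segments/day
    exercise_prob_per_day: float = 0.5
    exercise_minutes: tuple[float, float] = (30.0, 60.0)
    exercise_hr: tuple[float, float] = (105.0, 135.0)
    rest_hr: float = 72.0
    hr_dt: float = 5.0                   # min, fitness-band sampling

    def __post_init__(self):
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.icr_mU_per_g < 0 or self.dose_factor < 0:
            raise ValueError("dosing gains must be non-negative")
        if self.carb_bounds[0] <= 0:
            raise ValueError("carbohydrate bounds must be positive")


@dataclass
class Scenario:
    """Raw events plus their rasterized forcings."""

    events: list[EventRecord]
    forcing: ForcingSet
    hr: UniformSeries
    config: ScenarioConfig
    seed: int


_MODES = ("normal", "square", "normal_dual", "square_dual")


def make_scenario(seed: int, config: ScenarioConfig | None = None) -> Scenario:
    """Draw a reproducible synthetic daily-life scenario.

    Returns both the raw event stream (meals, boluses, basal segments, heart
    rate) and the rasterized forcing set (u1, u2, u3) on a 1-min grid.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    total_min = cfg.duration_days * 1440.0
    grid = UniformSeries(0.0, cfg.grid_dt,
                         np.zeros(int(total_min / cfg.grid_dt)))

    meal_slots = (7.5 * 60, 12.5 * 60, 18.5 * 60, 21.0 * 60)  # minutes of day
    events: list[EventRecord] = []
    basal: list[EventRecord] = []
    bouts: list[tuple[float, float, float]] = []
    u1b = 16.7

    for day in range(cfg.duration_days):
        day0 = day * 1440.0
        # basal: two segments per day with mild jitter around u1b
        for seg in range(2):
            rate = u1b * (1.0 + cfg.basal_rel_jitter * rng.uniform(-1, 1))
            basal.append(EventRecord("basal", day0 + seg * 720.0, rate))
        # meals + boluses
        n_meals = int(rng.integers(cfg.meals_per_day[0], cfg.meals_per_day[1] + 1))
        slots = rng.choice(len(meal_slots), size=n_meals, replace=False)
        for slot in sorted(slots):
            t_meal = day0 + meal_slots[slot] + rng.uniform(-45, 45)
            carbs = float(np.clip(rng.lognormal(cfg.carb_log_mean, cfg.carb_log_sd),
                                  *cfg.carb_bounds))
            events.append(EventRecord("meal", t_meal, carbs))
            dose = carbs * cfg.icr_mU_per_g * cfg.dose_factor
            if dose > 0:
                mode = _MODES[rng.choice(4, p=cfg.bolus_mode_probs)]
                t_end = None
                if mode != "normal":
                    t_end = t_meal + rng.uniform(*cfg.extended_bolus_minutes)
                events.append(EventRecord("bolus", t_meal, dose, t_end, mode))
        # exercise bout (internal; surfaced through the sampled HR channel)
        if rng.uniform() < cfg.exercise_prob_per_day:
            start = day0 + rng.uniform(16 * 60, 19 * 60)
            dur = rng.uniform(*cfg.exercise_minutes)
            hr_peak = rng.uniform(*cfg.exercise_hr)
            bouts.append((start, start + dur, hr_peak))

    # heart-rate series: resting baseline with plateaus during bouts
    hr_n = int(total_min / cfg.hr_dt)
    hr_t = cfg.hr_dt * np.arange(hr_n)
    hr = np.full(hr_n, cfg.rest_hr) + rng.normal(0.0, 1.5, hr_n)
    ramp = 5.0
    for t_on, t_off, hr_peak in bouts:
        rise = np.clip((hr_t - t_on) / ramp, 0, 1)
        fall = np.clip((t_off - hr_t) / ramp, 0, 1)
        hr += (hr_peak - cfg.rest_hr) * np.minimum(rise, fall)
    hr_series = UniformSeries(0.0, cfg.hr_dt, hr, unit="bpm")
    events.extend(EventRecord("heart_rate", t, v)
                  for t, v in zip(hr_t, hr))

    meals = [e for e in events if e.kind == "meal"]
    boluses = [e for e in events if e.kind == "bolus"]
    u1 = total_insulin_rate(basal, [], boluses, grid)
    u2 = meals_to_u2(meals, grid)
    _, u3_coarse = heart_rate_to_u3(hr_series)
    u3 = UniformSeries(0.0, cfg.grid_dt, u3_coarse.value_at(grid.times),
                       unit="%VO2max")
    events = basal + events
    return Scenario(events, ForcingSet(u1, u2, u3), hr_series, cfg, seed)


def synthesize_cgm(params: PatientParams, scenario: Scenario,
                   sample_dt: float = 5.0, noise_sd: float = 0.0,
                   gaps_per_day: float = 0.5,
                   gap_minutes: tuple[float, float] = (15.0, 75.0),
                   seed: int = 0) -> tuple[UniformSeries, pd.DataFrame]:
    """Simulate the twin on a scenario and sample a CGM trace from G.

    Returns ``(cgm, trajectory)``.  Optional Gaussian sensor noise and random
    dropout gaps (NaN spans, later imputed+flagged by the preprocessing layer)
    emulate real CGM streams; both default to benign settings.
    """
    rng = np.random.default_rng(seed)
    traj = simulate(params, scenario.forcing)
    t = np.arange(scenario.forcing.t0, scenario.forcing.u1.t_end, sample_dt)
    g = np.interp(t, traj["t"].to_numpy(), traj["G"].to_numpy())
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, g.size)
    n_gaps = rng.poisson(gaps_per_day * scenario.config.duration_days)
    for _ in range(n_gaps):
        start = rng.uniform(t[0], t[-1])
        width = rng.uniform(*gap_minutes)
        g[(t >= start) & (t < start + width)] = np.nan
    if np.isnan(g).all():
        raise RuntimeError("CGM dropout removed every sample")
    return UniformSeries(t[0], sample_dt, g, unit="mg/dl"), traj


# ---------------------------------------------------------------------------
# Ground-truth serialization (for parameter-recovery experiments)
# ---------------------------------------------------------------------------

def ground_truth_table(params: PatientParams) -> str:
    """Serialize a parameter set to YAML; round-trips exactly."""
    rec: dict = {"w": params.w, "u1b": params.u1b, "gb": params.gb}
    for name in PARAM_NAMES:
        v = getattr(params, name)
        if isinstance(v, UniformSeries):
            rec[name] = {"t0": v.t0, "dt": v.dt, "values": v.values.tolist(),
                         "unit": v.unit}
        elif callable(v):
            raise TypeError("callable parameters cannot be serialized")
        else:
            rec[name] = float(v)
    return yaml.safe_dump(rec, sort_keys=True)


def load_ground_truth(text: str) -> PatientParams:
    rec = yaml.safe_load(text)
    kwargs: dict = {}
    for name, v in rec.items():
        if isinstance(v, dict):
            kwargs[name] = UniformSeries(v["t0"], v["dt"],
                                         np.array(v["values"]), v.get("unit", ""))
        else:
            kwargs[name] = v
    return PatientParams(**kwargs)
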