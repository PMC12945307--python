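"""Wearable/pump event records -> uniformly sampled model forcings.

Converts raw time-stamped records (CGM glucose, basal / temp-basal / bolus
insulin, self-reported meals, heart rate) into the three forcing signals of the
glucose-insulin twin:

* ``u1`` — total insulin infusion rate (mU/min): basal + bolus, with temp-basal
  windows overriding the bolus term while active;
* ``u2`` — meal glucose appearance rate (g/min): each meal of ``m`` grams enters
  as a decaying exponential ``0.0083 * m * exp(-0.0083 * (t - t_meal))``, whose
  kernel integrates to the full carbohydrate mass;
* ``u3`` — exercise intensity: percentage of maximal oxygen uptake above the
  resting level of 8, derived linearly from heart rate
  (``PVO2max = 0.888 * HR - 71.91``) and clamped at zero.

Canonical internal units: minutes, mg/dl, mU/min, grams, bpm.
Grid cells are half-open ``[t, t + dt)``; instantaneous signals are sampled at
left edges, dose-type events are rasterized by exact overlap so that delivered
insulin equals the logged dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EventRecord", "UniformSeries",
    "MEAL_DECAY_PER_MIN", "NORMAL_BOLUS_MINUTES",
    "HR_SLOPE", "HR_INTERCEPT", "PVO2MAX_BASAL",
    "bolus_to_rate", "total_insulin_rate", "meals_to_u2",
    "pvo2max_to_u3", "heart_rate_to_u3",
    "impute_and_align", "coarse_grain", "rolling_mean",
]

#: exponential decay constant of the meal-appearance kernel (1/min)
MEAL_DECAY_PER_MIN = 0.0083
#: nominal release time of a normal-mode bolus (min)
NORMAL_BOLUS_MINUTES = 10.0
#: heart rate -> %VO2max conversion: PVO2max = HR_SLOPE * HR + HR_INTERCEPT
HR_SLOPE = 0.888
HR_INTERCEPT = -71.91
#: resting %VO2max subtracted before exercise forcing
PVO2MAX_BASAL = 8.0

_KINDS = {"basal", "temp_basal", "bolus", "meal", "heart_rate", "cgm"}
_BOLUS_MODES = {"normal", "square", "normal_dual", "square_dual"}


@dataclass(frozen=True)
class EventRecord:
    """One raw record from the pump / sensor / diary stream.

    ``value`` semantics by kind: basal & temp_basal — rate in mU/min; bolus —
    total dose in mU; meal — grams of carbohydrate; heart_rate — bpm;
    cgm — mg/dl.  ``mode`` is present iff kind == "bolus".
    """

    kind: str
    t_start: float
    value: float
    t_end: float | None = None
    mode: str | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.value < 0:
            raise ValueError(f"{self.kind} event with negative value {self.value}")
        if (self.mode is not None) != (self.kind == "bolus"):
            raise ValueError("mode must be present iff kind == 'bolus'")
        if self.kind == "bolus" and self.mode not in _BOLUS_MODES:
            raise ValueError(f"unknown bolus mode {self.mode!r}")
        if self.t_end is not None and self.t_end < self.t_start:
            raise ValueError("t_end < t_start")


@dataclass
class UniformSeries:
    """Regularly sampled scalar series on the grid ``t0 + k*dt``, k = 0..n-1.

    ``mask`` (optional) marks samples that are genuine observations; imputed
    values inside flagged gaps carry ``mask=False`` and are excluded from
    observation-driven losses downstream.
    """

    t0: float
    dt: float
    values: np.ndarray
    unit: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")

    def __len__(self):
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        """End of the last half-open cell."""
        return self.t0 + self.dt * self.values.size

    def zeros_like(self, unit: str = "") -> "UniformSeries":
        return UniformSeries(self.t0, self.dt, np.zeros_like(self.values), unit)

    def value_at(self, t) -> np.ndarray:
        """Zero-order-hold lookup (cell containing t; clipped at the ends)."""
        idx = np.clip(np.floor((np.asarray(t) - self.t0) / self.dt).astype(int),
                      0, self.values.size - 1)
        return self.values[idx]


# ---------------------------------------------------------------------------
# Insulin
# ---------------------------------------------------------------------------

def _bolus_segments(rec: EventRecord, strict: bool) -> list[tuple[float, float, float]]:
    """(start, end, rate) segments for one bolus; rates conserve the dose unless
    ``strict`` reproduces the literal dual-mode formula."""
    x = rec.value
    if x == 0:
        return []
    if rec.mode == "normal":
        return [(rec.t_start, rec.t_start + NORMAL_BOLUS_MINUTES,
                 x / NORMAL_BOLUS_MINUTES)]
    if rec.t_end is None or rec.t_end <= rec.t_start:
        raise ValueError(f"{rec.mode} bolus requires t_end > t_start")
    if rec.mode == "square":
        return [(rec.t_start, rec.t_end, x / (rec.t_end - rec.t_start))]

    # dual modes: dose split 50/50; release order follows the mode name
    half_dose = 0.5 * x
    mid = 0.5 * (rec.t_start + rec.t_end)
    half_len = mid - rec.t_start

    def normal_part(a: float, b: float) -> tuple[float, float, float]:
        if strict:
            # literal reading: rate x/2/10 over the whole half-interval
            return (a, b, half_dose / NORMAL_BOLUS_MINUTES)
        dur = min(NORMAL_BOLUS_MINUTES, b - a)
        return (a, a + dur, half_dose / dur)  # rescaled if truncated

    def square_part(a: float, b: float) -> tuple[float, float, float]:
        return (a, b, half_dose / (b - a))

    if rec.mode == "normal_dual":
        return [normal_part(rec.t_start, mid), square_part(mid, rec.t_end)]
    return [square_part(rec.t_start, mid), normal_part(mid, rec.t_end)]  # square_dual


def _rasterize_segments(segments, grid: UniformSeries) -> np.ndarray:
    """Cell-averaged rasterization: exact overlap of each constant-rate segment
    with each half-open grid cell, so the time integral is preserved."""
    out = np.zeros(len(grid))
    edges = grid.t0 + grid.dt * np.arange(len(grid) + 1)
    for a, b, rate in segments:
        lo = np.clip(np.maximum(edges[:-1], a), None, b)
        hi = np.clip(np.minimum(edges[1:], b), a, None)
        out += rate * np.clip(hi - lo, 0.0, None) / grid.dt
    return out


def bolus_to_rate(rec: EventRecord, grid: UniformSeries,
                  strict_eq2: bool = False) -> UniformSeries:
    """Rate contribution (mU/min) of a single bolus on the grid.

    normal: ``x/10`` over 10 min; square: ``x/(t_end-t_start)``; dual modes
    split the dose 50/50 across the two half-intervals, released with the
    first-named then second-named mode.  With ``strict_eq2=False`` (default)
    the normal component of a dual bolus runs for min(10, half-interval)
    minutes and is rescaled so each half integrates to exactly x/2.
    """
    if rec.kind != "bolus":
        raise ValueError("record is not a bolus")
    return UniformSeries(grid.t0, grid.dt,
                         _rasterize_segments(_bolus_segments(rec, strict_eq2), grid),
                         unit="mU/min")


def _basal_series(basal: list[EventRecord], grid: UniformSeries) -> np.ndarray:
    """Piecewise-constant basal: each record sets the rate from its t_start
    until the next record (zero before the first record)."""
    out = np.zeros(len(grid))
    if not basal:
        return out
    recs = sorted(basal, key=lambda r: r.t_start)
    t = grid.times
    starts = np.array([r.t_start for r in recs])
    vals = np.array([r.value for r in recs])
    idx = np.searchsorted(starts, t, side="right") - 1
    covered = idx >= 0
    out[covered] = vals[idx[covered]]
    return out


def total_insulin_rate(basal: list[EventRecord], temp_basal: list[EventRecord],
                       boluses: list[EventRecord], grid: UniformSeries,
                       strict_eq2: bool = False) -> UniformSeries:
    """Total infusion rate u1 = basal + bolus outside temp-basal windows;
    inside a temp-basal window the temp-basal rate replaces the bolus term
    (basal persists).  Overlapping temp-basal windows are rejected."""
    tb = sorted(temp_basal, key=lambda r: r.t_start)
    for a, b in zip(tb[:-1], tb[1:]):
        if a.t_end is None or b.t_start < a.t_end:
            raise ValueError("overlapping temp-basal windows")

    t = grid.times
    u1 = _basal_series(basal, grid)
    bolus_sum = np.zeros(len(grid))
    for rec in boluses:
        bolus_sum += bolus_to_rate(rec, grid, strict_eq2).values

    in_temp = np.zeros(len(grid), dtype=bool)
    temp_rate = np.zeros(len(grid))
    for rec in tb:
        if rec.t_end is None:
            raise ValueError("temp_basal record requires t_end")
        sel = (t >= rec.t_start) & (t < rec.t_end)  # left-edge inclusion
        in_temp |= sel
        temp_rate[sel] = rec.value

    u1 = u1 + np.where(in_temp, temp_rate, bolus_sum)
    return UniformSeries(grid.t0, grid.dt, u1, unit="mU/min")


# ---------------------------------------------------------------------------
# Meals and exercise
# ---------------------------------------------------------------------------

def meals_to_u2(meals: list[EventRecord], grid: UniformSeries) -> UniformSeries:
    """Meal glucose appearance rate (g/min), left-edge sampled.

    Each meal of m grams at t_j contributes
    ``0.0083 * m * exp(-0.0083 * (t - t_j))`` for t >= t_j; the kernel
    integrates to m, so carbohydrate mass is conserved.
    """
    t = grid.times
    u2 = np.zeros(len(grid))
    for rec in meals:
        if rec.kind != "meal":
            raise ValueError("record is not a meal")
        dt_since = t - rec.t_start
        active = dt_since >= 0
        u2[active] += (MEAL_DECAY_PER_MIN * rec.value
                       * np.exp(-MEAL_DECAY_PER_MIN * dt_since[active]))
    return UniformSeries(grid.t0, grid.dt, u2, unit="g/min")


def pvo2max_to_u3(pvo2max):
    """Exercise intensity above the resting level: max(PVO2max - 8, 0)."""
    return np.maximum(np.asarray(pvo2max, dtype=float) - PVO2MAX_BASAL, 0.0)


def heart_rate_to_u3(hr: UniformSeries) -> tuple[UniformSeries, UniformSeries]:
    """HR (bpm) -> (PVO2max, u3). PVO2max = 0.888*HR - 71.91, u3 clamped >= 0."""
    pvo = HR_SLOPE * hr.values + HR_INTERCEPT
    u3 = pvo2max_to_u3(pvo)
    return (UniformSeries(hr.t0, hr.dt, pvo, unit="%VO2max"),
            UniformSeries(hr.t0, hr.dt, u3, unit="%VO2max"))


# ---------------------------------------------------------------------------
# Imputation / alignment
# ---------------------------------------------------------------------------

def _interp_nan(values: np.ndarray, dt: float, gap_flag_minutes: float | None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of interior NaN runs; runs longer than the flag
    threshold are still filled (the series must be gap-free) but their mask is
    set False so downstream fitting can exclude them."""
    v = values.astype(float).copy()
    mask = ~np.isnan(v)
    if mask.all():
        return v, mask
    if not mask.any():
        raise ValueError("series has no observed samples")
    idx = np.arange(v.size)
    v[~mask] = np.interp(idx[~mask], idx[mask], v[mask])
    keep = mask.copy()
    if gap_flag_minutes is not None:
        # flag long interior gaps
        run_start = None
        for i in range(v.size + 1):
            missing = i < v.size and not mask[i]
            if missing and run_start is None:
                run_start = i
            elif not missing and run_start is not None:
                if (i - run_start) * dt <= gap_flag_minutes:
                    keep[run_start:i] = True  # short gap: trust the fill
                run_start = None
    else:
        keep[:] = True
    return v, keep


def impute_and_align(series: dict[str, UniformSeries], target_dt: float,
                     smooth_window: int | None = None,
                     gap_flag_minutes: float | None = 60.0,
                     ) -> dict[str, UniformSeries]:
    """Fill interior gaps, trim all channels to their common span, and resample
    onto a shared grid of spacing ``target_dt``.

    The common span starts at the latest ``t0`` and ends at the earliest end
    among the inputs.  NaN samples are linearly interpolated; interior gaps
    longer than ``gap_flag_minutes`` keep ``mask=False``.  An optional centered
    rolling mean of ``smooth_window`` points is applied after resampling.
    """
    if not series:
        raise ValueError("no series given")
    t0 = max(s.t0 for s in series.values())
    t_last = min(s.times[-1] for s in series.values())
    if t_last < t0:
        raise ValueError("series do not overlap in time")
    n = int(np.floor((t_last - t0) / target_dt)) + 1
    t_new = t0 + target_dt * np.arange(n)

    out = {}
    for name, s in series.items():
        filled, mask = _interp_nan(s.values, s.dt, gap_flag_minutes)
        v = np.interp(t_new, s.times, filled)
        m = np.interp(t_new, s.times, mask.astype(float)) >= 1.0 - 1e-12
        if smooth_window is not None and smooth_window > 1:
            v = rolling_mean(v, smooth_window)
        out[name] = UniformSeries(t0, target_dt, v, unit=s.unit, mask=m)
    return out


def rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edge-truncated (same length as the input)."""
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def coarse_grain(s: UniformSeries, target_dt: float = 60.0) -> UniformSeries:
    """Block-average down to ``target_dt`` (e.g. the 1-h control grid)."""
    factor = int(round(target_dt / s.dt))
    if factor < 1 or abs(factor * s.dt - target_dt) > 1e-9:
        raise ValueError("target_dt must be an integer multiple of dt")
    n = (len(s) // factor) * factor
    if n == 0:
        raise ValueError("series shorter than one coarse cell")
    v = s.values[:n].reshape(-1, factor).mean(axis=1)
    mask = None
    if s.mask is not None:
        mask = s.mask[:n].reshape(-1, factor).all(axis=1)
    return UniformSeries(s.t0, target_dt, v, unit=s.unit, mask=mask)
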