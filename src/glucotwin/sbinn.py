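"""Systems-biology-informed neural network (SBINN) inference for the twin.

A state network maps time to the six physical states (I, X, G, Gprod, Gup,
Ie) through an input-scaling layer (t normalized to [0, 1]), a Fourier feature
layer, a tanh MLP, and an output-scaling layer (per-state scale + basal
offset).  A bounded parameter head emits the ODE parameters, squashed by a
sigmoid onto the admissible box [0.2, 1.8] * xref (the raw midpoint maps to
xref exactly).

Training minimizes the composite loss

    L' = L_data + lambda_o * L_ode + lambda_a * L_aux

over the network and parameter head while the non-negative self-adaptive
weights lambda_o, lambda_a ascend their own gradients
(d L'/d lambda_o = L_ode, d L'/d lambda_a = L_aux), a min-max scheme that
automatically rebalances the loss terms.  L_data is the MSE between the
network's glucose output and CGM observations (glucose is the only observed
state; flagged CGM gaps are excluded); L_ode is the mean squared ODE residual
at collocation points, with the time derivative of the state network obtained
by exact forward-mode differentiation built into the computation graph;
L_aux pins the basal initial condition (Ib, 0, Gb, 0, 0, 0).

Validation closes the loop: `reconstruct` re-solves the ODE forward with the
inferred parameters and the result is scored on the Clarke error grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._nn import Adam, Dense, MLP, Tensor, concat
from .signals import UniformSeries
from .twin import (CARB_MG_PER_G, PARAM_NAMES, REFERENCE_PARAMS, ForcingSet,
                   PatientParams, simulate)

__all__ = ["SBINNConfig", "LossBreakdown", "InferredModel", "bound_params",
           "self_adaptive_step", "train", "data_loss", "ode_loss", "aux_loss",
           "multi_seed_band", "reconstruct"]

_STATE_SCALE = (50.0, 0.02, 80.0, 1.0, 1.0, 0.3)


@dataclass
class SBINNConfig:
    """Architecture and optimization settings.

    ``collocation_density`` is the number of collocation points relative to
    the number of observations (uniformly spaced over the training span).
    ``rho_o``/``rho_a`` are the ascent rates of the self-adaptive weights and
    are equal by default.  The box multipliers bound every emitted parameter
    to ``[box_lo, box_hi] * xref``.
    """

    hidden: tuple[int, ...] = (64, 64)
    n_fourier: int = 64
    fourier_max_freq: float | None = None   # cycles/span; None -> n_fourier
    collocation_density: float = 4.0
    lr_net: float = 1e-3
    lr_params: float = 5e-3
    rho_o: float = 0.1
    rho_a: float = 0.1
    lr_decay_points: tuple[float, ...] = (0.5, 0.8)   # fractions of training
    lr_decay_factor: float = 0.2
    basal_consistency_weight: float = 1.0
    warmup_reference_states: bool = True
    lbfgs_iterations: int = 0          # full-batch finishing phase
    box_lo: float = 0.2
    box_hi: float = 1.8
    iterations: int = 20000
    warmup_iterations: int = 2000      # data + aux only
    data_batch: int = 256
    collocation_batch: int = 256
    state_scale: tuple[float, ...] = _STATE_SCALE
    param_mode: str = "constant"       # "constant" | "time_varying"
    param_time_features: int = 4       # low-frequency features for the head
    record_every: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.box_lo < self.box_hi:
            raise ValueError("require 0 < box_lo < box_hi")
        if self.rho_o < 0 or self.rho_a < 0:
            raise ValueError("self-adaptive rates must be non-negative")
        if self.param_mode not in ("constant", "time_varying"):
            raise ValueError("param_mode must be 'constant' or 'time_varying'")


@dataclass
class LossBreakdown:
    l_data: float
    l_ode: float
    l_aux: float
    lam_o: float
    lam_a: float
    iteration: int = 0

    @property
    def total(self) -> float:
        return self.l_data + self.lam_o * self.l_ode + self.lam_a * self.l_aux


def bound_params(raw, xref, lo: float = 0.2, hi: float = 1.8):
    """Sigmoid squash of raw head output onto [lo, hi] * xref.

    Works on numpy arrays and autodiff tensors; raw = 0 maps to the midpoint
    (lo + hi)/2 * xref, which equals xref for the default box.
    """
    if isinstance(raw, Tensor):
        return (lo + (hi - lo) * raw.sigmoid()) * Tensor(np.asarray(xref, float))
    s = 1.0 / (1.0 + np.exp(-np.clip(np.asarray(raw, dtype=float), -500, 500)))
    return (lo + (hi - lo) * s) * np.asarray(xref, dtype=float)


def self_adaptive_step(lam_o: float, lam_a: float, l_ode: float, l_aux: float,
                       rho_o: float, rho_a: float) -> tuple[float, float]:
    """One gradient-ascent step on the self-adaptive weights.

    Since L' is linear in each weight, dL'/dlambda_o = L_ode and
    dL'/dlambda_a = L_aux; the updated weights are clipped at zero.
    """
    if rho_o < 0 or rho_a < 0:
        raise ValueError("learning rates must be non-negative")
    if lam_o < 0 or lam_a < 0:
        raise ValueError("weights must be non-negative")
    return (max(lam_o + rho_o * l_ode, 0.0),
            max(lam_a + rho_a * l_aux, 0.0))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class InferredModel:
    """Trained state network + bounded parameter head.

    ``states_at(t)`` evaluates the network in physical units;
    ``params_at(t)`` emits the bounded parameter trajectory; ``history``
    records the loss breakdown over training.
    """

    def __init__(self, cfg: SBINNConfig, t0: float, span: float,
                 w: float, u1b: float, gb: float, ib: float,
                 xref: dict[str, float]):
        self.cfg = cfg
        self.t0 = t0
        self.span = span
        self.w, self.u1b, self.gb, self.ib = w, u1b, gb, ib
        self.xref = dict(xref)
        self.xref_vec = np.array([xref[k] for k in PARAM_NAMES])
        self.scale = np.asarray(cfg.state_scale, dtype=float)
        self.offset = np.array([ib, 0.0, gb, 0.0, 0.0, 0.0])
        rng = np.random.default_rng(cfg.seed)
        max_freq = cfg.fourier_max_freq or cfg.n_fourier
        self.freqs = 2.0 * np.pi * np.linspace(1.0, max_freq, cfg.n_fourier)
        n_feat = 1 + 2 * cfg.n_fourier
        self.net = MLP([n_feat, *cfg.hidden, 6], rng, activation="tanh")
        if cfg.param_mode == "constant":
            self.raw_params = Tensor(np.zeros(len(PARAM_NAMES)),
                                     requires_grad=True)
            self.param_head = None
        else:
            k = cfg.param_time_features
            self.param_head = Dense(1 + 2 * k, len(PARAM_NAMES), rng)
            self.param_head.W.data *= 0.0   # start exactly at xref
            self.param_head.b.data *= 0.0
            self.raw_params = None
        self.history: list[LossBreakdown] = []

    # features --------------------------------------------------------------
    def _features(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fourier features of scaled time and their derivatives w.r.t. t."""
        th = ((np.asarray(t, dtype=float) - self.t0) / self.span)[:, None]
        ang = th * self.freqs[None, :]
        f = np.concatenate([th, np.sin(ang), np.cos(ang)], axis=1)
        df = np.concatenate([np.ones_like(th),
                             np.cos(ang) * self.freqs[None, :],
                             -np.sin(ang) * self.freqs[None, :]],
                            axis=1) / self.span
        return f, df

    def _param_features(self, t: np.ndarray) -> np.ndarray:
        k = self.cfg.param_time_features
        th = ((np.asarray(t, dtype=float) - self.t0) / self.span)[:, None]
        ang = th * (2.0 * np.pi * np.arange(1, k + 1))[None, :]
        return np.concatenate([th, np.sin(ang), np.cos(ang)], axis=1)

    # forward passes ---------------------------------------------------------
    def forward(self, t: np.ndarray, with_tdot: bool = False):
        """Physical states (and optionally their exact time derivatives).

        The tangent (d state / d t) is propagated through the same graph:
        for each tanh layer h = tanh(W h_prev + b), the tangent obeys
        v = (1 - h^2) * (W v_prev), so reverse-mode backprop through the pair
        yields exact parameter gradients of derivative-dependent losses.
        """
        f, df = self._features(t)
        h = Tensor(f)
        v = Tensor(df) if with_tdot else None
        for layer in self.net.layers[:-1]:
            h = layer(h).tanh()
            if with_tdot:
                v = (1.0 - h * h) * (v @ layer.W)
        last = self.net.layers[-1]
        y = last(h) * Tensor(self.scale) + Tensor(self.offset)
        if not with_tdot:
            return y
        ydot = (v @ last.W) * Tensor(self.scale)
        return y, ydot

    def param_tensor(self, t: np.ndarray | None = None) -> Tensor:
        """Bounded parameters: shape (12,) (constant) or (B, 12)."""
        cfg = self.cfg
        if cfg.param_mode == "constant":
            raw = self.raw_params
        else:
            raw = self.param_head(Tensor(self._param_features(t)))
        return bound_params(raw, self.xref_vec, cfg.box_lo, cfg.box_hi)

    def trainable_parameters(self):
        ps = self.net.parameters()
        if self.raw_params is not None:
            return ps, [self.raw_params]
        return ps, self.param_head.parameters()

    # public numpy API -------------------------------------------------------
    def states_at(self, t) -> np.ndarray:
        return self.forward(np.atleast_1d(np.asarray(t, float))).data

    def params_at(self, t) -> pd.DataFrame:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        p = self.param_tensor(t).data
        if p.ndim == 1:
            p = np.broadcast_to(p, (t.size, p.size))
        out = pd.DataFrame(p, columns=list(PARAM_NAMES))
        out.insert(0, "t", t)
        return out

    def to_patient_params(self, grid_dt: float = 60.0) -> PatientParams:
        """Export inferred parameters as a PatientParams for forward solving."""
        if self.cfg.param_mode == "constant":
            vals = dict(zip(PARAM_NAMES, self.param_tensor().data))
        else:
            t = np.arange(self.t0, self.t0 + self.span + grid_dt, grid_dt)
            p = self.param_tensor(t).data
            vals = {name: UniformSeries(self.t0, grid_dt, p[:, k])
                    for k, name in enumerate(PARAM_NAMES)}
        return PatientParams(**vals, w=self.w, u1b=self.u1b, gb=self.gb)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _residuals(model: InferredModel, y: Tensor, ydot: Tensor, p: Tensor,
               u1: np.ndarray, u2_mg: np.ndarray, e: np.ndarray) -> list:
    """ODE residuals (one tensor of shape (B,) per state equation)."""
    cols = [y[:, k] for k in range(6)]
    d = [ydot[:, k] for k in range(6)]
    i, x, g, gprod, gup, ie = cols
    if p.data.ndim == 1:
        pk = [p[k] for k in range(12)]
    else:
        pk = [p[:, k] for k in range(12)]
    n, vol_g, p1, p2, p3, p4, a1, a2, a3, a4, a5, a6 = pk
    w = model.w
    return [
        d[0] + n * i - p4 * Tensor(u1) + ie,
        d[1] + p2 * x - p3 * (i - model.ib),
        d[2] + p1 * (g - model.gb) + x * g
        - w * (gprod - gup) / vol_g - Tensor(u2_mg) / vol_g,
        d[3] - a1 * Tensor(e) + a2 * gprod,
        d[4] - a3 * Tensor(e) + a4 * gup,
        d[5] - a5 * Tensor(e) + a6 * ie,
    ]


#: characteristic time (min) converting state scales to residual scales
_RESIDUAL_TIME = 30.0


def _ode_loss_tensor(model: InferredModel, t: np.ndarray, u1, u2_mg, e) -> Tensor:
    y, ydot = model.forward(t, with_tdot=True)
    p = model.param_tensor(t if model.cfg.param_mode == "time_varying" else None)
    res = _residuals(model, y, ydot, p, u1, u2_mg, e)
    r_scale = model.scale / _RESIDUAL_TIME
    terms = [((rk * (1.0 / sk)) ** 2).mean() for rk, sk in zip(res, r_scale)]
    total = terms[0]
    for tm in terms[1:]:
        total = total + tm
    return total * (1.0 / 6.0)


def _data_loss_tensor(model: InferredModel, t: np.ndarray, g_obs: np.ndarray
                      ) -> Tensor:
    g = model.forward(t)[:, 2]
    diff = (g - Tensor(g_obs)) * (1.0 / model.scale[2])
    return (diff ** 2).mean()


def _aux_loss_tensor(model: InferredModel, s0: np.ndarray) -> Tensor:
    y0 = model.forward(np.array([model.t0]))
    diff = (y0 - Tensor(s0[None, :])) * Tensor(1.0 / model.scale)
    return (diff ** 2).sum()


def _basal_consistency_tensor(model: InferredModel) -> Tensor:
    """Known basal insulin ties the infusion gain to the clearance rate:
    Ib = (p4/n) u1b, enforced as a dimensionless squared residual."""
    p = model.param_tensor(np.array([model.t0])
                           if model.cfg.param_mode == "time_varying" else None)
    if p.data.ndim == 2:
        p = p[0, :]
    n, p4 = p[0], p[5]
    return ((p4 * model.u1b / (n * model.ib)) - 1.0) ** 2


def data_loss(model: InferredModel, cgm: UniformSeries) -> float:
    """MSE (in scaled units) between network glucose and CGM observations.

    Samples whose mask is False (flagged imputation gaps) are excluded.
    """
    keep = cgm.mask if cgm.mask is not None else np.ones(len(cgm), dtype=bool)
    if not keep.any():
        raise ValueError("no observed CGM samples")
    return float(_data_loss_tensor(model, cgm.times[keep],
                                   cgm.values[keep]).data)


def ode_loss(model: InferredModel, forcing: ForcingSet, tau: np.ndarray) -> float:
    """Mean squared ODE residual at collocation times ``tau``."""
    tau = np.asarray(tau, dtype=float)
    if tau.min() < forcing.t0 or tau.max() > forcing.u1.t_end:
        raise ValueError("collocation point outside the forcing span")
    u1 = forcing.u1.value_at(tau)
    u2 = forcing.u2.value_at(tau) * CARB_MG_PER_G
    e = forcing.u3.value_at(tau)
    return float(_ode_loss_tensor(model, tau, u1, u2, e).data)


def aux_loss(model: InferredModel, s0: np.ndarray | None = None) -> float:
    """Squared mismatch (scaled units) to the initial state, summed over the
    six components; default s0 is the basal state (Ib, 0, Gb, 0, 0, 0)."""
    if s0 is None:
        s0 = np.array([model.ib, 0.0, model.gb, 0.0, 0.0, 0.0])
    return float(_aux_loss_tensor(model, np.asarray(s0, float)).data)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(cfg: SBINNConfig, cgm: UniformSeries, forcing: ForcingSet,
          w: float = 60.0, u1b: float = 16.7, gb: float | None = None,
          ib: float | None = None, xref: dict[str, float] | None = None,
          ) -> InferredModel:
    """Fit the SBINN to a CGM trace and its forcing signals.

    ``gb`` defaults to the first observed CGM value and ``ib`` to the basal
    insulin implied by the reference parameters, (p4_ref/n_ref) * u1b; both
    can be supplied when better patient-specific estimates exist.  Training is
    deterministic given ``cfg.seed``.

    The warm-up phase fits observations and the initial condition, and (by
    default) also the hidden states of the *reference-parameter* twin solved
    forward on the same forcings — an initialization from the prior model
    that leaves the hidden exercise/insulin states physically plausible
    instead of zero; without it the exercise gains tend to collapse to the
    box bound, where the squashing transform saturates and gradients vanish.
    The reference trajectory is dropped entirely after warm-up; the min-max
    objective with self-adaptive weights (starting at 1) then refines states
    and parameters jointly.
    """
    xref = dict(REFERENCE_PARAMS if xref is None else xref)
    keep = cgm.mask if cgm.mask is not None else np.ones(len(cgm), dtype=bool)
    t_data = cgm.times[keep]
    g_data = cgm.values[keep]
    if t_data.size == 0:
        raise ValueError("no observed CGM samples")
    if gb is None:
        gb = float(g_data[0])
    if ib is None:
        ib = xref["p4"] / xref["n"] * u1b

    t0 = float(t_data[0])
    span = float(max(t_data[-1] - t0, forcing.u1.t_end - t0))
    model = InferredModel(cfg, t0, span, w, u1b, gb, ib, xref)
    s0 = np.array([ib, 0.0, gb, 0.0, 0.0, 0.0])

    n_colloc = max(int(cfg.collocation_density * t_data.size), 16)
    tau = np.linspace(t0, forcing.u1.t_end - 1e-9, n_colloc)
    u1c = forcing.u1.value_at(tau)
    u2c = forcing.u2.value_at(tau) * CARB_MG_PER_G
    ec = forcing.u3.value_at(tau)

    ref_states = None
    if cfg.warmup_reference_states and cfg.warmup_iterations > 0:
        ref_patient = PatientParams(**{k: xref[k] for k in PARAM_NAMES},
                                    w=w, u1b=u1b, gb=gb)
        ref_traj = simulate(ref_patient, forcing)
        t_ref = ref_traj["t"].to_numpy()
        ref_states = np.column_stack([
            np.interp(tau, t_ref, ref_traj[name].to_numpy())
            for name in ("I", "X", "G", "Gprod", "Gup", "Ie")])

    rng = np.random.default_rng(cfg.seed + 1)
    net_params, head_params = model.trainable_parameters()
    opt_net = Adam(net_params, lr=cfg.lr_net)
    opt_head = Adam(head_params, lr=cfg.lr_params)
    all_params = net_params + head_params

    decay_at = {int(f * cfg.iterations) for f in cfg.lr_decay_points}
    lam_o, lam_a = 1.0, 1.0
    for it in range(cfg.iterations):
        if it in decay_at:
            opt_net.lr *= cfg.lr_decay_factor
            opt_head.lr *= cfg.lr_decay_factor
        di = rng.integers(0, t_data.size, min(cfg.data_batch, t_data.size))
        l_data = _data_loss_tensor(model, t_data[di], g_data[di])
        l_aux = _aux_loss_tensor(model, s0)
        warmup = it < cfg.warmup_iterations
        if warmup:
            total = l_data + lam_a * l_aux
            if ref_states is not None:
                ci = rng.integers(0, tau.size,
                                  min(cfg.collocation_batch, tau.size))
                y_ref = model.forward(tau[ci])
                diff = (y_ref - Tensor(ref_states[ci])) \
                    * Tensor(1.0 / model.scale)
                total = total + (diff ** 2).mean()
            l_ode_val = float("nan")
        else:
            ci = rng.integers(0, tau.size, min(cfg.collocation_batch, tau.size))
            l_ode = _ode_loss_tensor(model, tau[ci], u1c[ci], u2c[ci], ec[ci])
            total = l_data + lam_o * l_ode + lam_a * l_aux
            if cfg.basal_consistency_weight > 0:
                total = total + (cfg.basal_consistency_weight
                                 * _basal_consistency_tensor(model))
            l_ode_val = float(l_ode.data)
        if not np.isfinite(total.data):
            raise RuntimeError(f"training diverged at iteration {it}")

        for p in all_params:
            p.grad = None
        total.backward()
        opt_net.step()
        if not warmup:
            opt_head.step()
            lam_o, lam_a = self_adaptive_step(lam_o, lam_a, l_ode_val,
                                              float(l_aux.data),
                                              cfg.rho_o, cfg.rho_a)
        if it % cfg.record_every == 0 or it == cfg.iterations - 1:
            model.history.append(LossBreakdown(float(l_data.data), l_ode_val,
                                               float(l_aux.data),
                                               lam_o, lam_a, it))

    if cfg.lbfgs_iterations > 0:
        _lbfgs_finish(model, cfg, t_data, g_data, s0, tau, u1c, u2c, ec,
                      lam_o, lam_a)
    return model


def _lbfgs_finish(model, cfg, t_data, g_data, s0, tau, u1c, u2c, ec,
                  lam_o, lam_a):
    """Full-batch deterministic finishing phase.

    Adam leaves the composite loss on a wide plateau where weakly observed
    parameter combinations are unresolved; a quasi-Newton polish with the
    self-adaptive weights frozen drives data misfit and residuals low enough
    to separate them.
    """
    from scipy.optimize import minimize

    net_params, head_params = model.trainable_parameters()
    variables = net_params + head_params
    shapes = [v.data.shape for v in variables]
    sizes = [v.data.size for v in variables]
    offsets = np.cumsum([0] + sizes)

    def unpack(x):
        for v, a, b, shape in zip(variables, offsets[:-1], offsets[1:], shapes):
            v.data = x[a:b].reshape(shape)

    def fun(x):
        unpack(x)
        for v in variables:
            v.grad = None
        total = (_data_loss_tensor(model, t_data, g_data)
                 + lam_o * _ode_loss_tensor(model, tau, u1c, u2c, ec)
                 + lam_a * _aux_loss_tensor(model, s0))
        if cfg.basal_consistency_weight > 0:
            total = total + (cfg.basal_consistency_weight
                             * _basal_consistency_tensor(model))
        total.backward()
        grad = np.concatenate([
            (v.grad if v.grad is not None else np.zeros_like(v.data)).ravel()
            for v in variables])
        return float(total.data), grad

    x0 = np.concatenate([v.data.ravel() for v in variables])
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": cfg.lbfgs_iterations,
                            "maxcor": 50, "ftol": 0.0, "gtol": 0.0})
    unpack(res.x)
    n_hist = model.history[-1].iteration if model.history else 0
    model.history.append(LossBreakdown(
        float(_data_loss_tensor(model, t_data, g_data).data),
        float(_ode_loss_tensor(model, tau, u1c, u2c, ec).data),
        float(_aux_loss_tensor(model, s0).data),
        lam_o, lam_a, n_hist + int(res.nit)))


def multi_seed_band(cfg: SBINNConfig, cgm: UniformSeries, forcing: ForcingSet,
                    seeds=(0, 1, 2, 3, 4), t_eval: np.ndarray | None = None,
                    **train_kwargs) -> pd.DataFrame:
    """Per-parameter mean and standard deviation across training seeds.

    Repeats :func:`train` with each seed and summarizes the emitted parameter
    trajectories — the uncertainty band reported alongside inferred kinetics.
    Returns a tidy frame with columns (t, parameter, mean, sd).
    """
    if t_eval is None:
        t_eval = np.array([cgm.times[0]])
    runs = []
    for seed in seeds:
        model = train(replace(cfg, seed=int(seed)), cgm, forcing,
                      **train_kwargs)
        runs.append(model.params_at(t_eval).set_index("t"))
    rows = []
    for name in PARAM_NAMES:
        stacked = np.column_stack([r[name].to_numpy() for r in runs])
        for k, t in enumerate(t_eval):
            rows.append({"t": t, "parameter": name,
                         "mean": stacked[k].mean(),
                         "sd": stacked[k].std(ddof=1) if len(runs) > 1 else 0.0})
    return pd.DataFrame(rows)


def reconstruct(model: InferredModel, forcing: ForcingSet,
                method: str = "rk4") -> pd.DataFrame:
    """Forward-solve the twin from the basal state with inferred parameters.

    This is the validation route: the resulting glucose trajectory is compared
    with the CGM observations (e.g. on the Clarke error grid).
    """
    return simulate(model.to_patient_params(), forcing, method=method)
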