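"""Offline reinforcement learning for insulin dosing on the digital twin.

MDP: the state is a window of the ``w`` most recent glucose readings on the
coarse (hourly) grid — no meal or exercise announcements; the action is the
insulin infusion rate u1 (mU/min) for the next step, capped at ``a_max``; the
per-step reward is

    r(G) = -((G - 120) / 120)^2   if 80 <= G <= 180 mg/dl,
    r(G) = -10                    otherwise,

and an episode's return is the discounted sum of rewards.

Two offline agents learn from a replay buffer collected by a behavior policy:

* **BCQ** (batch-constrained Q-learning, continuous variant): a variational
  autoencoder models the behavior action distribution (with a weighting factor
  ``w_kl`` on its KL term), a perturbation network adds a bounded correction,
  and twin Q-networks with soft-clipped double-Q targets score sampled
  candidate actions.
* **TD3+BC**: twin delayed deterministic policy gradient plus a behavior-
  cloning regularizer; the Q term is weighted by
  ``lambda = alpha / mean(|Q(s, pi(s))|)`` recomputed per batch.

Everything is numpy-deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from ._nn import Adam, Dense, MLP, Tensor, concat, minimum
from .twin import PatientParams, Scenario, ScenarioConfig, _deriv, basal_state, \
    make_scenario, CARB_MG_PER_G

__all__ = [
    "RewardConfig", "reward", "episode_return",
    "ReplayBuffer", "build_buffer", "merge_buffers", "rollout_to_table",
    "TwinEnv", "TherapyPolicy", "td3bc_lambda",
    "TD3BCConfig", "BCQConfig", "TD3BCAgent", "BCQAgent",
    "train_td3bc", "train_bcq", "evaluate_policy",
]

#: hard clinical cap on the insulin infusion rate (mU/min)
ACTION_CAP = 90.0


@dataclass(frozen=True)
class RewardConfig:
    """Glycemic set-point reward; maximum 0 is attained only at g_target."""

    g_target: float = 120.0
    g_min: float = 80.0
    g_max: float = 180.0
    penalty: float = -10.0
    gamma: float = 0.99

    def __post_init__(self):
        if not self.g_min < self.g_target < self.g_max:
            raise ValueError("require g_min < g_target < g_max")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")


def reward(g, cfg: RewardConfig = RewardConfig()):
    """Per-step reward for glucose ``g`` (scalar or array, mg/dl)."""
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("glucose must be finite")
    r = np.where((g >= cfg.g_min) & (g <= cfg.g_max),
                 -((g - cfg.g_target) / cfg.g_target) ** 2,
                 cfg.penalty)
    return float(r) if r.ndim == 0 else r


def episode_return(rewards, gamma: float) -> float:
    """Discounted return ``sum_i gamma^i r_i``; empty sequences return 0."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must be in (0, 1]")
    rewards = np.asarray(list(rewards), dtype=float)
    if rewards.size == 0:
        return 0.0
    return float(np.sum(rewards * gamma ** np.arange(rewards.size)))


# ---------------------------------------------------------------------------
# Replay buffer
# ---------------------------------------------------------------------------

@dataclass
class ReplayBuffer:
    """Sliding-window transitions plus normalization statistics.

    States are raw glucose windows (mg/dl); ``normalize``/``to_unit_action``
    map to the z-scored / [-1, 1] representations used by the agents.
    """

    states: np.ndarray        # (N, w)
    actions: np.ndarray       # (N,)
    rewards: np.ndarray       # (N,)
    next_states: np.ndarray   # (N, w)
    dones: np.ndarray         # (N,)
    w: int
    a_max: float
    gamma: float
    state_mean: float = 0.0
    state_std: float = 1.0

    def __post_init__(self):
        if self.states.shape[0] == 0:
            raise ValueError("empty replay buffer")
        if self.states.shape[1] != self.w:
            raise ValueError("window length mismatch")

    def __len__(self):
        return self.states.shape[0]

    # normalization ---------------------------------------------------------
    def normalize(self, s):
        return (np.asarray(s, dtype=float) - self.state_mean) / self.state_std

    def denormalize(self, s):
        return np.asarray(s, dtype=float) * self.state_std + self.state_mean

    def to_unit_action(self, a):
        return 2.0 * np.asarray(a, dtype=float) / self.a_max - 1.0

    def from_unit_action(self, u):
        return np.clip((np.asarray(u, dtype=float) + 1.0) / 2.0 * self.a_max,
                       0.0, self.a_max)

    def sample(self, rng: np.random.Generator, batch: int):
        idx = rng.integers(0, len(self), batch)
        return (self.normalize(self.states[idx]),
                self.to_unit_action(self.actions[idx])[:, None],
                self.rewards[idx][:, None],
                self.normalize(self.next_states[idx]),
                self.dones[idx][:, None].astype(float))

    # persistence -----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), states=self.states,
                 actions=self.actions, rewards=self.rewards,
                 next_states=self.next_states, dones=self.dones)
        meta = {"w": self.w, "a_max": self.a_max, "gamma": self.gamma,
                "state_mean": self.state_mean, "state_std": self.state_std}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ReplayBuffer":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(states=arrays["states"], actions=arrays["actions"],
                   rewards=arrays["rewards"], next_states=arrays["next_states"],
                   dones=arrays["dones"], **meta)


def build_buffer(table: pd.DataFrame, w: int = 5,
                 reward_cfg: RewardConfig = RewardConfig(),
                 a_max: float | None = None) -> ReplayBuffer:
    """Build transitions from an aligned (t, G, u1) table on the coarse grid.

    A table of L rows yields L - w transitions.  The action bound defaults to
    ``min(2 * max observed u1, 90 mU/min)`` — the documented infusion range is
    doubled to let the agent correct underdosing, under the clinical cap.
    """
    g = table["G"].to_numpy(dtype=float)
    u1 = table["u1"].to_numpy(dtype=float)
    if g.size < w + 1:
        raise ValueError(f"need at least {w + 1} rows, got {g.size}")
    if a_max is None:
        a_max = min(2.0 * float(u1.max()), ACTION_CAP)

    n = g.size - w
    idx = np.arange(w)[None, :] + np.arange(n)[:, None]
    states = g[idx]                       # windows ending at t = w-1 .. L-2
    next_states = g[idx + 1]
    actions = np.clip(u1[w - 1: -1], 0.0, a_max)
    rewards = reward(g[w:], reward_cfg)
    dones = np.zeros(n)
    dones[-1] = 1.0
    return ReplayBuffer(states=states, actions=actions, rewards=rewards,
                        next_states=next_states, dones=dones, w=w, a_max=a_max,
                        gamma=reward_cfg.gamma,
                        state_mean=float(g.mean()),
                        state_std=float(g.std() + 1e-8))


def merge_buffers(parts: list[ReplayBuffer]) -> ReplayBuffer:
    """Concatenate buffers (e.g. several recorded weeks) into one dataset.

    Episode boundaries are preserved through the per-part ``done`` flags;
    normalization statistics are recomputed over the union.
    """
    if not parts:
        raise ValueError("no buffers to merge")
    w, a_max, gamma = parts[0].w, parts[0].a_max, parts[0].gamma
    if any(b.w != w or b.a_max != a_max or b.gamma != gamma for b in parts):
        raise ValueError("buffers have incompatible metadata")
    states = np.concatenate([b.states for b in parts])
    return ReplayBuffer(
        states=states,
        actions=np.concatenate([b.actions for b in parts]),
        rewards=np.concatenate([b.rewards for b in parts]),
        next_states=np.concatenate([b.next_states for b in parts]),
        dones=np.concatenate([b.dones for b in parts]),
        w=w, a_max=a_max, gamma=gamma,
        state_mean=float(states.mean()), state_std=float(states.std() + 1e-8))


def rollout_to_table(traj: pd.DataFrame, step_minutes: float = 60.0
                     ) -> pd.DataFrame:
    """Closed-loop trajectory -> aligned (t, G, u1) table for `build_buffer`.

    Row i carries the glucose the policy observed when choosing action i
    (decision-time glucose), so windows and actions pair causally; the final
    post-step glucose is appended as a terminal row whose action is unused.
    """
    g = np.append(traj["G_obs"].to_numpy(float), traj["G"].to_numpy(float)[-1])
    u1 = np.append(traj["u1"].to_numpy(float), 0.0)
    return pd.DataFrame({"t": step_minutes * np.arange(g.size),
                         "G": g, "u1": u1})


# ---------------------------------------------------------------------------
# Closed-loop twin environment
# ---------------------------------------------------------------------------

class TwinEnv:
    """Hourly closed-loop rollout on the digital twin.

    Meals (u2) and exercise (u3) follow a per-episode synthetic scenario and
    are *fixed*; the agent chooses only the insulin rate u1, held constant over
    each coarse step.  The observation is the window of the last ``w`` hourly
    glucose values.
    """

    def __init__(self, params: PatientParams,
                 scenario_cfg: ScenarioConfig | None = None,
                 reward_cfg: RewardConfig = RewardConfig(),
                 w: int = 5, a_max: float = ACTION_CAP,
                 horizon_steps: int | None = None, step_minutes: float = 60.0):
        self.params = params
        self.scenario_cfg = scenario_cfg or ScenarioConfig()
        self.reward_cfg = reward_cfg
        self.w = w
        self.a_max = a_max
        self.step_minutes = step_minutes
        max_steps = int(self.scenario_cfg.duration_days * 1440 / step_minutes)
        self.horizon = min(horizon_steps or max_steps, max_steps)
        self._scenario: Scenario | None = None

    def reset(self, episode_seed: int) -> np.ndarray:
        self._scenario = make_scenario(episode_seed, self.scenario_cfg)
        f = self._scenario.forcing
        self._u2_mg = f.u2.values * CARB_MG_PER_G      # per-minute grids
        self._e = f.u3.values
        self._grid_dt = f.dt
        self._state = tuple(basal_state(self.params))
        self._t = 0.0
        self._step_idx = 0
        self._window = np.full(self.w, self.params.gb)
        return self._window.copy()

    def behavior_action(self, step_idx: int) -> float:
        """Hourly mean of the scenario's own logged infusion rate."""
        f = self._scenario.forcing
        per_step = int(round(self.step_minutes / f.dt))
        seg = f.u1.values[step_idx * per_step:(step_idx + 1) * per_step]
        return float(np.clip(seg.mean(), 0.0, self.a_max))

    def step(self, action: float) -> tuple[np.ndarray, float, bool, dict]:
        if self._scenario is None:
            raise RuntimeError("call reset() first")
        u1 = float(np.clip(action, 0.0, self.a_max))
        pv = self.params.values_at(self._t)
        ib, gb, w_kg = self.params.ib, self.params.gb, self.params.w
        per_step = int(round(self.step_minutes / self._grid_dt))
        k0 = self._step_idx * per_step
        s = self._state
        h = self._grid_dt
        for k in range(k0, k0 + per_step):
            u2, e = self._u2_mg[k], self._e[k]
            k1 = _deriv(s, pv, u1, u2, e, ib, gb, w_kg)
            s2 = tuple(si + 0.5 * h * ki for si, ki in zip(s, k1))
            k2 = _deriv(s2, pv, u1, u2, e, ib, gb, w_kg)
            s3 = tuple(si + 0.5 * h * ki for si, ki in zip(s, k2))
            k3 = _deriv(s3, pv, u1, u2, e, ib, gb, w_kg)
            s4 = tuple(si + h * ki for si, ki in zip(s, k3))
            k4 = _deriv(s4, pv, u1, u2, e, ib, gb, w_kg)
            s = tuple(si + h / 6.0 * (a + 2 * b + 2 * c + d)
                      for si, a, b, c, d in zip(s, k1, k2, k3, k4))
        if not all(np.isfinite(v) for v in s):
            raise RuntimeError(f"twin integration failed at step {self._step_idx}")
        self._state = s
        self._t += self.step_minutes
        self._step_idx += 1
        g_new = s[2]
        self._window = np.append(self._window[1:], g_new)
        r = reward(g_new, self.reward_cfg)
        done = self._step_idx >= self.horizon
        return self._window.copy(), r, done, {"G": g_new, "u1": u1}


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

class TherapyPolicy:
    """Self-administered insulin therapy as the behavior policy.

    Follows the scenario's scheduled therapy (basal + meal boluses, possibly
    systematically underdosed via the scenario's ``dose_factor``) with
    multiplicative execution noise, plus occasional correction boluses: when
    the patient checks the monitor (probability ``check_prob`` per hour) and
    the last reading exceeds ``correction_threshold``, a noisy correction of
    ``correction_gain * (G - 120)`` mU/min is added for the next hour.  The
    corrections give the logged data the state-conditioned action variation
    real self-management has.
    """

    def __init__(self, seed: int, correction_gain: float = 0.15,
                 correction_threshold: float = 180.0, check_prob: float = 0.5,
                 exec_noise: float = 0.3, g_target: float = 120.0):
        self.rng = np.random.default_rng(seed)
        self.correction_gain = correction_gain
        self.correction_threshold = correction_threshold
        self.check_prob = check_prob
        self.exec_noise = exec_noise
        self.g_target = g_target

    def __call__(self, window, step_idx: int, env: "TwinEnv") -> float:
        a = env.behavior_action(step_idx) \
            * (1.0 + self.exec_noise * self.rng.uniform(-1, 1))
        g = window[-1]
        if g > self.correction_threshold and self.rng.uniform() < self.check_prob:
            a += (g - self.g_target) * self.correction_gain \
                * self.rng.lognormal(0.0, 0.4)
        return float(np.clip(a, 0.0, env.a_max))


def td3bc_lambda(q_values, alpha: float, eps: float = 1e-8) -> float:
    """Behavior-cloning trade-off weight: alpha / mean |Q| over the batch."""
    denom = float(np.mean(np.abs(q_values)))
    return alpha / max(denom, eps)


@dataclass
class TD3BCConfig:
    hidden: tuple[int, ...] = (64, 64)
    lr: float = 3e-4
    batch: int = 128
    tau: float = 0.005
    policy_noise: float = 0.2        # in unit-action space
    noise_clip: float = 0.5
    policy_freq: int = 2
    alpha: float = 2.5               # higher favors RL, lower favors imitation
    episodes: int = 20               # training blocks, each followed by eval
    iters_per_episode: int = 100
    eval_episodes: int = 2


@dataclass
class BCQConfig:
    hidden: tuple[int, ...] = (64, 64)
    lr: float = 3e-4
    batch: int = 128
    tau: float = 0.005
    latent_dim: int = 2
    w_kl: float = 0.5                # weighting factor on the VAE KL term
    phi: float = 0.2                 # perturbation range (unit actions)
    n_candidates: int = 20           # VAE samples per state for the Q target
    n_candidates_act: int = 50       # VAE samples at action selection
    lmbda: float = 0.75              # soft clipped double-Q mixing
    episodes: int = 20
    iters_per_episode: int = 100
    eval_episodes: int = 4


class _AgentBase:
    """Common artifact fields + persistence."""

    algorithm: str

    def __init__(self, buffer_meta: dict, hyper: dict, seed: int):
        self.buffer_meta = buffer_meta
        self.hyper = hyper
        self.seed = seed
        self.best_episode: int = -1
        self.history: list[dict] = []

    # normalization from the training buffer
    def _norm_state(self, s):
        m = self.buffer_meta
        return (np.asarray(s, dtype=float) - m["state_mean"]) / m["state_std"]

    def _from_unit(self, u):
        a_max = self.buffer_meta["a_max"]
        return np.clip((u + 1.0) / 2.0 * a_max, 0.0, a_max)

    def _weight_dict(self) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self._weight_dict())
        meta = {"algorithm": self.algorithm, "hyper": self.hyper,
                "seed": self.seed, "best_episode": self.best_episode,
                "buffer_meta": self.buffer_meta}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


class TD3BCAgent(_AgentBase):
    algorithm = "td3bc"

    def __init__(self, w: int, cfg: TD3BCConfig, buffer_meta: dict, seed: int):
        super().__init__(buffer_meta, asdict(cfg), seed)
        rng = np.random.default_rng(seed)
        sizes = [w, *cfg.hidden, 1]
        self.actor = MLP(sizes, rng, "relu", out_activation="tanh")
        self.q1 = MLP([w + 1, *cfg.hidden, 1], rng, "relu")
        self.q2 = MLP([w + 1, *cfg.hidden, 1], rng, "relu")
        self.actor_t = MLP(sizes, rng, "relu", out_activation="tanh")
        self.q1_t = MLP([w + 1, *cfg.hidden, 1], rng, "relu")
        self.q2_t = MLP([w + 1, *cfg.hidden, 1], rng, "relu")
        for t, s in ((self.actor_t, self.actor), (self.q1_t, self.q1),
                     (self.q2_t, self.q2)):
            t.set_weights(s.get_weights())

    def act(self, window) -> float:
        s = self._norm_state(np.atleast_2d(window))
        u = self.actor(Tensor(s)).data[0, 0]
        return float(self._from_unit(u))

    def _weight_dict(self):
        out = {}
        for name in ("actor", "q1", "q2"):
            for i, w in enumerate(getattr(self, name).get_weights()):
                out[f"{name}_{i}"] = w
        return out


class BCQAgent(_AgentBase):
    algorithm = "bcq"

    def __init__(self, w: int, cfg: BCQConfig, buffer_meta: dict, seed: int):
        super().__init__(buffer_meta, asdict(cfg), seed)
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self._rng_act = np.random.default_rng(seed + 104729)
        z = cfg.latent_dim
        self.enc = MLP([w + 1, *cfg.hidden], rng, "relu", out_activation="relu")
        self.enc_mu = Dense(cfg.hidden[-1], z, rng)
        self.enc_logstd = Dense(cfg.hidden[-1], z, rng)
        self.dec = MLP([w + z, *cfg.hidden, 1], rng, "relu", out_activation="tanh")
        self.pert = MLP([w + 1, *cfg.hidden, 1], rng, "relu", out_activation="tanh")
        self.q1 = MLP([w + 1, *cfg.hidden, 1], rng, "relu")
        self.q2 = MLP([w + 1, *cfg.hidden, 1], rng, "relu")
        self.pert_t = MLP([w + 1, *cfg.hidden, 1], rng, "relu", out_activation="tanh")
        self.q1_t = MLP([w + 1, *cfg.hidden, 1], rng, "relu")
        self.q2_t = MLP([w + 1, *cfg.hidden, 1], rng, "relu")
        for t, s in ((self.pert_t, self.pert), (self.q1_t, self.q1),
                     (self.q2_t, self.q2)):
            t.set_weights(s.get_weights())

    def decode(self, s_norm: np.ndarray, z: np.ndarray | None,
               rng: np.random.Generator) -> np.ndarray:
        """Sample unit actions from the generative behavior model."""
        if z is None:
            z = rng.standard_normal((s_norm.shape[0], self.cfg.latent_dim))
            z = np.clip(z, -0.5, 0.5)
        x = concat([Tensor(s_norm), Tensor(z)], axis=1)
        return self.dec(x).data

    def _candidates(self, s_norm: np.ndarray, rng: np.random.Generator,
                    k: int | None = None) -> np.ndarray:
        if k is None:
            k = self.cfg.n_candidates
        rep = np.repeat(s_norm, k, axis=0)
        a = self.decode(rep, None, rng)
        xi = self.pert(concat([Tensor(rep), Tensor(a)], axis=1)).data
        return rep, np.clip(a + self.cfg.phi * xi, -1.0, 1.0)

    def act(self, window) -> float:
        s = self._norm_state(np.atleast_2d(window))
        rep, cand = self._candidates(s, self._rng_act,
                                     k=self.cfg.n_candidates_act)
        q = self.q1(concat([Tensor(rep), Tensor(cand)], axis=1)).data
        return float(self._from_unit(cand[int(np.argmax(q[:, 0])), 0]))

    def _weight_dict(self):
        out = {}
        nets = {"enc": self.enc, "dec": self.dec, "pert": self.pert,
                "q1": self.q1, "q2": self.q2}
        for name, net in nets.items():
            for i, w in enumerate(net.get_weights()):
                out[f"{name}_{i}"] = w
        for i, p in enumerate(self.enc_mu.parameters()):
            out[f"enc_mu_{i}"] = p.data.copy()
        for i, p in enumerate(self.enc_logstd.parameters()):
            out[f"enc_logstd_{i}"] = p.data.copy()
        return out


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _buffer_meta(buffer: ReplayBuffer) -> dict:
    return {"w": buffer.w, "a_max": buffer.a_max, "gamma": buffer.gamma,
            "state_mean": buffer.state_mean, "state_std": buffer.state_std}


def _maybe_eval(agent, env, episodes: int, seed: int) -> float:
    returns, _ = evaluate_policy(agent, env, episodes, seed)
    return float(np.mean(returns))


def train_td3bc(buffer: ReplayBuffer, cfg: TD3BCConfig | None = None,
                seed: int = 0, env: TwinEnv | None = None) -> TD3BCAgent:
    """Train a TD3+BC agent on an offline buffer.

    When an evaluation environment is given, the weights from the training
    block ("episode") with the highest mean evaluation return are kept.
    """
    cfg = cfg or TD3BCConfig()
    agent = TD3BCAgent(buffer.w, cfg, _buffer_meta(buffer), seed)
    rng = np.random.default_rng(seed + 1)
    gamma = buffer.gamma
    opt_actor = Adam(agent.actor.parameters(), lr=cfg.lr)
    opt_q = Adam(agent.q1.parameters() + agent.q2.parameters(), lr=cfg.lr)

    best_ret, best_weights = -np.inf, None
    it = 0
    for ep in range(cfg.episodes):
        for _ in range(cfg.iters_per_episode):
            s, a, r, s2, d = buffer.sample(rng, cfg.batch)
            # critic update
            noise = np.clip(rng.standard_normal(a.shape) * cfg.policy_noise,
                            -cfg.noise_clip, cfg.noise_clip)
            a2 = np.clip(agent.actor_t(Tensor(s2)).data + noise, -1.0, 1.0)
            x2 = np.concatenate([s2, a2], axis=1)
            q_t = np.minimum(agent.q1_t(Tensor(x2)).data,
                             agent.q2_t(Tensor(x2)).data)
            y = r + gamma * (1.0 - d) * q_t
            x = Tensor(np.concatenate([s, a], axis=1))
            opt_q.zero_grad()
            diff1 = agent.q1(x) - Tensor(y)
            diff2 = agent.q2(x) - Tensor(y)
            q_loss = (diff1 * diff1).mean() + (diff2 * diff2).mean()
            q_loss.backward()
            opt_q.step()

            pi_loss_val = np.nan
            if it % cfg.policy_freq == 0:
                # actor update: -lambda * Q1(s, pi(s)) + BC term
                st = Tensor(s)
                pi = agent.actor(st)
                q_pi = agent.q1(concat([st, pi], axis=1))
                lam = td3bc_lambda(q_pi.data, cfg.alpha)
                bc = ((pi - Tensor(a)) ** 2).mean()
                pi_loss = (-lam) * q_pi.mean() + bc
                opt_actor.zero_grad()
                # clear critic grads produced through q_pi before stepping actor
                pi_loss.backward()
                for p in agent.q1.parameters():
                    p.grad = None
                opt_actor.step()
                pi_loss_val = float(pi_loss.data)
                agent.actor_t.soft_update_from(agent.actor, cfg.tau)
                agent.q1_t.soft_update_from(agent.q1, cfg.tau)
                agent.q2_t.soft_update_from(agent.q2, cfg.tau)
            it += 1
            if not np.isfinite(q_loss.data):
                raise RuntimeError("non-finite critic loss")
        rec = {"episode": ep, "q_loss": float(q_loss.data),
               "pi_loss": pi_loss_val}
        if env is not None:
            rec["eval_return"] = _maybe_eval(agent, env, cfg.eval_episodes,
                                             seed + 7919)
            if rec["eval_return"] > best_ret:
                best_ret = rec["eval_return"]
                best_weights = agent.actor.get_weights()
                agent.best_episode = ep
        agent.history.append(rec)
    if best_weights is not None:
        agent.actor.set_weights(best_weights)
    else:
        agent.best_episode = cfg.episodes - 1
    return agent


def train_bcq(buffer: ReplayBuffer, cfg: BCQConfig | None = None,
              seed: int = 0, env: TwinEnv | None = None) -> BCQAgent:
    """Train a continuous BCQ agent on an offline buffer."""
    cfg = cfg or BCQConfig()
    agent = BCQAgent(buffer.w, cfg, _buffer_meta(buffer), seed)
    rng = np.random.default_rng(seed + 2)
    gamma = buffer.gamma
    vae_params = (agent.enc.parameters() + agent.enc_mu.parameters()
                  + agent.enc_logstd.parameters() + agent.dec.parameters())
    opt_vae = Adam(vae_params, lr=cfg.lr)
    opt_q = Adam(agent.q1.parameters() + agent.q2.parameters(), lr=cfg.lr)
    opt_pert = Adam(agent.pert.parameters(), lr=cfg.lr)

    best_ret, best_weights = -np.inf, None
    for ep in range(cfg.episodes):
        for _ in range(cfg.iters_per_episode):
            s, a, r, s2, d = buffer.sample(rng, cfg.batch)
            st, at = Tensor(s), Tensor(a)

            # --- VAE: reconstruction + w_kl * KL ---------------------------
            h = agent.enc(concat([st, at], axis=1))
            mu = agent.enc_mu(h)
            logstd = agent.enc_logstd(h).clip(-4.0, 15.0)
            std = logstd.exp()
            eps = rng.standard_normal(mu.shape)
            z = mu + std * Tensor(eps)
            recon = agent.dec(concat([st, z], axis=1))
            recon_loss = ((recon - at) ** 2).mean()
            kl = (-0.5) * (1.0 + 2.0 * logstd - mu ** 2 - (std ** 2)).sum(axis=1).mean()
            vae_loss = recon_loss + cfg.w_kl * kl
            opt_vae.zero_grad()
            vae_loss.backward()
            opt_vae.step()

            # --- critics: soft clipped double-Q over sampled candidates ----
            k = cfg.n_candidates
            s2_rep = np.repeat(s2, k, axis=0)
            a_cand = agent.decode(s2_rep, None, rng)
            xi = agent.pert_t(concat([Tensor(s2_rep), Tensor(a_cand)], axis=1)).data
            a_pert = np.clip(a_cand + cfg.phi * xi, -1.0, 1.0)
            x2 = np.concatenate([s2_rep, a_pert], axis=1)
            q1n = agent.q1_t(Tensor(x2)).data
            q2n = agent.q2_t(Tensor(x2)).data
            q_mix = cfg.lmbda * np.minimum(q1n, q2n) \
                + (1.0 - cfg.lmbda) * np.maximum(q1n, q2n)
            q_best = q_mix.reshape(-1, k).max(axis=1, keepdims=True)
            y = r + gamma * (1.0 - d) * q_best
            x = Tensor(np.concatenate([s, a], axis=1))
            opt_q.zero_grad()
            diff1 = agent.q1(x) - Tensor(y)
            diff2 = agent.q2(x) - Tensor(y)
            q_loss = (diff1 * diff1).mean() + (diff2 * diff2).mean()
            q_loss.backward()
            opt_q.step()

            # --- perturbation model: ascend Q1 -----------------------------
            a_dec = agent.decode(s, None, rng)
            st2 = Tensor(s)
            xi_t = agent.pert(concat([st2, Tensor(a_dec)], axis=1))
            a_p = (Tensor(a_dec) + cfg.phi * xi_t).clip(-1.0, 1.0)
            q_p = agent.q1(concat([st2, a_p], axis=1))
            pert_loss = (-1.0) * q_p.mean()
            opt_pert.zero_grad()
            pert_loss.backward()
            for p in agent.q1.parameters():
                p.grad = None
            opt_pert.step()

            agent.pert_t.soft_update_from(agent.pert, cfg.tau)
            agent.q1_t.soft_update_from(agent.q1, cfg.tau)
            agent.q2_t.soft_update_from(agent.q2, cfg.tau)
            if not np.isfinite(q_loss.data) or not np.isfinite(vae_loss.data):
                raise RuntimeError("non-finite loss in BCQ training")
        rec = {"episode": ep, "vae_loss": float(vae_loss.data),
               "q_loss": float(q_loss.data)}
        if env is not None:
            rec["eval_return"] = _maybe_eval(agent, env, cfg.eval_episodes,
                                             seed + 7919)
            if rec["eval_return"] > best_ret:
                best_ret = rec["eval_return"]
                best_weights = {n: getattr(agent, n).get_weights()
                                for n in ("dec", "pert", "q1")}
                agent.best_episode = ep
        agent.history.append(rec)
    if best_weights is not None:
        for n, wts in best_weights.items():
            getattr(agent, n).set_weights(wts)
    else:
        agent.best_episode = cfg.episodes - 1
    return agent


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_policy(policy, env: TwinEnv, episodes: int, seed: int
                    ) -> tuple[list[float], list[pd.DataFrame]]:
    """Closed-loop rollout of a policy on the twin.

    ``policy`` is an agent with ``.act(window)``, the string ``"behavior"``
    (replay the scenario's own logged infusion), or a callable
    ``(window, step_idx, env) -> action``.  Episodes differ in their scenario
    seed (meal/exercise schedule); u2 and u3 stay fixed within an episode.
    Failed twin integrations are excluded with a warning.
    """
    import warnings

    returns, trajectories = [], []
    for ep in range(episodes):
        window = env.reset(seed + ep)
        rows, rews = [], []
        try:
            done = False
            step = 0
            while not done:
                if policy == "behavior":
                    action = env.behavior_action(step)
                elif hasattr(policy, "act"):
                    action = policy.act(window)
                else:
                    action = policy(window, step, env)
                g_obs = window[-1]          # decision-time glucose
                window, r, done, info = env.step(action)
                rows.append({"step": step, "G": info["G"], "G_obs": g_obs,
                             "u1": info["u1"], "reward": r})
                rews.append(r)
                step += 1
        except RuntimeError as exc:
            warnings.warn(f"episode {ep} failed and was excluded: {exc}")
            continue
        returns.append(episode_return(rews, env.reward_cfg.gamma))
        trajectories.append(pd.DataFrame(rows))
    return returns, trajectories
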