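# glucotwin

Offline, patient-specific artificial-pancreas tooling for type 1 diabetes
research: a glucose–insulin **digital twin**, physics-informed **parameter
inference** from wearable data, and **offline reinforcement-learning** agents
that learn insulin dosing from logged behavior — trained and evaluated without
ever interacting with a real patient.

Who it is for: researchers prototyping closed-loop insulin-dosing algorithms
on CGM + pump + fitness-band data (or fully synthetic stand-ins), who need the
whole chain — raw event preprocessing, a personalizable simulator, inference,
offline RL, and clinical scoring — in one reproducible, pure-Python package.

## The model

The twin is a modified Roy–Parker system in six states — plasma insulin
*I* (μU/ml), remote insulin action *X* (1/min), glucose *G* (mg/dl), and the
exercise-driven hepatic production *G*<sub>prod</sub>, uptake *G*<sub>up</sub>
(mg/kg/min) and insulin removal *I*<sub>e</sub>:

```
dI/dt     = −n I + p4 u1 − Ie                 I(0) = Ib = (p4/n) u1b
dX/dt     = −p2 X + p3 (I − Ib)               X(0) = 0
dG/dt     = −p1 (G − Gb) − X G + (W/VolG)(Gprod − Gup) + u2/VolG
dGprod/dt = a1 E − a2 Gprod
dGup/dt   = a3 E − a4 Gup
dIe/dt    = a5 E − a6 Ie
```

driven by the insulin infusion rate `u1` (mU/min), the meal glucose
appearance `u2(t) = 0.0083 Σ m_j exp(−0.0083 (t − t_j))`, and the exercise
intensity `E = max(0.888·HR − 71.91 − 8, 0)` (above-basal %VO2max from heart
rate).  Patient-specific parameters live in `[0.2, 1.8]×` their reference
values and are inferred by a systems-biology-informed neural network (SBINN):
a state network fitted jointly to CGM observations and the ODE residuals
(derivatives by exact forward-mode differentiation), with self-adaptive loss
weights `min_θ max_λ  L_data + λo·L_ode + λa·L_aux`.

Dosing agents see only a window of the last 5 hourly glucose values (no meal
or exercise announcements), emit an insulin rate capped at 90 mU/min, and are
rewarded with `−((G−120)/120)²` inside 80–180 mg/dl and −10 outside.  Two
offline algorithms are implemented on the package's own numpy autodiff core:
**BCQ** (batch-constrained Q-learning with a conditional VAE over behavior
actions) and **TD3+BC** (twin delayed deterministic policy gradient with a
λ-normalized behavior-cloning term).  Results are scored with Clarke error
grids, time-in/above/below-range, and rank-sum tests on episode returns.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Simulate an underdosing synthetic patient, train both offline agents on a
month of its logged therapy, and compare closed-loop performance on the twin:

```python
import numpy as np
from glucotwin import twin, rl, evalmetrics

patient = twin.PatientParams.from_multipliers(twin.DEFAULT_PATIENT_MULTIPLIERS)
week = twin.ScenarioConfig(duration_days=7, dose_factor=0.5)   # 50% bolusing
env = rl.TwinEnv(patient, week, w=5, a_max=90.0)

# a month of self-managed therapy (scheduled doses + noisy corrections)
behavior = rl.TherapyPolicy(seed=77)
buffer = rl.merge_buffers([
    rl.build_buffer(rl.rollout_to_table(
        rl.evaluate_policy(behavior, env, 1, 500 + wk)[1][0]), a_max=90.0)
    for wk in range(4)])

eval_env = rl.TwinEnv(patient, twin.ScenarioConfig(duration_days=4,
                                                   dose_factor=0.5),
                      w=5, a_max=90.0, horizon_steps=96)
agent = rl.train_td3bc(buffer, rl.TD3BCConfig(episodes=10,
                                              iters_per_episode=500),
                       seed=0, env=eval_env)

for name, pol in [("behavior", rl.TherapyPolicy(999)), ("td3bc", agent)]:
    rets, trajs = rl.evaluate_policy(pol, eval_env, episodes=6, seed=100)
    g = np.concatenate([t["G"] for t in trajs])
    tir, tar, tbr = evalmetrics.range_fractions(g)
    print(f"{name:8s} return {np.mean(rets):8.1f}   TIR {tir:.3f}  TAR {tar:.3f}")
```

Output:

```
behavior   return   -137.0   TIR 0.773  TAR 0.227
td3bc      return    -89.7   TIR 0.854  TAR 0.146
```

The agent, reading nothing but recent glucose, raises time-in-range from 77%
to 85% and improves the discounted return, mostly by dosing more insulin when
the recent window runs high — the systematic underdosing in the logged data is
corrected without a single interaction with the "patient" during training.

A full pipeline run (synthetic patient → preprocessing → SBINN → buffer →
both agents → report) is one call or one command:

```bash
glucotwin run --seed 31 --out runs/demo
```

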