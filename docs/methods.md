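# Methods

`glucotwin` builds a patient-specific *offline* artificial-pancreas workflow in
three layers: a physiological glucose–insulin simulator (the digital twin), a
physics-informed inference engine that personalizes the twin from wearable
data, and offline reinforcement-learning agents that learn insulin dosing from
logged behavior and are evaluated in closed loop on the twin.

## Signal model

Raw records (CGM glucose, pump basal/temp-basal/bolus events, self-reported
meals, heart rate) are converted to three uniformly sampled forcings on a
half-open left-edge grid (canonical units: minutes, mg/dl, mU/min, grams,
bpm):

* **Insulin** `u1(t) = u1_basal + (1 − 1_temp)·u1_bolus + 1_temp·u1_temp`:
  the basal rate persists everywhere, and while a temp-basal override is
  active it *replaces* the bolus term (overlapping temp-basal windows are
  rejected rather than silently ordered).  A normal-mode bolus of `x` mU is
  released at `x/10` mU/min over 10 minutes; a square bolus at
  `x/(t_end − t_start)`; dual modes split the dose 50/50 and release the
  halves with the first- then second-named mode over the two half-intervals.
  As printed, the dual-mode normal component runs at `x/2/10` for the whole
  half-interval, which conserves the dose only when that half-interval is
  10 min; by default the normal component runs for `min(10, half)` minutes
  and is rescaled so each half integrates to exactly `x/2` (total delivered
  insulin must equal the logged dose), with `strict_eq2=True` reproducing the
  literal formula.  Dose-type events are rasterized by exact cell overlap, so
  conservation holds on any grid.
* **Meals** `u2(t) = 0.0083 Σ_j m_j exp(−0.0083 (t − t_j))` in g/min; the
  kernel integrates to the full carbohydrate mass.  The twin converts grams
  to mg through the named constant `CARB_MG_PER_G = 1000`.
* **Exercise** `PVO2max = 0.888·HR − 71.91`; the intensity above the resting
  level of 8 is `u3 = max(PVO2max − 8, 0)`.

Interior sensor gaps are linearly interpolated; gaps longer than 60 min are
filled but flagged (`mask=False`) so that observation-driven fitting excludes
them — inference should not fit invented glucose.  Channels are trimmed to
their common span (latest start, earliest end), optionally smoothed with a
centered 30-point rolling mean, and block-averaged to the 1-h control grid.

## The digital twin

Six states — plasma insulin `I`, remote insulin action `X`, glucose `G`, and
the exercise-driven states `Gprod`, `Gup`, `Ie` — follow the modified
Roy–Parker system given in `twin.py`; the glycogenolysis-decline term of the
prolonged-exercise literature is deliberately omitted (the targeted wear-data
regime contains only sporadic, light activity).  The basal state
`(Ib, 0, Gb, 0, 0, 0)` with `Ib = (p4/n)·u1b` is an exact fixed point and the
default initial condition.  The exercise forcing is the above-basal `u3`, so
rest is a true zero fixed point of the exercise states; a config offset
restores the literal absolute-PVO2max reading.

Reference parameter values (`REFERENCE_PARAMS`) follow the published
exercise-extended minimal model (e.g. `n = 0.142 /min`, `VolG = 117 dl`,
`p1 = 0.035 /min`); per-patient values live in the admissible box
`[0.2, 1.8]·xref`.  Body weight defaults to 60 kg and basal infusion to
16.7 mU/min (≈1 U/h).  The default synthetic study patient reduces the
insulin-independent clearance to 40 % of reference (`p1` multiplier 0.4),
which yields realistic T1DM meal excursions: adequate bolusing
(≈120 mU per gram of carbohydrate) holds glucose mostly in 80–180 mg/dl,
while 50 % dosing produces frequent readings above 180 mg/dl.

The solver is a fixed-step classical Runge–Kutta integrator with ~1-min
substeps inside each forcing cell; forcings and (possibly time-varying)
parameters are held constant within a cell because they are step functions by
construction.  The system is non-stiff at these parameters, and the same
stepper drives the closed-loop RL environment, where speed and bitwise
determinism matter.  scipy's adaptive stiff-capable LSODA is available as
`method="lsoda"` and serves as the cross-checking integrator in the tests
(agreement to <1e-3 mg/dl over a 12-h meal-plus-exercise day).

The scenario generator emulates free-living records: 2–4 meals/day with
lognormal carbohydrate mass (median 50 g, log-sd 0.35, clipped to
10–120 g), meal boluses with pump modes drawn at random (70 % normal, 10 %
each square/dual), a piecewise-constant basal with ±15 % jitter, at most one
exercise bout per day (30–60 min, heart-rate plateau 105–135 bpm), 5-min CGM
sampling with optional dropout gaps and sensor noise.  It does **not**
emulate CGM calibration drift, meal-absorption variability beyond the single
exponential kernel, circadian insulin-sensitivity rhythms, or reporting
errors in meal diaries — so passing tests demonstrate correctness of the
machinery on plausible data, not robustness to every artifact of real wear
data.

## Physics-informed inference

A state network maps time to the six states: input scaling `t → t/T`,
a Fourier feature layer (64 sine/cosine pairs by default; glucose dynamics at
the hour scale need periods down to ~2 h over a week), a tanh MLP, and an
output-scaling layer `y = offset + scale·raw` with the basal state as offset
— so the untrained network starts at the fixed point.  Time derivatives are
propagated *exactly* alongside the forward pass (for each tanh layer
`h = tanh(Wx + b)` the tangent obeys `v = (1 − h²)(Wv)`), and this tangent
path is part of the computation graph, so reverse-mode differentiation gives
exact parameter gradients of residual losses.

Parameters are emitted by a bounded head: a sigmoid squash onto
`[0.2, 1.8]·xref`, whose raw midpoint maps exactly to `xref` (the hard box
replaces penalty terms).  The head is a raw constant vector by default, or a
low-frequency function of time for the time-varying setting.

The composite loss `L' = L_data + λo·L_ode + λa·L_aux` uses:

* `L_data`: MSE between the network's glucose and CGM observations (glucose
  is the only observed state), in scaled units, gaps masked;
* `L_ode`: mean squared residual of the six equations at collocation points,
  each residual normalized by `scale/30 min` (a characteristic rate) so the
  equations contribute comparably;
* `L_aux`: the squared mismatch to the basal initial condition, plus a
  dimensionless basal-consistency residual `((p4·u1b)/(n·Ib) − 1)²` — the
  patient's basal insulin is a known input, and it ties the infusion gain to
  the clearance rate, removing the otherwise poorly constrained joint scaling
  of `n` and `p4`.

The non-negative self-adaptive weights ascend their own gradients
(`∂L'/∂λo = L_ode`), with equal rates `ρo = ρa` (default 0.1), starting from
1 — a min–max scheme that rebalances the terms automatically.  Training is
mini-batch Adam (256 observation + 256 collocation points/iteration) with a
warm-up phase that fits observations, the initial condition, and the hidden
states of the *reference-parameter* twin solved forward on the same forcings
(an initialization from the prior model; without it the exercise states start
at zero and their gains collapse to the box bound, where the squash
saturates and gradients vanish).  Learning rates step-decay (×0.2 at 50 %
and 80 % of the run), and an optional full-batch L-BFGS finishing phase with
the self-adaptive weights frozen (`lbfgs_iterations`) polishes the optimum —
it typically lowers data misfit and residuals by one to two orders of
magnitude.  Everything is seeded and single-threaded-deterministic.

Validation re-solves the ODE forward from the basal state with the inferred
parameters and scores the result against CGM on the Clarke error grid.

Desk-scale problem sizes: the recovery experiment uses a 7-day patient,
noiseless 5-min CGM (2016 observations), collocation every ~10 min, a
Fourier spectrum reaching 63-min periods, 16 000 Adam iterations and an
8 000-iteration L-BFGS polish.  Collocation density and iteration counts are
configurable; a practitioner with more compute should raise all of them.

## Offline reinforcement learning

State = window of the `w = 5` most recent hourly glucose values (no meal or
exercise announcements); action = insulin rate for the next hour, capped at
`a_max = min(2 × max logged rate, 90 mU/min)` — the logged range is doubled
so an agent can correct underdosing, under the clinical cap; reward
`−((G−120)/120)²` inside 80–180 mg/dl and −10 outside; discount 0.99.
States are z-scored per buffer and actions mapped to [−1, 1] internally.

The behavior policy (`TherapyPolicy`) reproduces self-managed therapy:
the scenario's scheduled basal + meal boluses (systematically halved for the
underdosing patient) with ±30 % execution noise, plus noisy correction
boluses when a monitor check (50 %/h) finds glucose above 180 mg/dl.  The
corrections matter methodologically: purely scheduled dosing makes large
actions coincide with meal spikes, so naively Q(s, a) *decreases* in a — the
classic confounding of observational dosing data; state-conditioned
corrections provide the causal variation that lets the critics learn the true
sign of the insulin effect.  Buffers pair each action with its decision-time
glucose window (`rollout_to_table`), not the glucose the action already
influenced.

Both agents are trained with small fully connected networks (two hidden
layers of 64) on the package's own autodiff core:

* **TD3+BC**: twin critics with clipped double-Q targets, delayed policy
  updates, target-policy smoothing; the policy objective weights the Q term
  by `λ = α / mean|Q(s, π(s))|` per batch (α = 2.5) against a behavior-
  cloning MSE.
* **BCQ** (continuous): a conditional VAE models the behavior action
  distribution (latent dim 2, KL weighted by `w_kl = 0.5`), a perturbation
  network adds up to `Φ = 0.2` (unit actions), and candidates (20/state) are
  scored by soft-clipped double-Q (λ = 0.75); action selection is argmax-Q
  over perturbed VAE samples.

Training proceeds in blocks ("episodes") of a few hundred gradient steps,
each followed by a closed-loop evaluation on the twin; the weights of the
best-evaluating block are kept.  Evaluation rolls the agent hourly against
fixed per-episode meal/exercise forcings (episodes differ in their scenario
seed); failed integrations are excluded with a warning.  Desk-scale budgets:
5000 gradient steps (TD3+BC) / 3000 (BCQ), 4-week buffers (~650
transitions), 4-day evaluation episodes.  Because agent and behavior are
evaluated on the same scenario seeds, return comparisons are paired.

## Scoring

Clarke error-grid regions follow the canonical published inequalities
(region A: within 20 % of reference, or both readings ≤70 mg/dl).
Time-in/above/below-range uses the reporting band [80, 180] mg/dl with
inclusive bounds — deliberately independent of the 70 mg/dl corner inside
the Clarke inequalities; the hypoglycemia threshold is 80 mg/dl throughout
(CGM overestimates at the low end).  Return distributions are compared with
the two-sided Wilcoxon rank-sum test by default (the signed-rank variant is
available for declared pairing), and degenerate all-equal comparisons return
p = 1 with a warning.

## Known limitations

* **Practical identifiability.**  With glucose as the only observed state,
  several parameter combinations are sloppy: the basal-consistency tie pins
  the ratio `p4/n` but their joint scale trades off against `p2`/`p3`
  (similar filtered insulin-action shapes), and glucose sees mainly the
  filtered *difference* of the exercise production/uptake states, so their
  individual gains and decay rates tend to merge into one effective
  compartment.  At desk-scale optimization the inferred parameters land on a
  compensated manifold whose forward glucose trajectory is clinically
  indistinguishable from the truth (Clarke A+B ≥ 99 % in the recovery
  experiment) while several individual parameters deviate beyond 20 % —
  reconstruction accuracy, not per-parameter error, is the property the
  validation reliably delivers.  Structural (local) identifiability holds for
  the full set when weight and basal insulin are known; resolving the sloppy
  directions in practice requires data misfits far below 0.1 mg/dl, i.e.
  near machine-precision optimization.
* Recovery is assessed in the constant-parameter setting; the time-varying
  head is exercised structurally but its recovery quality is not asserted
  (a week of glucose-only data cannot pin twelve trajectories).
* `Ie` enters the insulin equation directly as a removal rate; its units are
  treated as μU/ml/min.
* The VAE/critic hyperparameters follow the original continuous-control
  settings with a wider perturbation range; no per-patient grid search is
  performed at desk scale.
* The XML reader targets the 2018-cohort field set (heart rate required) and
  attaches no calendar semantics to the privacy-shifted timestamps.
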