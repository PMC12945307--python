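import numpy as np
import pytest

from glucotwin import rl, signals, twin


@pytest.fixture
def grid_1min():
    """One-day 1-minute grid template."""
    return signals.UniformSeries(0.0, 1.0, np.zeros(1440))


@pytest.fixture
def default_params():
    return twin.PatientParams.from_multipliers(twin.DEFAULT_PATIENT_MULTIPLIERS)


@pytest.fixture
def basal_forcing(default_params, grid_1min):
    """Pure basal forcing: u1 = u1b, no meals, no exercise."""
    u1 = signals.UniformSeries(0.0, 1.0,
                               np.full(len(grid_1min), default_params.u1b),
                               unit="mU/min")
    return twin.ForcingSet(u1, grid_1min.zeros_like("g/min"),
                           grid_1min.zeros_like())


@pytest.fixture(scope="session")
def behavior_buffer():
    """Small offline buffer from the underdosing therapy policy (2 weeks)."""
    params = twin.PatientParams.from_multipliers(twin.DEFAULT_PATIENT_MULTIPLIERS)
    cfg = twin.ScenarioConfig(duration_days=7, dose_factor=0.5)
    env = rl.TwinEnv(params, cfg, w=5, a_max=90.0)
    policy = rl.TherapyPolicy(77)
    parts = []
    for week in range(2):
        _, trajs = rl.evaluate_policy(policy, env, 1, 500 + week)
        parts.append(rl.build_buffer(rl.rollout_to_table(trajs[0]), a_max=90.0))
    return rl.merge_buffers(parts)
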