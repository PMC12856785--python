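import numpy as np
import pytest

from aperiodic_wm.design import make_task_design
from aperiodic_wm.simulate import ParticipantParams, simulate_behavior, simulate_epochs


def make_params(**overrides) -> ParticipantParams:
    base = dict(
        participant="sub-000", group="younger", exponent_fixation=1.5,
        segment_deltas={"R2": -0.04, "R3": -0.05, "R4": -0.05}, offset=1.5,
        alpha_peak=(10.0, 0.5, 1.5), p3b_base=5.0,
        p3b_load_slope_encoding=0.25, p3b_load_slope_probe=-0.34,
        rt_intercept=0.5, rt_load_slope=0.05, rt_jitter_sd=0.4,
        rt_jitter_scale=0.1, accuracy={1: 0.96, 3: 0.958, 5: 0.928}, seed=7,
    )
    base.update(overrides)
    return ParticipantParams(**base)


@pytest.fixture
def params():
    return make_params()


@pytest.fixture
def small_task():
    """2 blocks x 15 trials = 30 trials, 10 per load."""
    return make_task_design(n_blocks=2, trials_per_block=15, seed=11)


@pytest.fixture
def small_epochs(params, small_task):
    design, trials = small_task
    trials = simulate_behavior(params, trials)
    epochs = simulate_epochs(params, design, trials, channels=8)
    return epochs, trials
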