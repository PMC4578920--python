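import numpy as np
import pytest

from desirmix.optimal_control import DynamicsSpec, EffectorState, GoalSpec


@pytest.fixture
def reach_dynamics():
    return DynamicsSpec()


@pytest.fixture
def noisy_dynamics():
    return DynamicsSpec(process_noise_sd=10.0)


@pytest.fixture
def origin_state():
    return EffectorState(position=np.zeros(2), velocity=np.zeros(2), t=0)


@pytest.fixture
def simple_goal():
    return GoalSpec(position=[10.0, 0.0], label="g")
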