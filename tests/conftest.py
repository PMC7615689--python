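import random

import hypothesis
import pytest

from streetnav.agents import AgentParams

hypothesis.settings.register_profile("streetnav", derandomize=True, deadline=None)
hypothesis.settings.load_profile("streetnav")


@pytest.fixture
def agent() -> AgentParams:
    """A mid-skill learner used across simulator tests."""
    return AgentParams(
        baseline_skill=0.5, learning_rate=0.03, asymptote_gain=0.5,
        motor_noise_sd=12.0, noise_floor=2.0, competence=2, rng_seed=1)


@pytest.fixture
def rng():
    return random.Random(0)
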