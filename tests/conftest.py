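import numpy as np
import pytest

from lcfatigue.core import StimEvents
from lcfatigue.synthgen import FatigueParams, StimProtocol, generate_protocol


@pytest.fixture
def default_protocol() -> StimProtocol:
    return StimProtocol()


@pytest.fixture
def regular_events() -> StimEvents:
    """Jitter-free events: 12 pulses at 0,10,...,110 s in each of 4 episodes."""
    proto = StimProtocol(inter_pulse_jitter_s=0.0, n_episodes=4)
    return generate_protocol(proto, 4 * 600.0, seed=0)


@pytest.fixture
def default_fatigue() -> FatigueParams:
    return FatigueParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
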