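import numpy as np
import pytest
from hypothesis import settings

from pcmux.synthgen import SynthConfig, gen_session

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def session60():
    """One default synthetic session (60 s), shared across test modules."""
    return gen_session(SynthConfig(duration_s=60.0), seed=7)


@pytest.fixture(scope="session")
def simple60(session60):
    return session60.spikes.simple()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
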