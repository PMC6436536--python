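import numpy as np
import pytest

from ansacuity import GenerativeParams, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return GenerativeParams(seed=0)


@pytest.fixture
def session_025():
    """A deterministic 30-trial session from a W = 0.25 responder."""
    return simulate_session(0.25, "cards", "p1", rng_seed=7)
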