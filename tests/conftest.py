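import numpy as np
import pytest

from actionrace import DecisionUnitParams, RaceSimConfig


@pytest.fixture
def unit_params():
    """Canonical chosen-condition unit parameters."""
    return DecisionUnitParams(mu=1.7, sigma=0.3, theta=1.0, k=4)


@pytest.fixture
def default_cfg():
    return RaceSimConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
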