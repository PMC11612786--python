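import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sitsim

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    """Canonical low-fecundity pest (the defaults of the parameter table)."""
    return sitsim.SimParams()


@pytest.fixture
def high_fecundity_params():
    """High-fecundity pest with weak sterile males."""
    return sitsim.SimParams(F=45.0, Csterile=0.5, Csperm="first")


def empty_population(params, seed=0):
    """A population shell with no agents (for hand-built scenarios)."""
    pop = sitsim.init_population(params, seed)
    pop.alive[:] = False
    pop.compact()
    return pop
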