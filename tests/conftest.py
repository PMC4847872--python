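import pytest
from hypothesis import settings

from repliwave.core import (InitSpec, SimulationParams, empty_lattice,
                            init_lattice)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def params():
    """Reference parameter set on a small lattice."""
    return SimulationParams(L=32, seed=7)


@pytest.fixture
def small_state(params):
    return init_lattice(params, InitSpec(density_replicators=0.3,
                                         density_parasites=0.1,
                                         ka_init=1.0, beta_init=1.4), seed=7)


def make_empty(L=9, seed=0, **overrides):
    p = SimulationParams(L=L, seed=seed, **overrides)
    return p, empty_lattice(p, seed=seed)
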