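import numpy as np
import pytest

from dopacircuit import build_network
from dopacircuit.simulate import integrate


@pytest.fixture(scope="session")
def full_net():
    return build_network("Full", seed=7)


@pytest.fixture(scope="session")
def compiled_full(full_net):
    from dopacircuit._compiled import compile_network

    return compile_network(full_net)


@pytest.fixture(scope="session")
def short_trace(full_net, compiled_full):
    """A 200 ms full-circuit trace shared by energy/metrics tests."""
    return integrate(full_net, duration=200.0, compiled=compiled_full)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
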