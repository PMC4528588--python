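import numpy as np
import pytest

from phosphorelay import (
    ParameterSet,
    bistable_core_params,
    build_core_hybrid,
    build_regular_relay,
    build_shared_hpt,
)


@pytest.fixture(scope="session")
def core_network():
    return build_core_hybrid()


@pytest.fixture(scope="session")
def unit_params():
    """All rates 1, totals 1: the monostable reference point of the core."""
    return ParameterSet({f"k{i}": 1.0 for i in range(1, 7)}, {"HK": 1.0, "Hpt": 1.0})


@pytest.fixture(scope="session")
def core_witness():
    return bistable_core_params()


@pytest.fixture(scope="session")
def relay_network():
    return build_regular_relay()


@pytest.fixture(scope="session")
def shared2_network():
    return build_shared_hpt(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
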