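import numpy as np
import pytest

import nirstwin as nt


@pytest.fixture(scope="session")
def phantom_850():
    return nt.phantom_properties(850.0)


@pytest.fixture(scope="session")
def default_system():
    return nt.ExtinctionSystem.default(pathlength_mm=40.0)


@pytest.fixture()
def single_module_network():
    return nt.OptodeNetwork.from_positions([(0.0, 0.0)])


@pytest.fixture()
def two_module_network():
    return nt.OptodeNetwork.from_positions([(0.0, 0.0), (40.0, 0.0)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170818)
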