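import numpy as np
import pytest

from spiegelstruct import fixtures as fx
from spiegelstruct.spr import KineticModel


@pytest.fixture(scope="session")
def duplex8():
    return fx.make_duplex(8)


@pytest.fixture(scope="session")
def duplex8_l():
    return fx.make_duplex(8, chirality="L")


@pytest.fixture(scope="session")
def tetrad45():
    return fx.make_tetrad_stack(2, twist=45.0, ion="CA", ion_distance=2.48)


@pytest.fixture(scope="session")
def kinetic_model():
    return KineticModel(ka=1e6, kd=1e-3, rmax=100.0, kt=1e7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150422)
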