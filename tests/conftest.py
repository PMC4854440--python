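import numpy as np
import pytest

from dpdmem import ForceField, default_forcefield
from dpdmem.fixtures import fixture_generator


@pytest.fixture(scope="session")
def ff_default():
    return default_forcefield()


@pytest.fixture(scope="session")
def ff_water():
    return ForceField(labels=("W",), repulsion=np.array([[100.0]]),
                      friction=np.array([[4.5]]))


@pytest.fixture()
def bulk64():
    return fixture_generator("bulk64", seed=11)


@pytest.fixture()
def slab750():
    return fixture_generator("slab750", seed=12)


@pytest.fixture()
def bilayer32():
    return fixture_generator("bilayer32", seed=13)
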