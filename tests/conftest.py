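import numpy as np
import pytest

from spinbarrier import synthdata
from spinbarrier.steric import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def methyl():
    """(Molecule, SpinSystem, MotionModel) of the ideal tetrahedral rotor."""
    return synthdata.build_methyl()


@pytest.fixture(scope="session")
def ethane():
    return synthdata.build_ethane_like()


@pytest.fixture(scope="session")
def isopropyl_sym():
    return synthdata.build_isopropyl_toy(asymmetry=0.0)


@pytest.fixture(scope="session")
def isopropyl_asym():
    return synthdata.build_isopropyl_toy(
        asymmetry=synthdata.DEFAULT_ISOPROPYL_ASYMMETRY
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
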