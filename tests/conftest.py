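import numpy as np
import pytest

from mitonadph.redox_network import Geometry, KineticParameters
from mitonadph.sensor import SensorCalibration
from mitonadph.steady_state import MoietyTotals, initialize_oxidized_species


@pytest.fixture(scope="session")
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture(scope="session")
def totals():
    return MoietyTotals()


@pytest.fixture(scope="session")
def basal_state(params, geometry, totals):
    """The default basal operating point, computed once per session."""
    return initialize_oxidized_species(totals, params, geometry)


@pytest.fixture(scope="session")
def calibration():
    return SensorCalibration()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
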