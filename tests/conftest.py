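import pytest

from broilervent import FlockState, HouseConfig, SetpointSchedule, broiler_mass
from broilervent.config import EnvelopeSpec


@pytest.fixture
def cfg() -> HouseConfig:
    """Default house: 87x14 m floor, 14 fans of 37,000 m3/h, pad eff 0.65."""
    return HouseConfig()


@pytest.fixture
def setpoints() -> SetpointSchedule:
    return SetpointSchedule()


@pytest.fixture
def flock() -> FlockState:
    """Stocked experimental building: 28,120 birds at 28 days of age."""
    return FlockState(28, 28120, broiler_mass(28))


@pytest.fixture
def bare_envelope_cfg() -> HouseConfig:
    """House with a near-adiabatic envelope, for pure-ventilation ODE checks."""
    return HouseConfig(envelope=EnvelopeSpec(Uw=1e-9, Uf=1e-9))


def constant_setpoints(td: float) -> SetpointSchedule:
    """Age-independent setpoint schedule (helper for grid tests)."""
    return SetpointSchedule(points=((0.0, td),))
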