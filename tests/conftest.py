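import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stimcoil as sc
from stimcoil import axisym, config

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# the linear FEM intentionally exceeds real-core saturation; keep logs quiet
logging.getLogger("stimcoil.axisym").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def g20():
    return sc.awg_properties(20)


@pytest.fixture(scope="session")
def g12():
    return sc.awg_properties(12)


@pytest.fixture(scope="session")
def air_coil(g20):
    """The as-simulated air-core microscope coil."""
    return sc.CircularCoilSpec.from_mm(45.0, 85.0, 11.5, 264, g20)


@pytest.fixture(scope="session")
def merritt(g12):
    """The as-simulated three-coil square stack."""
    return sc.merritt_stack(150.0, 227.47, 50.0, 276, g12,
                            total_height_mm=123.17)


@pytest.fixture(scope="session")
def rod():
    return config.build_device(config.load_fixture("rod_core"))


@pytest.fixture(scope="session")
def pot():
    return config.build_device(config.load_fixture("pot_core"))


@pytest.fixture(scope="session")
def drive15():
    return sc.DriveCondition(15.0)


@pytest.fixture(scope="session")
def drive1():
    return sc.DriveCondition(1.0)


@pytest.fixture(scope="session")
def rod_solution(rod, drive15):
    """One shared rod-core solve at the default mesh (reused across tests)."""
    return axisym.simulate_rod_core(rod, drive15)


@pytest.fixture(scope="session")
def pot_solution(pot, drive15):
    return axisym.simulate_pot_core(pot, drive15)
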