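import numpy as np
import pytest

from pfoce.beam import DEFAULT_BEAM, AcquisitionPlan, force_profile_from_model
from pfoce.mechanics import MELAMINE_RESIN, MediumSpec


@pytest.fixture(scope="session")
def beam():
    return DEFAULT_BEAM


@pytest.fixture(scope="session")
def plan():
    return AcquisitionPlan()


@pytest.fixture(scope="session")
def bead():
    return MELAMINE_RESIN


@pytest.fixture(scope="session")
def water():
    return MediumSpec(refractive_index=1.33, density=1000.0)


@pytest.fixture(scope="session")
def gel_medium():
    return MediumSpec(refractive_index=1.34, density=1000.0)


@pytest.fixture(scope="session")
def model_force_map(beam, bead, gel_medium):
    """Axial force map spanning the synthetic imaging FOV (focus at z = 0)."""
    grid_x = np.linspace(-60e-6, 60e-6, 41)
    grid_z = np.linspace(-10e-6, 70e-6, 33)
    return force_profile_from_model(beam, bead, gel_medium, grid_x, grid_z)
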