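import numpy as np
import pytest

from vacuodyn import (
    ModelParameters,
    NoiseModel,
    OsmoticProtocol,
    VacuoleGeometry,
)


@pytest.fixture(scope="session")
def geometry():
    """Standard 40-um-diameter spherical vacuole."""
    return VacuoleGeometry.from_diameter_um(40.0)


@pytest.fixture(scope="session")
def protocol():
    """Standard hypo-osmotic perfusion protocol (450 -> 258.8 mOsmol/Kgw)."""
    return OsmoticProtocol()


@pytest.fixture(scope="session")
def noiseless():
    """Noise model with quantization and Gaussian noise both disabled."""
    return NoiseModel(pixel_scale=0.0, diameter_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def ws_ph70():
    """WS parameters at the pH 7.0 condition means."""
    return ModelParameters(model_id="WS", Pf=27e-3, Ps=2.1e-3)


@pytest.fixture(scope="session")
def truth_by_model(geometry):
    """Identifiable generating parameters for each of the five models."""
    V0 = geometry.V0
    return {
        "W": ModelParameters(model_id="W", Pf=2e-3),
        "WNOV": ModelParameters(model_id="WNOV", Pf=2e-3, Vb=0.3 * V0),
        "WME": ModelParameters(model_id="WME", Pf=9e-3, eps_star=5e7 / V0),
        "WS": ModelParameters(model_id="WS", Pf=27e-3, Ps=2.1e-3),
        "WSNOV": ModelParameters(model_id="WSNOV", Pf=9e-3, Ps=1e-3, Vb=0.25 * V0),
    }
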