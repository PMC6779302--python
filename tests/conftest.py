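import numpy as np
import pytest

from heartfsi import geometry, ibfe
from heartfsi.params import (
    ChordaeParams,
    GeometryConfig,
    HolzapfelOgdenParams,
    MVLeafletParams,
    NumericalParams,
    SimulationConfig,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def material_set() -> ibfe.MaterialSet:
    return ibfe.MaterialSet(
        anterior=MVLeafletParams(),
        posterior=MVLeafletParams(C1=10.2, av=50.0, bv=63.48),
        chordae=ChordaeParams(),
        myocardium=HolzapfelOgdenParams(),
        numerics=NumericalParams(),
    )


@pytest.fixture(scope="session")
def chamber():
    cfg = SimulationConfig()
    mesh, apparatus = geometry.build_lv_chamber(cfg.geometry, cfg.tethers)
    return mesh, apparatus


@pytest.fixture()
def channel_valve_mesh():
    return geometry.build_channel_valve(GeometryConfig())


def random_admissible_F(rng: np.random.Generator, spread: float = 0.25) -> np.ndarray:
    """A random 3x3 deformation gradient with det in [0.7, 1.5], away from the
    tension-compression switch kinks (|I4 - 1| > 1e-3 for the axis frames used
    in the tests)."""
    while True:
        F = np.eye(3) + spread * rng.standard_normal((3, 3))
        d = np.linalg.det(F)
        if not (0.7 <= d <= 1.5):
            continue
        C = F.T @ F
        if min(abs(C[0, 0] - 1.0), abs(C[1, 1] - 1.0), abs(C[2, 2] - 1.0)) < 1e-3:
            continue
        return F
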