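import numpy as np
import pytest

from mpekit import (
    AssemblageMember,
    FRParams,
    PredatorAssemblage,
    default_density_grid,
    simulate_deterministic,
)

BASE_A = 2.0
BASE_H = 0.005


@pytest.fixture(scope="session")
def base_params() -> FRParams:
    return FRParams(BASE_A, BASE_H)


@pytest.fixture(scope="session")
def density_grid() -> np.ndarray:
    return default_density_grid()


@pytest.fixture(scope="session")
def det_dataset(base_params, density_grid):
    """Noiseless single-predator trials at the default grid, 24 h."""
    return simulate_deterministic(base_params, grid=density_grid, t=1.0, assemblage_id="A")


@pytest.fixture(scope="session")
def conspecific_pair(base_params) -> PredatorAssemblage:
    return PredatorAssemblage(
        (AssemblageMember("A", 1, base_params), AssemblageMember("A", 1, base_params))
    )


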