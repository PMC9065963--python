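import numpy as np
import pytest

from citypatterns import ModelParams, ScalarField, SpatialGrid


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return ModelParams.defaults("base")


@pytest.fixture(scope="session")
def competition_params() -> ModelParams:
    return ModelParams.defaults("competition")


@pytest.fixture(scope="session")
def growth_params() -> ModelParams:
    return ModelParams.defaults("growth")


@pytest.fixture
def line_grid() -> SpatialGrid:
    """1-D 200 km periodic interval, 1 km spacing short of nothing fancy."""
    return SpatialGrid.line(200.0, 256)


@pytest.fixture
def square_grid() -> SpatialGrid:
    return SpatialGrid.square(150.0, 64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220176)


def random_admissible_fields(grid: SpatialGrid, rng: np.random.Generator):
    """Arbitrary admissible (p, s) pair: positive p, s in [0, 1]."""
    p = np.abs(8000.0 + 3000.0 * rng.standard_normal(grid.shape))
    s = np.clip(0.3 + 0.2 * rng.standard_normal(grid.shape), 0.0, 1.0)
    return (
        ScalarField(grid, p, role="population"),
        ScalarField(grid, s, role="service"),
    )
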