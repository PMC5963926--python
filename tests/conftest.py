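import numpy as np
import pytest

from scobserver import Grid, ObserverModel, ObserverParams, default_params


@pytest.fixture(scope="session")
def params() -> ObserverParams:
    """Canonical synthetic-observer parameters."""
    return default_params()


@pytest.fixture(scope="session")
def grid() -> Grid:
    return Grid()


@pytest.fixture(scope="session")
def coarse_grid() -> Grid:
    """Fit-resolution grid used where speed matters."""
    return Grid(60.0, 0.4)


@pytest.fixture(scope="session")
def model(params, grid) -> ObserverModel:
    """Session-cached model so estimate mappings are computed once."""
    return ObserverModel(params, grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
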