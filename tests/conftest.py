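import numpy as np
import pytest

from nirquant import SpectraSet, WavenumberGrid


@pytest.fixture
def small_grid() -> WavenumberGrid:
    # 9,000 -> 4,000 cm^-1 at 8 cm^-1: 626 points, both endpoints on-grid
    return WavenumberGrid.from_range(9000.0, 4000.0, 8.0)


@pytest.fixture
def coarse_grid() -> WavenumberGrid:
    return WavenumberGrid.from_range(9000.0, 4000.0, 40.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def random_set(coarse_grid, rng) -> SpectraSet:
    n = 8
    ids = tuple(f"s{i}" for i in range(n))
    base = np.exp(-((coarse_grid.values - 5200.0) / 400.0) ** 2)
    matrix = 0.5 * base + rng.normal(0.1, 0.05, size=(n, coarse_grid.n_points))
    return SpectraSet(ids, coarse_grid, matrix)
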