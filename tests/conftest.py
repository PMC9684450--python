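import numpy as np
import pytest

from popdisagg import (
    BuildingCountMap,
    CensusTable,
    GridSpec,
    PopulationMap,
    RegionMap,
    default_config,
    simulate_landscape,
)
from popdisagg.grids import CovariateStack


@pytest.fixture(scope="session")
def small_landscape():
    """32x32 landscape: quick to train on, still has real structure."""
    cfg = default_config(
        seed=1,
        grid=GridSpec(32, 32),
        n_fine_regions=12,
        n_coarse_regions=4,
        built_fraction_target=0.12,
    )
    return simulate_landscape(cfg)


@pytest.fixture(scope="session")
def default_landscape():
    """The standard 128x128 landscape (seed 0)."""
    return simulate_landscape(default_config(seed=0))


def random_instance(rng, n_rows=8, n_cols=8, n_regions=4, with_zero_region=False):
    """A random (buildings, regions, census, raw map) tuple for property tests."""
    grid = GridSpec(n_rows, n_cols)
    counts = rng.poisson(1.2, size=grid.shape)
    ids = rng.integers(1, n_regions + 1, size=grid.shape)
    if with_zero_region:
        ids[0, 0] = 0
    buildings = BuildingCountMap(grid, counts)
    regions = RegionMap(grid, ids)
    present = np.unique(ids[ids > 0])
    census = CensusTable(
        "fine", {int(r): float(rng.integers(0, 500)) for r in present}
    )
    raw = PopulationMap(grid, rng.gamma(1.0, 2.0, size=grid.shape))
    return buildings, regions, census, raw


def toy_stack(grid, n_channels, rng):
    vals = rng.standard_normal((grid.n_rows, grid.n_cols, n_channels))
    return CovariateStack(grid, [f"ch{k:02d}" for k in range(n_channels)], vals)
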