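import numpy as np
import pandas as pd
import pytest

from patchlink.landscape import CostSurface, CostTable, LandUseRaster, assign_costs


@pytest.fixture
def simple_costs() -> CostTable:
    """Habitat / favourable / unfavourable / barrier tiers."""
    return CostTable(
        costs={1: 1, 2: 10, 3: 100, 4: 1000},
        labels={1: "habitat", 2: "favourable", 3: "unfavourable", 4: "barrier"},
    )


def make_surface(grid, costs=None, resolution=2.0) -> CostSurface:
    """Cost surface from a small integer class grid."""
    raster = LandUseRaster(grid=np.asarray(grid, dtype=np.int64),
                          resolution=resolution)
    table = costs or CostTable(costs={1: 1, 2: 10, 3: 100, 4: 1000})
    return assign_costs(raster, table)


@pytest.fixture
def corridor_surface() -> CostSurface:
    """Two 2x2 habitat blocks joined by a single-file 10-cell corridor of
    cost 10, embedded in a barrier matrix (2-m cells)."""
    g = np.full((5, 16), 4, dtype=np.int64)
    g[1:3, 0:2] = 1          # left patch
    g[1, 2:12] = 2           # corridor, cost 10, 10 cells
    g[0:2, 12:14] = 1        # right patch
    g[2, 2:12] = 4
    return make_surface(g)
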