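import numpy as np
import pandas as pd
import pytest

from refugia.raster import Raster
from refugia.sdm import SuitabilityStack
from refugia.synthetic import ClimateConfig, LandscapeConfig, OccurrenceSet, generate_dem


@pytest.fixture
def landscape_cfg() -> LandscapeConfig:
    return LandscapeConfig(nrows=24, ncols=24, relief_smoothness=3.0, seed=7)


@pytest.fixture
def dem(landscape_cfg) -> Raster:
    return generate_dem(landscape_cfg)


@pytest.fixture
def climate_cfg() -> ClimateConfig:
    return ClimateConfig(n_bioclim=6, noise_sd=0.3, seed=3)


def make_raster(data, cell_size=300.0) -> Raster:
    data = np.asarray(data, dtype=float)
    return Raster(data, x_origin=0.0, y_origin=data.shape[-2] * cell_size,
                  cell_size=cell_size)


def make_stack(slices, cell_size=300.0, species="sp", scenario="ssp245"
               ) -> SuitabilityStack:
    """A suitability stack from four 2-D arrays (current + 3 future)."""
    return SuitabilityStack(species=species, scenario=scenario,
                            rasters=[make_raster(s, cell_size) for s in slices])


def make_occurrences(rc, grid: Raster, species="sp", elevation=None) -> OccurrenceSet:
    rc = np.atleast_2d(np.asarray(rc, dtype=int))
    xs = grid.x_origin + (rc[:, 1] + 0.5) * grid.cell_size
    ys = grid.y_origin - (rc[:, 0] + 0.5) * grid.cell_size
    if elevation is None:
        elevation = np.full(len(rc), np.nan)
    return OccurrenceSet(pd.DataFrame({
        "species": species, "x": xs, "y": ys,
        "row": rc[:, 0], "col": rc[:, 1], "elevation": elevation,
    }))
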