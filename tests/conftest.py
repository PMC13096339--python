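"""Shared fixtures: small synthetic worlds and target sets."""

import numpy as np
import pytest

from landalloc.grids_io import Layer, PlanningGrid
from landalloc.synthworld import SyntheticWorldConfig, generate_world
from landalloc.targets import build_targets


def make_world(seed=7, **overrides):
    defaults = dict(
        seed=seed,
        n_rows=24,
        n_cols=24,
        n_countries=2,
        n_regions=1,
        n_species=12,
        climate_overlap_frac=0.7,
    )
    defaults.update(overrides)
    return generate_world(SyntheticWorldConfig(**defaults))


@pytest.fixture(scope="session")
def small_world():
    return make_world()


@pytest.fixture(scope="session")
def small_targets(small_world):
    return build_targets(small_world)


@pytest.fixture
def tiny_grid():
    """3x3 single-country grid with one ocean cell (bottom-right)."""
    cid = np.ones((3, 3), dtype=np.int32)
    cid[2, 2] = 0
    return PlanningGrid(
        n_rows=3,
        n_cols=3,
        geotransform=(0.0, 5.0, 0.0, 0.0, 0.0, -5.0),
        cell_area_km2=25.0,
        country_id=cid,
        region_of_country={1: "R1"},
    )


def uniform_layer(grid, value, units=""):
    return Layer(np.full(grid.shape, float(value)), units=units)
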