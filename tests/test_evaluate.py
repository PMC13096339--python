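"""Evaluation metrics: achievement, efficiency, exposure, conflict, overlap."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_world
from landalloc.allocator import Allocation
from landalloc.evaluate import (
    CONFLICT_CLASSES,
    carbon_exposure,
    colocation_overlap,
    conflict_overlay,
    exposure_counts,
    land_efficiency,
    species_exposure,
    targets_met,
)
from landalloc.grids_io import Layer, PlanningGrid
from landalloc.scenarios import CATEGORY_CODES, ScenarioResult
from landalloc.targets import SpeciesFeature, TargetSet, build_targets


def _grid(n=4, countries=1):
    cid = np.ones((n, n), dtype=np.int32)
    if countries == 2:
        cid[:, n // 2 :] = 2
    return PlanningGrid(
        n_rows=n, n_cols=n,
        geotransform=(0.0, 5.0, 0.0, 0.0, 0.0, -5.0),
        cell_area_km2=25.0,
        country_id=cid,
        region_of_country={c: "R1" for c in range(1, countries + 1)},
    )


def _result(grid, category_map, held_rows=None, allocations=None, scenario="production_first"):
    held = pd.DataFrame(
        held_rows or [],
        columns=["country", "feature", "kind", "units", "target", "held"],
    )
    return ScenarioResult(
        scenario=scenario, constrain30=False, grid=grid,
        category_map=np.asarray(category_map, dtype=np.int16),
        held=held, allocations=allocations or {},
    )


class TestTargetsMet:
    def test_boundary_held_equals_target_is_met(self, tiny_grid):
        r = _result(
            tiny_grid, np.zeros(tiny_grid.shape),
            [(1, "ncp1", "ncp", "index", 100.0, 100.0)],
        )
        rows = targets_met(r, TargetSet())
        assert bool(rows["met"].iloc[0])

    def test_species_aggregated_across_countries(self, tiny_grid):
        r = _result(
            tiny_grid, np.zeros(tiny_grid.shape),
            [
                (1, "sp0", "species", "km2", 20.0, 25.0),
                (2, "sp0", "species", "km2", 30.0, 20.0),
            ],
        )
        rows = targets_met(r, TargetSet())
        assert len(rows) == 1
        assert not bool(rows["met"].iloc[0])  # 45 held < 50 target
        assert rows["fraction"].iloc[0] == pytest.approx(0.9)

    def test_zero_target_is_met(self, tiny_grid):
        r = _result(
            tiny_grid, np.zeros(tiny_grid.shape),
            [(1, "wind", "sector", "GW", 0.0, 0.0)],
        )
        rows = targets_met(r, TargetSet())
        assert bool(rows["met"].iloc[0])
        assert rows["fraction"].iloc[0] == 1.0


def _alloc_with_held(feature, held_value, country_cells):
    return Allocation(
        cell_ids=np.asarray(country_cells),
        zone_names=[feature],
        feature_names=[feature],
        assignment=np.zeros(len(country_cells), dtype=int),
        objective_value=0.0,
        achieved_gap=0.0,
        status="optimal",
        held=np.array([held_value]),
    )


class TestLandEfficiency:
    def test_simple_ratio(self):
        grid = _grid(4)
        cm = np.zeros(grid.shape)
        cm.ravel()[: 340 // 25 + 1] = CATEGORY_CODES["hydro"]  # not used: set below
        cm = np.zeros(grid.shape)
        # 8 hydro cells x 25 km2 = 200 km2 at 10 GW held -> 20 km2/GW
        cm.ravel()[:8] = CATEGORY_CODES["hydro"]
        r = _result(
            grid, cm,
            allocations={(1, "development"): _alloc_with_held("hydro", 10.0, range(8))},
        )
        eff = land_efficiency(r).set_index("sector")
        assert eff.loc["hydro", "km2_per_unit"] == pytest.approx(20.0)

    def test_zero_production_reported_as_absent(self):
        grid = _grid(4)
        r = _result(grid, np.zeros(grid.shape))
        eff = land_efficiency(r).set_index("sector")
        assert np.isnan(eff.loc["wind", "km2_per_unit"])
        assert eff.loc["wind", "note"] == "no achieved production"

    def test_pooled_is_area_weighted_combination(self):
        grid = _grid(4, countries=2)
        cm = np.zeros(grid.shape)
        cm[0, 0] = CATEGORY_CODES["wind"]  # country 1
        cm[0, 3] = CATEGORY_CODES["wind"]  # country 2
        r = _result(
            grid, cm,
            allocations={
                (1, "development"): _alloc_with_held("wind", 2.0, [0]),
                (2, "development"): _alloc_with_held("wind", 8.0, [3]),
            },
        )
        pooled = land_efficiency(r).set_index("sector").loc["wind"]
        per = land_efficiency(r, per_country=True)
        per = per[per["sector"] == "wind"].set_index("country")
        # total area / total production == weighted harmonic combination
        assert pooled["km2_per_unit"] == pytest.approx(
            (per["area_km2"].sum()) / (per["production"].sum())
        )


def _species(grid, cells, sid="sp0", cat="EN"):
    habitat = np.zeros(grid.shape)
    habitat.ravel()[cells] = grid.cell_area_km2
    layer = Layer(habitat, "km2")
    return SpeciesFeature(
        sid, cat, layer, layer.copy(), float(habitat.sum()), 0.5
    )


class TestSpeciesExposure:
    def test_boundary_ten_percent_is_exposed(self):
        grid = _grid(4)
        spf = _species(grid, list(range(10)))  # 10 cells = 250 km2 range
        dev = np.zeros(grid.shape, dtype=bool)
        dev.ravel()[0] = True  # exactly 10% of the range
        out = species_exposure(dev, [spf], grid)
        assert out["overlap_frac"].iloc[0] == pytest.approx(0.10)
        assert bool(out["exposed"].iloc[0])

    def test_above_threshold_exposed_and_empty_map_not(self):
        grid = _grid(4)
        spf = _species(grid, list(range(8)))
        dev = np.zeros(grid.shape, dtype=bool)
        dev.ravel()[:1] = True  # 12.5%
        assert bool(species_exposure(dev, [spf], grid)["exposed"].iloc[0])
        none = species_exposure(np.zeros(grid.shape, dtype=bool), [spf], grid)
        assert not none["exposed"].any()
        assert (none["overlap_frac"] == 0).all()

    def test_monotone_in_footprint(self):
        grid = _grid(6)
        rng = np.random.default_rng(0)
        species = [_species(grid, rng.choice(36, size=12, replace=False), f"sp{i}") for i in range(5)]
        small = np.zeros(grid.shape, dtype=bool)
        small.ravel()[:6] = True
        big = small.copy()
        big.ravel()[6:12] = True
        a = species_exposure(small, species, grid)
        b = species_exposure(big, species, grid)
        assert (b["overlap_frac"] >= a["overlap_frac"] - 1e-12).all()
        assert b["exposed"].sum() >= a["exposed"].sum()

    def test_counts_by_iucn_category(self):
        grid = _grid(4)
        species = [
            _species(grid, [0, 1], "sp0", "EN"),
            _species(grid, [4, 5], "sp1", "CR"),
        ]
        dev = np.zeros(grid.shape, dtype=bool)
        dev.ravel()[0] = True  # 50% of sp0, 0% of sp1
        counts = exposure_counts(species_exposure(dev, species, grid))
        assert counts["EN"]["n_exposed"] == 1
        assert counts["CR"]["n_exposed"] == 0
        assert counts["total_exposed"] == 1


class TestCarbonExposure:
    def test_uniform_carbon_sums_over_dev_cells(self):
        grid = _grid(8)
        carbon = Layer(np.ones(grid.shape), "Mt")
        dev = np.zeros(grid.shape, dtype=bool)
        dev.ravel()[:50] = True
        assert carbon_exposure(dev, carbon) == pytest.approx(50.0)
        assert carbon_exposure(np.zeros(grid.shape, dtype=bool), carbon) == 0.0

    def test_matches_dense_masked_sum_on_random_world(self):
        world = make_world(seed=13, n_rows=16, n_cols=16, n_species=0)
        rng = np.random.default_rng(1)
        dev = rng.random(world.grid.shape) < 0.3
        expected = float(
            world.carbon.layer.values[dev & (world.carbon.layer.values != -9999.0)].sum()
        )
        assert carbon_exposure(dev, world.carbon.layer) == pytest.approx(expected)


class TestConflictOverlay:
    def _scenarios(self, grid):
        z = np.zeros(grid.shape, dtype=np.int16)
        pf30 = z.copy()
        pf30[0, 0] = CATEGORY_CODES["wind"]  # dev over NF30 conservation
        pf30[0, 1] = CATEGORY_CODES["wind"]  # dev over NF-full conservation only
        pf30[0, 2] = CATEGORY_CODES["wind"]  # dev alone
        nf30 = z.copy()
        nf30[0, 0] = CATEGORY_CODES["new_conservation"]
        nf30[1, 0] = CATEGORY_CODES["new_conservation"]
        nffull = z.copy()
        nffull[0, 1] = CATEGORY_CODES["new_conservation"]
        nffull[1, 1] = CATEGORY_CODES["new_conservation"]
        mk = lambda cm, scen: _result(grid, cm, scenario=scen)
        return (
            mk(pf30, "production_first"),
            mk(nf30, "nature_first"),
            mk(z.copy(), "production_first"),
            mk(nffull, "nature_first"),
        )

    def test_classes_assigned_with_precedence(self):
        grid = _grid(4)
        pa = Layer(np.zeros(grid.shape))
        pf30, nf30, pffull, nffull = self._scenarios(grid)
        cm = conflict_overlay(pf30, nf30, pffull, nffull, pa)
        assert cm.class_map[0, 0] == CONFLICT_CLASSES["conflict_30_or_pa"]
        assert cm.class_map[0, 1] == CONFLICT_CLASSES["conflict_full"]
        assert cm.class_map[0, 2] == CONFLICT_CLASSES["development"]
        assert cm.class_map[1, 0] == CONFLICT_CLASSES["conservation_30"]
        assert cm.class_map[1, 1] == CONFLICT_CLASSES["conservation_full"]

    def test_development_over_pa_is_strong_conflict(self):
        grid = _grid(4)
        pa_vals = np.zeros(grid.shape)
        pa_vals[0, 2] = 1.0
        pf30, nf30, pffull, nffull = self._scenarios(grid)
        cm = conflict_overlay(pf30, nf30, pffull, nffull, Layer(pa_vals))
        assert cm.class_map[0, 2] == CONFLICT_CLASSES["conflict_30_or_pa"]

    def test_identical_runs_produce_no_conflict(self):
        grid = _grid(4)
        z = np.zeros(grid.shape, dtype=np.int16)
        r = _result(grid, z)
        cm = conflict_overlay(r, r, r, r, Layer(np.zeros(grid.shape)))
        assert cm.areas_km2["conflict_30_or_pa"] == 0.0
        assert cm.areas_km2["conflict_full"] == 0.0

    def test_class_areas_partition_total_area(self):
        grid = _grid(4)
        pa_vals = np.zeros(grid.shape)
        pa_vals[3, 3] = 1.0
        pf30, nf30, pffull, nffull = self._scenarios(grid)
        cm = conflict_overlay(pf30, nf30, pffull, nffull, Layer(pa_vals))
        total = grid.n_rows * grid.n_cols * grid.cell_area_km2
        assert sum(cm.areas_km2.values()) == pytest.approx(total)


class TestColocation:
    def test_ratio_arithmetic_with_known_footprints(self):
        world = make_world(seed=14, n_rows=20, n_cols=20, n_species=0, land_fraction=1.0)
        t = build_targets(world)
        shape = world.grid.shape
        crops = np.zeros(shape, dtype=bool)
        pv = np.zeros(shape, dtype=bool)
        wind = np.zeros(shape, dtype=bool)
        crops.ravel()[:200] = True
        pv.ravel()[195:295] = True  # 5-cell overlap with crops
        out = colocation_overlap(
            world, t, footprints={"crops": crops, "pv_solar": pv, "wind": wind}
        )
        row = out[(out["a"] == "crops") & (out["b"] == "pv_solar")].iloc[0]
        assert row["pct_of_a"] == pytest.approx(2.5)  # 5 / 200
        assert row["pct_of_b"] == pytest.approx(5.0)  # 5 / 100
        disjoint = out[(out["a"] == "crops") & (out["b"] == "wind")].iloc[0]
        assert disjoint["overlap_km2"] == 0.0

    def test_solved_overlap_bounded_by_each_footprint(self):
        world = make_world(seed=15, n_rows=16, n_cols=16, n_species=4)
        t = build_targets(world)
        out = colocation_overlap(world, t)
        assert (out["pct_of_a"] >= 0).all() and (out["pct_of_a"] <= 100).all()
        assert (out["pct_of_b"] >= 0).all() and (out["pct_of_b"] <= 100).all()
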