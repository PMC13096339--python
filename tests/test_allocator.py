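"""Zoned MILP solver: cost composition, objectives, locks, oracle checks."""

import numpy as np
import pytest
from scipy import sparse as sp

from conftest import uniform_layer
from helpers import enumerate_optimum, random_instance
from landalloc.allocator import (
    AllocationProblem,
    Zone,
    apply_locks,
    compose_dev_cost,
    conservation_value_layer,
    problem_from_json,
    problem_to_json,
    solve_min_set,
    solve_min_shortfall,
)
from landalloc.grids_io import Layer
from landalloc.targets import SectorSpec


def _sector(grid, dpi_value):
    return SectorSpec(
        "wind", uniform_layer(grid, 1.0, "GW"), uniform_layer(grid, dpi_value)
    )


class TestComposeDevCost:
    def test_production_first_best_case_costs_one(self, tiny_grid):
        cost = compose_dev_cost(
            _sector(tiny_grid, 1.0), "production_first", uniform_layer(tiny_grid, 0.0)
        )
        assert cost.values[0, 0] == pytest.approx(1.0)

    def test_production_first_worst_case_costs_three(self, tiny_grid):
        cost = compose_dev_cost(
            _sector(tiny_grid, 0.0), "production_first", uniform_layer(tiny_grid, 1.0)
        )
        assert cost.values[0, 0] == pytest.approx(3.0)

    def test_nature_first_uses_conservation_value(self, tiny_grid):
        cost = compose_dev_cost(
            _sector(tiny_grid, 0.5),
            "nature_first",
            uniform_layer(tiny_grid, 1.0),
            conservation_value=uniform_layer(tiny_grid, 0.2),
        )
        assert cost.values[0, 0] == pytest.approx(1.7)

    def test_missing_conservation_value_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            compose_dev_cost(
                _sector(tiny_grid, 0.5), "nature_first", uniform_layer(tiny_grid, 0.0)
            )


class TestConservationValue:
    def test_single_cell_endemic_has_unit_rarity(self, tiny_grid):
        from landalloc.targets import SpeciesFeature

        habitat = np.zeros(tiny_grid.shape)
        habitat[1, 1] = 25.0
        spf = SpeciesFeature(
            "sp0", "CR", Layer(habitat, "km2"), Layer(habitat.copy(), "km2"),
            global_range_km2=25.0, pct_target=1.0,
        )
        out = conservation_value_layer([spf], uniform_layer(tiny_grid, 0.0), [])
        # carbon and NCP are zero everywhere: composite = rarity / 3
        assert out.values[1, 1] == pytest.approx(1.0 / 3.0)
        assert out.values[0, 0] == 0.0

    def test_all_zero_components_give_zero_layer(self, tiny_grid):
        out = conservation_value_layer([], uniform_layer(tiny_grid, 0.0), [])
        assert np.all(out.values == 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_bounded_by_one_on_random_worlds(self, seed):
        from conftest import make_world

        world = make_world(seed=seed, n_rows=16, n_cols=16, n_species=6)
        out = conservation_value_layer(
            world.species, world.carbon.layer, [a.layer for a in world.ncp_layers]
        )
        assert out.values.max() <= 1.0 + 1e-12
        assert out.values.min() >= 0.0


def _simple_problem(amounts, targets, costs=None, **kw):
    amounts = np.atleast_2d(np.asarray(amounts, dtype=float)).T
    nc = amounts.shape[0]
    costs = np.ones(nc) if costs is None else np.asarray(costs, dtype=float)
    zone = Zone("z", costs, sp.csr_matrix(amounts))
    return AllocationProblem(
        cell_ids=np.arange(nc),
        zones=[zone],
        feature_names=[f"f{j}" for j in range(amounts.shape[1])],
        targets=np.atleast_1d(targets),
        mip_gap=0.0,
        **kw,
    )


class TestMinSet:
    def test_three_cell_example_selects_both_contributors(self):
        alloc = solve_min_set(_simple_problem([1.0, 1.0, 0.0], [2.0]))
        assert alloc.objective_value == pytest.approx(2.0)
        assert set(np.flatnonzero(alloc.assignment == 0)) == {0, 1}

    def test_zero_targets_select_nothing(self):
        alloc = solve_min_set(_simple_problem([1.0, 1.0, 1.0], [0.0]))
        assert alloc.objective_value == pytest.approx(0.0)
        assert (alloc.assignment == -1).all()

    def test_unreachable_target_reports_infeasible(self):
        alloc = solve_min_set(_simple_problem([1.0, 1.0], [5.0]))
        assert alloc.status == "infeasible"


class TestMinShortfall:
    def test_zero_budget_totals_all_positive_targets(self):
        p = _simple_problem(
            np.array([[1.0, 2.0], [1.0, 0.0]]).T[:, 0],  # amounts column f0
            [2.0],
            objective="min_shortfall",
            budget=0.0,
            tie_break=0.0,
        )
        alloc = solve_min_shortfall(p)
        assert alloc.objective_value == pytest.approx(1.0)  # one positive target
        assert (alloc.assignment == -1).all()

    def test_infinite_budget_meets_feasible_targets(self):
        p = _simple_problem([1.0, 1.0, 1.0], [2.0], objective="min_shortfall")
        alloc = solve_min_shortfall(p)
        assert alloc.shortfalls is not None
        assert alloc.shortfalls.sum() == pytest.approx(0.0, abs=1e-9)

    def test_budget_two_cells_matches_brute_force(self):
        rng = np.random.default_rng(5)
        amounts = rng.random((4, 2))
        zone = Zone("z", np.ones(4), sp.csr_matrix(amounts))
        p = AllocationProblem(
            cell_ids=np.arange(4),
            zones=[zone],
            feature_names=["a", "b"],
            targets=amounts.sum(axis=0) * 0.9,
            objective="min_shortfall",
            budget=2.0,
            mip_gap=0.0,
        )
        alloc = solve_min_shortfall(p)
        assert alloc.objective_value == pytest.approx(enumerate_optimum(p), abs=1e-9)


class TestLocks:
    def test_conflicting_locks_rejected(self):
        p = _simple_problem([1.0, 1.0], [1.0])
        grid_mask = np.zeros(2, dtype=bool)
        grid_mask[0] = True
        locked = apply_locks(p, grid_mask, None, "z")
        with pytest.raises(ValueError):
            apply_locks(locked, None, grid_mask, "z")

    def test_locking_out_everything_makes_positive_targets_infeasible(self):
        p = _simple_problem([1.0, 1.0], [1.0])
        locked = apply_locks(p, None, np.ones(2, dtype=bool), "z")
        assert solve_min_set(locked).status == "infeasible"

    def test_locked_in_cells_always_selected(self):
        p = _simple_problem([1.0, 1.0, 1.0], [1.0])
        mask = np.zeros(3, dtype=bool)
        mask[2] = True
        alloc = solve_min_set(apply_locks(p, mask, None, "z"))
        assert alloc.assignment[2] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_locking_in_never_increases_unmet_targets(self, seed):
        """Forcing a cell into the only zone (the conservation lock-in case,
        under an unlimited budget) can only add held amounts, so the number
        of unmet targets never grows. With several zones a lock-in may
        reassign a cell away from another zone and lose amounts, so the
        guarantee is specific to single-zone problems."""
        from dataclasses import replace

        rng = np.random.default_rng(seed)
        p = random_instance(rng, "min_shortfall")
        if p.n_zones != 1:
            return
        p = replace(p, budget=None)  # effectively infinite
        base = solve_min_shortfall(p)
        mask = np.zeros(p.n_cells, dtype=bool)
        mask[rng.integers(p.n_cells)] = True
        try:
            locked = apply_locks(p, mask, None, p.zones[0].name)
        except ValueError:
            return  # the drawn cell was already locked elsewhere
        locked_alloc = solve_min_shortfall(locked)
        if base.status == "infeasible" or locked_alloc.status == "infeasible":
            return
        tol = 1e-9
        unmet_base = int((base.shortfalls > tol).sum())
        unmet_locked = int((locked_alloc.shortfalls > tol).sum())
        assert unmet_locked <= unmet_base


class TestOracleEquivalence:
    """Cross-check the MILP against exhaustive enumeration at gap 0."""

    @pytest.mark.parametrize("objective", ["min_set", "min_shortfall"])
    def test_objective_matches_enumeration(self, objective):
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(60):
            p = random_instance(rng, objective)
            expected = enumerate_optimum(p)
            alloc = (solve_min_set if objective == "min_set" else solve_min_shortfall)(p)
            if expected is None:
                assert alloc.status == "infeasible"
            else:
                assert alloc.status != "infeasible"
                assert alloc.objective_value == pytest.approx(
                    expected, rel=1e-6, abs=1e-6
                )
            n_checked += 1
        assert n_checked == 60

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_degradation_under_lockouts(self, seed):
        rng = np.random.default_rng(seed + 100)
        p = random_instance(rng, "min_shortfall")
        base = enumerate_optimum(p)
        mask = rng.random(p.n_cells) < 0.3
        locked = p
        for z in [z.name for z in p.zones]:
            try:
                locked = apply_locks(locked, None, mask, z)
            except ValueError:
                return
        worse = enumerate_optimum(locked)
        if base is None or worse is None:
            return
        assert worse >= base - 1e-9


class TestContracts:
    @pytest.mark.parametrize("seed", range(6))
    def test_gap_and_exclusivity_contracts(self, seed):
        rng = np.random.default_rng(seed + 50)
        p = random_instance(rng, "min_set")
        alloc = solve_min_set(p)
        if alloc.status == "infeasible":
            return
        assert alloc.achieved_gap <= p.mip_gap + 1e-12
        # at most one zone per cell by construction of the assignment vector
        assert alloc.assignment.max() < p.n_zones

    def test_json_round_trip_solves_identically(self):
        rng = np.random.default_rng(77)
        p = random_instance(rng, "min_set")
        q = problem_from_json(problem_to_json(p))
        a, b = solve_min_set(p), solve_min_set(q)
        assert a.status == b.status
        if a.status != "infeasible":
            assert a.objective_value == pytest.approx(b.objective_value, rel=1e-9)
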