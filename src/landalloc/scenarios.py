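"""Orchestration of the three planning scenarios, per country.

* **Production-First** — one six-sector development problem (minimum set on
  sector demand, protected areas carry an extra cost), then conservation on
  the remaining land (minimum shortfall, or the 30% target-scaling loop).
* **Nature-First** — conservation first (minimum set on full targets, or the
  30% loop), then development on the remaining land (minimum shortfall with
  an effectively infinite budget; protected areas and the conservation
  solution are unavailable; the development cost carries the
  conservation-value term).
* **Multi-Sector** — one joint problem over seven zones (conservation plus
  six sectors), minimum shortfall on all targets; under the 30% constraint
  the conservation zone is additionally capped by a hard per-country area
  constraint and driven by the same target-scaling loop.

Two loops make otherwise unattainable instances solvable: the 30% loop
lowers all conservation targets to 10% of their original values and raises
them by fixed increments until 30% of country land is conserved, and the
demand-decrement loop shrinks all development targets by fixed steps until
the development problem becomes feasible. Every reported achievement is
evaluated against the original targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse as sp

from .allocator import (
    Allocation,
    AllocationProblem,
    Zone,
    compose_dev_cost,
    conservation_value_layer,
    solve_min_set,
    solve_min_shortfall,
)
from .grids_io import PlanningGrid
from .targets import TargetSet

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "ScaleLoopResult",
    "DecrementResult",
    "CATEGORY_CODES",
    "run_scenario",
    "run_production_first",
    "run_nature_first",
    "run_multi_sector",
    "scale_targets_to_area",
    "decrement_demand_until_feasible",
]

CATEGORY_CODES = {
    "unallocated": 0,
    "existing_conservation": 1,
    "new_conservation": 2,
    "food_crops": 3,
    "energy_crops": 4,
    "pv_solar": 5,
    "csp": 6,
    "wind": 7,
    "hydro": 8,
}
SECTOR_CODES = {k: v for k, v in CATEGORY_CODES.items() if v >= 3}


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str = "multi_sector"
    constrain30: bool = False
    land_budget_pct: float = 0.30
    target_floor_pct: float = 0.10
    target_increment: float = 0.01
    demand_decrement: float = 0.05
    mip_gap: float = 0.01
    hm_threshold: float = 0.8
    # wall-clock cap per individual solve; incumbents are accepted past it
    solve_time_limit: float | None = 5.0

    def __post_init__(self):
        if self.scenario not in ("production_first", "nature_first", "multi_sector"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.target_floor_pct <= 1):
            raise ValueError("target_floor_pct must lie in (0, 1]")
        if self.target_increment <= 0 or self.demand_decrement <= 0:
            raise ValueError("increments must be positive")


@dataclass
class ScenarioResult:
    """Solved scenario: category map, held amounts, per-step allocations."""

    scenario: str
    constrain30: bool
    grid: PlanningGrid
    category_map: np.ndarray  # int16, grid shape
    held: pd.DataFrame  # country, feature, kind, units, target, held
    allocations: dict  # (country, step) -> Allocation
    traces: dict = field(default_factory=dict)

    def mask_for(self, *categories) -> np.ndarray:
        codes = [CATEGORY_CODES[c] for c in categories]
        return np.isin(self.category_map, codes)

    def dev_mask(self) -> np.ndarray:
        return np.isin(self.category_map, list(SECTOR_CODES.values()))

    def new_conservation_mask(self) -> np.ndarray:
        return self.category_map == CATEGORY_CODES["new_conservation"]

    def conservation_mask(self) -> np.ndarray:
        return self.mask_for("existing_conservation", "new_conservation")

    def category_areas_km2(self) -> dict:
        out = {}
        for name, code in CATEGORY_CODES.items():
            out[name] = float((self.category_map == code).sum()) * self.grid.cell_area_km2
        return out


@dataclass
class ScaleLoopResult:
    allocation: Allocation  # reported solution (under-shooting by default)
    crossing: Allocation | None  # first solution at/over the area budget
    factor: float
    scaled_targets: np.ndarray | None  # target vector actually solved for
    trace: list  # dicts: factor, area_cells, status


@dataclass
class DecrementResult:
    allocation: Allocation
    factor: float
    trace: list  # dicts: factor, status


# ---------------------------------------------------------------------------
# problem builders


def _layer_lookup(world) -> dict:
    lut = {spf.id: spf.retained for spf in world.species}
    lut.update({a.id: a.layer for a in world.assets})
    return lut


def _sample(layer, cells: np.ndarray) -> np.ndarray:
    v = layer.values.ravel()[cells]
    return np.where((v == layer.nodata) | ~np.isfinite(v), 0.0, v)


def _conservation_zone(world, cells: np.ndarray, cons_rows: pd.DataFrame):
    lut = _layer_lookup(world)
    cols = [_sample(lut[f], cells) for f in cons_rows["feature"]]
    amounts = sp.csr_matrix(np.column_stack(cols)) if cols else sp.csr_matrix(
        (len(cells), 0)
    )
    return Zone("conservation", np.ones(len(cells)), amounts)


def build_conservation_problem(
    world,
    country: int,
    targets: TargetSet,
    cfg: ScenarioConfig,
    excluded: np.ndarray | None = None,
    objective: str = "min_set",
    cap_targets: bool = True,
) -> AllocationProblem | None:
    """Single-zone conservation problem on a country's remaining land.

    Candidate cells are the country's available cells plus its protected
    areas (always locked in), minus any ``excluded`` footprint. Targets may
    be capped at the amount actually present among candidate cells, which
    keeps the minimum-set problem feasible when part of a feature's country
    amount lies on unavailable or excluded cells.
    """
    grid = world.grid
    avail = world.availability(cfg.hm_threshold).values.astype(bool)
    pa = world.pa_mask.values.astype(bool)
    cand = (avail | pa) & grid.country_mask(country)
    if excluded is not None:
        cand &= ~(excluded & ~pa)  # existing PAs stay locked in regardless
    cells = np.flatnonzero(cand.ravel())
    if len(cells) == 0:
        return None
    rows = targets.conservation(country)
    zone = _conservation_zone(world, cells, rows)
    t = rows["target"].to_numpy(dtype=float)
    if cap_targets and len(t):
        caps = np.asarray(zone.amounts.sum(axis=0)).ravel()
        t = np.minimum(t, caps)
    locked_in = pa.ravel()[cells][None, :].copy()
    return AllocationProblem(
        cell_ids=cells,
        zones=[zone],
        feature_names=list(rows["feature"]),
        targets=t,
        locked_in=locked_in,
        objective=objective,
        mip_gap=cfg.mip_gap,
        time_limit=cfg.solve_time_limit,
    )


def build_development_problem(
    world,
    country: int,
    targets: TargetSet,
    cfg: ScenarioConfig,
    mode: str,
    cons_value=None,
    excluded: np.ndarray | None = None,
    objective: str = "min_set",
    sectors: list | None = None,
) -> AllocationProblem | None:
    """Multi-zone development problem (one zone per sector) for a country.

    In production-first mode protected areas stay selectable at an extra
    unit cost; in nature-first / multi-sector mode they are unavailable.
    """
    grid = world.grid
    avail = world.availability(cfg.hm_threshold).values.astype(bool)
    pa = world.pa_mask.values.astype(bool)
    cand = avail & grid.country_mask(country)
    if mode in ("nature_first", "multi_sector"):
        cand &= ~pa
    if excluded is not None:
        cand &= ~excluded
    cells = np.flatnonzero(cand.ravel())
    if len(cells) == 0:
        return None
    use = sectors if sectors is not None else [s.name for s in world.sectors]
    specs = [s for s in world.sectors if s.name in use]
    dev_rows = targets.development(country).set_index("feature")
    names = [s.name for s in specs]
    t = np.array([float(dev_rows["target"].get(n, 0.0)) for n in names])
    zones = []
    for j, s in enumerate(specs):
        cost = compose_dev_cost(s, mode, world.pa_mask, cons_value)
        m = sp.lil_matrix((len(cells), len(names)))
        m[:, j] = _sample(s.yield_layer, cells).reshape(-1, 1)
        zones.append(Zone(s.name, _sample(cost, cells), m.tocsr()))
    return AllocationProblem(
        cell_ids=cells,
        zones=zones,
        feature_names=names,
        targets=t,
        objective=objective,
        mip_gap=cfg.mip_gap,
        time_limit=cfg.solve_time_limit,
    )


def build_joint_problem(
    world,
    country: int,
    targets: TargetSet,
    cfg: ScenarioConfig,
    cons_value,
    area_budget_cells: float | None = None,
    conservation_locked_to_pa: bool = False,
) -> AllocationProblem | None:
    """Seven-zone joint problem: conservation plus every sector.

    ``conservation_locked_to_pa`` restricts the conservation zone to the
    existing protected areas (used when a country already meets the 30%
    land budget with its current conservation estate).
    """
    grid = world.grid
    avail = world.availability(cfg.hm_threshold).values.astype(bool)
    pa = world.pa_mask.values.astype(bool)
    cand = (avail | pa) & grid.country_mask(country)
    cells = np.flatnonzero(cand.ravel())
    if len(cells) == 0:
        return None
    cons_rows = targets.conservation(country)
    dev_rows = targets.development(country).set_index("feature")
    sector_names = [s.name for s in world.sectors]
    features = list(cons_rows["feature"]) + sector_names
    nf = len(features)
    ncons = len(cons_rows)

    cz = _conservation_zone(world, cells, cons_rows)
    cons_amounts = sp.hstack(
        [cz.amounts, sp.csr_matrix((len(cells), len(sector_names)))], format="csr"
    )
    zones = [Zone("conservation", np.ones(len(cells)), cons_amounts)]
    pa_sel = pa.ravel()[cells]
    for j, s in enumerate(world.sectors):
        cost = compose_dev_cost(s, "multi_sector", world.pa_mask, cons_value)
        m = sp.lil_matrix((len(cells), nf))
        m[:, ncons + j] = _sample(s.yield_layer, cells).reshape(-1, 1)
        zones.append(Zone(s.name, _sample(cost, cells), m.tocsr()))

    t = np.concatenate(
        [
            cons_rows["target"].to_numpy(dtype=float),
            [float(dev_rows["target"].get(n, 0.0)) for n in sector_names],
        ]
    )
    locked_in = np.zeros((len(zones), len(cells)), dtype=bool)
    locked_in[0, pa_sel] = True
    locked_out = np.zeros_like(locked_in)
    locked_out[1:, pa_sel] = True
    if conservation_locked_to_pa:
        locked_out[0, ~pa_sel] = True
    extra = []
    if area_budget_cells is not None:
        coef = np.zeros((len(zones), len(cells)))
        coef[0, :] = 1.0
        extra.append((coef, -np.inf, float(area_budget_cells)))
    return AllocationProblem(
        cell_ids=cells,
        zones=zones,
        feature_names=features,
        targets=t,
        locked_in=locked_in,
        locked_out=locked_out,
        objective="min_shortfall",
        mip_gap=cfg.mip_gap,
        time_limit=cfg.solve_time_limit,
        extra_constraints=extra,
    )


# ---------------------------------------------------------------------------
# loops


def _pa_only_allocation(problem: AllocationProblem) -> Allocation:
    """Allocation holding only the locked-in (existing PA) cells."""
    zi = [z.name for z in problem.zones].index("conservation")
    assignment = np.full(problem.n_cells, -1, dtype=int)
    assignment[problem.locked_in[zi]] = zi
    x = np.zeros(problem.n_zones * problem.n_cells)
    x[zi * problem.n_cells : (zi + 1) * problem.n_cells][problem.locked_in[zi]] = 1.0
    amounts = sp.vstack([z.amounts for z in problem.zones]).tocsc()
    held = np.asarray(amounts.T @ x).ravel()
    return Allocation(
        cell_ids=problem.cell_ids,
        zone_names=[z.name for z in problem.zones],
        feature_names=list(problem.feature_names),
        assignment=assignment,
        objective_value=float(problem.locked_in[zi].sum()),
        achieved_gap=0.0,
        status="optimal",
        held=held,
    )


def scale_targets_to_area(
    problem: AllocationProblem,
    country_n_cells: int,
    cfg: ScenarioConfig,
    scale_mask: np.ndarray | None = None,
) -> ScaleLoopResult:
    """Raise a common conservation-target factor until 30% of land is used.

    All conservation targets (the features flagged by ``scale_mask``; by
    default every feature in the problem) are multiplied by one factor,
    starting at ``target_floor_pct`` and increased by ``target_increment``
    per step (solving each time) until the selected conservation area —
    including locked-in protected areas — first reaches ``land_budget_pct``
    of the country's land, or the factor reaches 1. Returns the last
    solution not exceeding the area budget (the default report) together
    with the first-crossing solution and the full trace. Countries already
    at or above the budget keep their existing protected areas only.
    """
    solver = solve_min_set if problem.objective == "min_set" else solve_min_shortfall
    zi = [z.name for z in problem.zones].index("conservation")
    budget_cells = cfg.land_budget_pct * country_n_cells
    pa_cells = int(problem.locked_in[zi].sum())
    trace = []
    if pa_cells >= budget_cells:
        alloc = _pa_only_allocation(problem)
        trace.append({"factor": None, "area_cells": pa_cells, "status": "pa_only"})
        return ScaleLoopResult(alloc, None, 0.0, None, trace)

    base = problem.targets.copy()
    if scale_mask is None:
        scale_mask = np.ones(len(base), dtype=bool)
    caps = np.asarray(
        sp.vstack([z.amounts for z in problem.zones]).sum(axis=0)
    ).ravel()
    under = under_scaled = None
    under_factor = None
    crossing = crossing_scaled = None
    factor = cfg.target_floor_pct
    while True:
        factor = min(factor, 1.0)
        scaled = base.copy()
        scaled[scale_mask] = np.minimum(base[scale_mask] * factor, caps[scale_mask])
        trial = replace(problem, targets=scaled)
        alloc = solver(trial)
        area = (
            int((alloc.assignment == zi).sum())
            if alloc.status != "infeasible"
            else None
        )
        trace.append({"factor": factor, "area_cells": area, "status": alloc.status})
        if alloc.status == "infeasible":
            # capped single-zone problems cannot be infeasible; defensive stop
            break
        if area > budget_cells:
            crossing, crossing_scaled = alloc, scaled
            break
        under, under_scaled, under_factor = alloc, scaled, factor
        if area >= budget_cells:
            crossing, crossing_scaled = alloc, scaled
            break
        if factor >= 1.0:
            break
        factor += cfg.target_increment
    final = under if under is not None else crossing
    final_scaled = under_scaled if under is not None else crossing_scaled
    final_factor = under_factor if under is not None else min(factor, 1.0)
    return ScaleLoopResult(final, crossing, final_factor, final_scaled, trace)


def decrement_demand_until_feasible(
    problem: AllocationProblem, decrement: float = 0.05
) -> DecrementResult:
    """Shrink all development targets stepwise until the problem solves.

    Targets are multiplied by (1 - k * decrement) for k = 0, 1, 2, ... until
    the minimum-set problem is feasible; a factor reaching zero returns the
    empty development solution. Achievement must be evaluated against the
    original targets afterwards.
    """
    base = problem.targets.copy()
    trace = []
    k = 0
    while True:
        factor = max(1.0 - k * decrement, 0.0)
        trial = replace(problem, targets=base * factor)
        alloc = solve_min_set(trial)
        trace.append({"factor": factor, "status": alloc.status})
        if alloc.status != "infeasible" or factor <= 0.0:
            return DecrementResult(alloc, factor, trace)
        k += 1


# ---------------------------------------------------------------------------
# scenario runners


def _held_frame(targets: TargetSet, country, allocs: list) -> pd.DataFrame:
    """Original targets for a country joined with held amounts."""
    rows = targets.subset(country).copy()
    held = np.zeros(len(rows))
    for i, (_, r) in enumerate(rows.iterrows()):
        for a in allocs:
            if a is not None and r["feature"] in a.feature_names:
                held[i] += a.held_for(r["feature"])
    rows["held"] = held
    return rows


def _paint(category_map: np.ndarray, grid, alloc: Allocation | None, pa: np.ndarray):
    if alloc is None:
        return
    flat = category_map.ravel()
    for z, name in enumerate(alloc.zone_names):
        cells = alloc.cell_ids[alloc.assignment == z]
        if name == "conservation":
            is_pa = pa.ravel()[cells]
            flat[cells[is_pa]] = CATEGORY_CODES["existing_conservation"]
            flat[cells[~is_pa]] = CATEGORY_CODES["new_conservation"]
        else:
            flat[cells] = SECTOR_CODES[name]


def run_production_first(world, targets: TargetSet, cfg: ScenarioConfig) -> ScenarioResult:
    """Development first (minimum set), conservation on the remaining land."""
    cfg = replace(cfg, scenario="production_first")
    grid = world.grid
    pa = world.pa_mask.values.astype(bool)
    category_map = np.zeros(grid.shape, dtype=np.int16)
    category_map[pa & grid.land_mask] = CATEGORY_CODES["existing_conservation"]
    allocations, traces, held_frames = {}, {}, []
    for country in grid.countries:
        trace = {}
        dev_problem = build_development_problem(
            world, country, targets, cfg, "production_first", objective="min_set"
        )
        dev_alloc = None
        if dev_problem is not None:
            dec = decrement_demand_until_feasible(dev_problem, cfg.demand_decrement)
            dev_alloc = dec.allocation
            trace["demand_decrement"] = dec.trace
            allocations[(country, "development")] = dev_alloc
        dev_footprint = np.zeros(grid.shape, dtype=bool)
        if dev_alloc is not None:
            dev_footprint.ravel()[dev_alloc.cell_ids[dev_alloc.assignment >= 0]] = True

        cons_alloc = None
        if cfg.constrain30:
            cons_problem = build_conservation_problem(
                world, country, targets, cfg, excluded=dev_footprint,
                objective="min_set",
            )
            if cons_problem is not None:
                loop = scale_targets_to_area(
                    cons_problem, len(grid.country_cells(country)), cfg
                )
                cons_alloc = loop.allocation
                trace["target_scaling"] = loop.trace
        else:
            cons_problem = build_conservation_problem(
                world, country, targets, cfg, excluded=dev_footprint,
                objective="min_shortfall", cap_targets=False,
            )
            if cons_problem is not None:
                cons_alloc = solve_min_shortfall(cons_problem)
        if cons_alloc is not None:
            allocations[(country, "conservation")] = cons_alloc

        _paint(category_map, grid, cons_alloc, pa)
        _paint(category_map, grid, dev_alloc, pa)
        held_frames.append(_held_frame(targets, country, [dev_alloc, cons_alloc]))
        traces[country] = trace
    held = pd.concat(held_frames, ignore_index=True) if held_frames else pd.DataFrame()
    return ScenarioResult(
        "production_first", cfg.constrain30, grid, category_map, held, allocations, traces
    )


def run_nature_first(world, targets: TargetSet, cfg: ScenarioConfig) -> ScenarioResult:
    """Conservation first, development on the remaining land."""
    cfg = replace(cfg, scenario="nature_first")
    grid = world.grid
    pa = world.pa_mask.values.astype(bool)
    cons_value = conservation_value_layer(
        world.species, world.carbon.layer, [a.layer for a in world.ncp_layers]
    )
    category_map = np.zeros(grid.shape, dtype=np.int16)
    category_map[pa & grid.land_mask] = CATEGORY_CODES["existing_conservation"]
    allocations, traces, held_frames = {}, {}, []
    for country in grid.countries:
        trace = {}
        cons_problem = build_conservation_problem(
            world, country, targets, cfg, objective="min_set"
        )
        cons_alloc = None
        if cons_problem is not None:
            if cfg.constrain30:
                loop = scale_targets_to_area(
                    cons_problem, len(grid.country_cells(country)), cfg
                )
                cons_alloc = loop.allocation
                trace["target_scaling"] = loop.trace
            else:
                cons_alloc = solve_min_set(cons_problem)
                if cons_alloc.status == "infeasible":  # defensive; targets are capped
                    cons_alloc = solve_min_shortfall(
                        replace(cons_problem, objective="min_shortfall")
                    )
            allocations[(country, "conservation")] = cons_alloc
        cons_footprint = np.zeros(grid.shape, dtype=bool)
        if cons_alloc is not None:
            cons_footprint.ravel()[
                cons_alloc.cell_ids[cons_alloc.assignment >= 0]
            ] = True

        dev_problem = build_development_problem(
            world, country, targets, cfg, "nature_first",
            cons_value=cons_value, excluded=cons_footprint,
            objective="min_shortfall",
        )
        dev_alloc = None
        if dev_problem is not None:
            dev_alloc = solve_min_shortfall(dev_problem)
            allocations[(country, "development")] = dev_alloc

        _paint(category_map, grid, dev_alloc, pa)
        _paint(category_map, grid, cons_alloc, pa)
        held_frames.append(_held_frame(targets, country, [dev_alloc, cons_alloc]))
        traces[country] = trace
    held = pd.concat(held_frames, ignore_index=True) if held_frames else pd.DataFrame()
    return ScenarioResult(
        "nature_first", cfg.constrain30, grid, category_map, held, allocations, traces
    )


def run_multi_sector(world, targets: TargetSet, cfg: ScenarioConfig) -> ScenarioResult:
    """All zones allocated concurrently in one problem per country."""
    cfg = replace(cfg, scenario="multi_sector")
    grid = world.grid
    pa = world.pa_mask.values.astype(bool)
    cons_value = conservation_value_layer(
        world.species, world.carbon.layer, [a.layer for a in world.ncp_layers]
    )
    category_map = np.zeros(grid.shape, dtype=np.int16)
    category_map[pa & grid.land_mask] = CATEGORY_CODES["existing_conservation"]
    allocations, traces, held_frames = {}, {}, []
    for country in grid.countries:
        trace = {}
        n_country = len(grid.country_cells(country))
        budget_cells = cfg.land_budget_pct * n_country if cfg.constrain30 else None
        n_pa = int((pa & grid.country_mask(country)).sum())
        alloc = None
        if cfg.constrain30 and n_pa >= budget_cells:
            # current conservation estate already meets the land budget:
            # no new conservation, development still allocated
            problem = build_joint_problem(
                world, country, targets, cfg, cons_value,
                conservation_locked_to_pa=True,
            )
            if problem is not None:
                alloc = solve_min_shortfall(problem)
                trace["target_scaling"] = [
                    {"factor": None, "area_cells": n_pa, "status": "pa_only"}
                ]
        else:
            problem = build_joint_problem(
                world, country, targets, cfg, cons_value,
                area_budget_cells=budget_cells,
            )
            if problem is not None:
                if cfg.constrain30:
                    n_cons = len(targets.conservation(country))
                    mask = np.zeros(len(problem.feature_names), dtype=bool)
                    mask[:n_cons] = True
                    loop = scale_targets_to_area(problem, n_country, cfg, scale_mask=mask)
                    alloc = loop.allocation
                    trace["target_scaling"] = loop.trace
                else:
                    alloc = solve_min_shortfall(problem)
        if alloc is not None:
            allocations[(country, "joint")] = alloc
        _paint(category_map, grid, alloc, pa)
        held_frames.append(_held_frame(targets, country, [alloc]))
        traces[country] = trace
    held = pd.concat(held_frames, ignore_index=True) if held_frames else pd.DataFrame()
    return ScenarioResult(
        "multi_sector", cfg.constrain30, grid, category_map, held, allocations, traces
    )


def run_scenario(world, targets: TargetSet, cfg: ScenarioConfig) -> ScenarioResult:
    runner = {
        "production_first": run_production_first,
        "nature_first": run_nature_first,
        "multi_sector": run_multi_sector,
    }[cfg.scenario]
    return runner(world, targets, cfg)
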