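"""Zoned mixed-integer programs for land allocation.

A problem assigns each available planning unit (cell) to at most one zone —
conservation or one of the development sectors. Two objectives are
supported:

* **minimum set** — minimise total selection cost subject to every feature
  target being met (held[j] >= T_j);
* **minimum shortfall** — minimise the sum of proportional target
  shortfalls sum_j s_j / T_j subject to a budget on total cost, where
  held[j] + s_j >= T_j and s_j >= 0. With an effectively infinite budget
  this meets every individually attainable target.

Solving is delegated to the HiGHS branch-and-cut backend through
``scipy.optimize.milp``; the relative optimality gap is configurable
(default 1%). Infeasibility is reported as a status, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import json
import numpy as np
from scipy import sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .grids_io import Layer, PlanningGrid

__all__ = [
    "Zone",
    "AllocationProblem",
    "Allocation",
    "SolverError",
    "compose_dev_cost",
    "conservation_value_layer",
    "solve",
    "solve_min_set",
    "solve_min_shortfall",
    "apply_locks",
    "effectively_infinite_budget",
    "problem_to_json",
    "problem_from_json",
]


class SolverError(RuntimeError):
    """Backend failure distinct from model infeasibility."""


@dataclass
class Zone:
    """One assignable land use: its per-cell cost and what it counts toward."""

    name: str
    cost: np.ndarray  # (n_cells,)
    amounts: sp.csr_matrix  # (n_cells, n_features)

    def __post_init__(self):
        self.cost = np.asarray(self.cost, dtype=np.float64)
        if not sp.issparse(self.amounts):
            self.amounts = sp.csr_matrix(np.asarray(self.amounts, dtype=np.float64))
        if self.cost.ndim != 1 or self.amounts.shape[0] != self.cost.shape[0]:
            raise ValueError("zone cost/amounts shapes disagree")
        if not np.all(np.isfinite(self.cost)) or self.cost.min() < 0:
            raise ValueError("zone cost must be finite and non-negative")


@dataclass
class AllocationProblem:
    """A zoned MILP instance over a set of candidate cells."""

    cell_ids: np.ndarray  # flat grid indices of candidate cells
    zones: list  # list of Zone
    feature_names: list
    targets: np.ndarray  # (n_features,)
    locked_in: np.ndarray | None = None  # bool (n_zones, n_cells)
    locked_out: np.ndarray | None = None
    objective: str = "min_set"
    budget: float | None = None
    mip_gap: float = 0.01
    # wall-clock cap per solve; the incumbent is accepted (status
    # 'time_limit') when the gap is not certified within it
    time_limit: float | None = None
    # tiny cost weight added to the min-shortfall objective so ties among
    # equal-shortfall solutions break toward cheap, parsimonious selections
    tie_break: float = 1e-7
    extra_constraints: list = field(default_factory=list)  # (coef (nz,nc), lb, ub)

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        nz, nc = len(self.zones), len(self.cell_ids)
        if self.locked_in is None:
            self.locked_in = np.zeros((nz, nc), dtype=bool)
        if self.locked_out is None:
            self.locked_out = np.zeros((nz, nc), dtype=bool)
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    def validate(self) -> None:
        nz, nc = self.n_zones, self.n_cells
        if self.targets.shape != (len(self.feature_names),):
            raise ValueError("targets/feature_names length mismatch")
        if self.targets.min(initial=0.0) < 0:
            raise ValueError("targets must be non-negative")
        for z in self.zones:
            if z.cost.shape[0] != nc or z.amounts.shape != (nc, len(self.feature_names)):
                raise ValueError(f"zone {z.name!r} does not conform to the problem")
        if self.locked_in.shape != (nz, nc) or self.locked_out.shape != (nz, nc):
            raise ValueError("lock masks must be (n_zones, n_cells)")
        if (self.locked_in & self.locked_out).any():
            raise ValueError("a cell is locked in and out of the same zone")
        if (self.locked_in.sum(axis=0) > 1).any():
            raise ValueError("a cell is locked in to more than one zone")


@dataclass
class Allocation:
    """A solved assignment: cell -> zone index (-1 = unassigned)."""

    cell_ids: np.ndarray
    zone_names: list
    feature_names: list
    assignment: np.ndarray  # (n_cells,) int
    objective_value: float
    achieved_gap: float
    status: str  # optimal | gap_ok | time_limit | infeasible
    held: np.ndarray  # (n_features,)
    shortfalls: np.ndarray | None = None

    def zone_cells(self, zone: str) -> np.ndarray:
        """Flat grid indices of cells assigned to ``zone``."""
        z = self.zone_names.index(zone)
        return self.cell_ids[self.assignment == z]

    def zone_mask(self, grid: PlanningGrid, zone: str) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool).ravel()
        m[self.zone_cells(zone)] = True
        return m.reshape(grid.shape)

    def held_for(self, feature: str) -> float:
        return float(self.held[self.feature_names.index(feature)])


def compose_dev_cost(
    sector,
    scenario_mode: str,
    pa_mask: Layer,
    conservation_value: Layer | None = None,
) -> Layer:
    """Three-component development cost for one sector.

    cost = 1 (ubiquitous land cost) + (1 - DPI) (siting feasibility, the
    inverse of the development-potential index) + a scenario-dependent third
    term: the protected-area indicator (value 1 on current conservation
    areas) in production-first mode, or the normalised conservation-value
    layer in nature-first / multi-sector mode.
    """
    dpi = sector.dpi.values
    valid = (dpi != sector.dpi.nodata) & np.isfinite(dpi)
    if valid.any() and (dpi[valid].min() < 0 or dpi[valid].max() > 1):
        raise ValueError("DPI must lie in [0, 1]")
    if scenario_mode == "production_first":
        third = pa_mask.values
    elif scenario_mode in ("nature_first", "multi_sector"):
        if conservation_value is None:
            raise ValueError(f"{scenario_mode} requires a conservation-value layer")
        third = conservation_value.values
    else:
        raise ValueError(f"unknown scenario mode {scenario_mode!r}")
    cost = 1.0 + (1.0 - np.where(valid, dpi, 0.0)) + third
    return Layer(cost, units="cost")


def conservation_value_layer(species_features, carbon: Layer, ncp_layers) -> Layer:
    """Equal-weight composite of rarity, carbon and summed NCP, in [0, 1].

    Range-size rarity is the per-cell sum over species of retained amount
    divided by global range. Each of the three components is rescaled to
    [0, 1] by its world maximum (an all-zero component contributes zero) and
    the composite is their mean.
    """
    shape = carbon.values.shape
    rarity = np.zeros(shape)
    for spf in species_features:
        v = spf.retained.values
        v = np.where((v == spf.retained.nodata) | ~np.isfinite(v), 0.0, v)
        rarity += v / spf.global_range_km2
    carbon_v = np.where(
        (carbon.values == carbon.nodata) | ~np.isfinite(carbon.values), 0.0, carbon.values
    )
    ncp_sum = np.zeros(shape)
    for layer in ncp_layers:
        v = layer.values
        ncp_sum += np.where((v == layer.nodata) | ~np.isfinite(v), 0.0, v)

    def rescale(v: np.ndarray) -> np.ndarray:
        m = v.max()
        return v / m if m > 0 else np.zeros_like(v)

    composite = (rescale(rarity) + rescale(carbon_v) + rescale(ncp_sum)) / 3.0
    return Layer(composite, units="index")


def effectively_infinite_budget(problem: AllocationProblem) -> float:
    """A budget guaranteed slack: every cell at its dearest zone, plus one."""
    total = sum(float(z.cost.sum()) for z in problem.zones)
    return total + 1.0


def apply_locks(
    problem: AllocationProblem,
    locked_in_mask: np.ndarray | None,
    locked_out_mask: np.ndarray | None,
    zone: str,
) -> AllocationProblem:
    """Return a copy of ``problem`` with extra locks on one zone.

    Masks are full-grid boolean arrays; they are sampled at the problem's
    candidate cells. Locking a cell in to ``zone`` also locks it out of all
    other zones (one land use per cell).
    """
    zi = [z.name for z in problem.zones].index(zone)
    locked_in = problem.locked_in.copy()
    locked_out = problem.locked_out.copy()
    if locked_in_mask is not None:
        sel = np.asarray(locked_in_mask, dtype=bool).ravel()[problem.cell_ids]
        locked_in[zi, sel] = True
        for other in range(problem.n_zones):
            if other != zi:
                locked_out[other, sel] = True
    if locked_out_mask is not None:
        sel = np.asarray(locked_out_mask, dtype=bool).ravel()[problem.cell_ids]
        locked_out[zi, sel] = True
    new = replace(problem, locked_in=locked_in, locked_out=locked_out)
    return new


def _assemble(problem: AllocationProblem, with_shortfall: bool):
    nz, nc = problem.n_zones, problem.n_cells
    nf = len(problem.feature_names)
    nx = nz * nc
    tgt_idx = np.flatnonzero(problem.targets > 0)
    ns = len(tgt_idx) if with_shortfall else 0
    nvar = nx + ns

    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    li = problem.locked_in.ravel()
    lo = problem.locked_out.ravel()
    lb[:nx][li] = 1.0
    ub[:nx][lo] = 0.0
    # locking a cell in to one zone shuts the others via the cell constraint,
    # but tighten the bounds directly so presolve sees it
    cell_locked = problem.locked_in.any(axis=0)
    for z in range(nz):
        shut = cell_locked & ~problem.locked_in[z]
        ub[z * nc : (z + 1) * nc][shut] = 0.0
    if ns:
        ub[nx:] = np.inf

    cost = np.concatenate([z.cost for z in problem.zones])
    amounts = sp.vstack([z.amounts for z in problem.zones]).tocsc()  # (nx, nf)

    constraints = []
    # one zone per cell
    rows = np.tile(np.arange(nc), nz)
    cols = np.arange(nx)
    a_cell = sp.csr_matrix((np.ones(nx), (rows, cols)), shape=(nc, nvar))
    constraints.append(LinearConstraint(a_cell, -np.inf, 1.0))

    if len(tgt_idx):
        a_tgt = amounts[:, tgt_idx].T.tocsr()  # (nt, nx)
        if ns:
            a_tgt = sp.hstack([a_tgt, sp.identity(ns, format="csr")], format="csr")
        constraints.append(
            LinearConstraint(a_tgt, problem.targets[tgt_idx], np.inf)
        )

    if with_shortfall:
        if problem.budget is None:
            raise ValueError("min_shortfall requires a budget")
        a_budget = sp.csr_matrix(
            np.concatenate([cost, np.zeros(ns)])[None, :]
        )
        constraints.append(LinearConstraint(a_budget, -np.inf, problem.budget))
        c = np.concatenate([problem.tie_break * cost, 1.0 / problem.targets[tgt_idx]])
    else:
        c = np.concatenate([cost, np.zeros(ns)])

    for coef, clo, cup in problem.extra_constraints:
        coef = np.asarray(coef, dtype=np.float64).reshape(nz, nc)
        row = sp.csr_matrix(
            np.concatenate([coef.ravel(), np.zeros(ns)])[None, :]
        )
        constraints.append(LinearConstraint(row, clo, cup))

    integrality = np.concatenate([np.ones(nx), np.zeros(ns)])
    return c, constraints, (lb, ub), integrality, tgt_idx, amounts


def _finish(problem: AllocationProblem, res, tgt_idx, amounts, with_shortfall: bool):
    nz, nc = problem.n_zones, problem.n_cells
    nx = nz * nc
    nf = len(problem.feature_names)
    if res.status == 2:
        return Allocation(
            cell_ids=problem.cell_ids,
            zone_names=[z.name for z in problem.zones],
            feature_names=list(problem.feature_names),
            assignment=np.full(nc, -1, dtype=int),
            objective_value=np.inf,
            achieved_gap=np.inf,
            status="infeasible",
            held=np.zeros(nf),
        )
    limit_hit = res.status == 1 and res.x is not None
    if not res.success and not limit_hit:
        raise SolverError(f"solver failure: {res.message}")
    x = np.asarray(res.x[:nx]) > 0.5
    xz = x.reshape(nz, nc)
    assignment = np.full(nc, -1, dtype=int)
    for z in range(nz):
        assignment[xz[z]] = z
    held = np.asarray(amounts.T @ x.astype(np.float64)).ravel()
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    shortfalls = None
    if with_shortfall:
        shortfalls = np.zeros(nf)
        shortfalls[tgt_idx] = np.maximum(problem.targets[tgt_idx] - held[tgt_idx], 0.0)
    if limit_hit:
        status = "time_limit"
    else:
        status = "optimal" if gap <= 1e-9 else "gap_ok"
    return Allocation(
        cell_ids=problem.cell_ids,
        zone_names=[z.name for z in problem.zones],
        feature_names=list(problem.feature_names),
        assignment=assignment,
        objective_value=float(res.fun),
        achieved_gap=gap,
        status=status,
        held=held,
        shortfalls=shortfalls,
    )


def _options(problem: AllocationProblem) -> dict:
    opts = {"mip_rel_gap": problem.mip_gap, "presolve": True}
    if problem.time_limit is not None:
        opts["time_limit"] = float(problem.time_limit)
    return opts


def solve_min_set(problem: AllocationProblem) -> Allocation:
    """Minimise total cost subject to meeting every positive target."""
    c, constraints, (lb, ub), integrality, tgt_idx, amounts = _assemble(
        problem, with_shortfall=False
    )
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=_options(problem),
    )
    return _finish(problem, res, tgt_idx, amounts, with_shortfall=False)


def solve_min_shortfall(problem: AllocationProblem) -> Allocation:
    """Minimise the sum of proportional shortfalls under a cost budget.

    Zero targets are trivially met and carry no shortfall term. The budget
    may be finite or "effectively infinite"
    (:func:`effectively_infinite_budget`), the latter simulating no budget.
    The objective carries a ``tie_break``-weighted cost term so solutions
    with equal shortfall resolve to the cheapest selection.
    """
    if problem.budget is None:
        problem = replace(problem, budget=effectively_infinite_budget(problem))
    c, constraints, (lb, ub), integrality, tgt_idx, amounts = _assemble(
        problem, with_shortfall=True
    )
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=_options(problem),
    )
    return _finish(problem, res, tgt_idx, amounts, with_shortfall=True)


def solve(problem: AllocationProblem) -> Allocation:
    if problem.objective == "min_set":
        return solve_min_set(problem)
    if problem.objective == "min_shortfall":
        return solve_min_shortfall(problem)
    raise ValueError(f"unknown objective {problem.objective!r}")


# ---------------------------------------------------------------------------
# JSON round trip for debugging and oracle replay


def problem_to_json(problem: AllocationProblem) -> str:
    zones = []
    for z in problem.zones:
        coo = z.amounts.tocoo()
        zones.append(
            {
                "name": z.name,
                "cost": z.cost.tolist(),
                "triplets": [
                    [int(i), int(j), float(v)]
                    for i, j, v in zip(coo.row, coo.col, coo.data)
                ],
            }
        )
    return json.dumps(
        {
            "cell_ids": problem.cell_ids.tolist(),
            "feature_names": list(problem.feature_names),
            "targets": problem.targets.tolist(),
            "zones": zones,
            "locked_in": problem.locked_in.astype(int).tolist(),
            "locked_out": problem.locked_out.astype(int).tolist(),
            "objective": problem.objective,
            "budget": problem.budget,
            "mip_gap": problem.mip_gap,
        }
    )


def problem_from_json(text: str) -> AllocationProblem:
    d = json.loads(text)
    nc = len(d["cell_ids"])
    nf = len(d["feature_names"])
    zones = []
    for zd in d["zones"]:
        m = sp.lil_matrix((nc, nf))
        for i, j, v in zd["triplets"]:
            m[i, j] = v
        zones.append(Zone(zd["name"], np.array(zd["cost"]), m.tocsr()))
    return AllocationProblem(
        cell_ids=np.array(d["cell_ids"]),
        zones=zones,
        feature_names=d["feature_names"],
        targets=np.array(d["targets"]),
        locked_in=np.array(d["locked_in"], dtype=bool),
        locked_out=np.array(d["locked_out"], dtype=bool),
        objective=d["objective"],
        budget=d["budget"],
        mip_gap=d["mip_gap"],
    )
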