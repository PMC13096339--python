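"""Independent exhaustive-enumeration oracle for small zoned instances.

Enumerates every assignment of cells to zones (or to none) and evaluates
the minimum-set / minimum-shortfall objectives in closed form, entirely
independent of the MILP path it cross-checks.
"""

import itertools

import numpy as np
from scipy import sparse as sp

from landalloc.allocator import AllocationProblem, Zone


def enumerate_optimum(problem: AllocationProblem):
    """Optimal objective value by brute force, or None when infeasible."""
    nz, nc = problem.n_zones, problem.n_cells
    nf = len(problem.feature_names)
    codes = np.array(
        list(itertools.product(range(nz + 1), repeat=nc)), dtype=np.int64
    )  # 0 = unassigned, z+1 = zone z
    m = len(codes)

    cost_of = np.zeros((nz + 1, nc))
    amts = np.zeros((nz + 1, nc, nf))
    for z, zone in enumerate(problem.zones):
        cost_of[z + 1] = zone.cost
        amts[z + 1] = zone.amounts.toarray()

    ok = np.ones(m, dtype=bool)
    for z in range(nz):
        if problem.locked_in[z].any():
            ok &= (codes[:, problem.locked_in[z]] == z + 1).all(axis=1)
        if problem.locked_out[z].any():
            ok &= (codes[:, problem.locked_out[z]] != z + 1).all(axis=1)
    for coef, lo, hi in problem.extra_constraints:
        coef = np.asarray(coef).reshape(nz, nc)
        coef_of = np.vstack([np.zeros(nc), coef])
        val = coef_of[codes, np.arange(nc)].sum(axis=1)
        ok &= (val >= lo - 1e-9) & (val <= hi + 1e-9)

    idx = np.arange(nc)
    total_cost = cost_of[codes, idx].sum(axis=1)
    held = amts[codes, idx].sum(axis=1)  # (m, nf)
    T = problem.targets

    if problem.objective == "min_set":
        feas = ok & (held >= T[None, :] - 1e-9).all(axis=1)
        if not feas.any():
            return None
        return float(total_cost[feas].min())
    budget = problem.budget
    feas = ok & (total_cost <= budget + 1e-9)
    if not feas.any():
        return None
    pos = T > 0
    short = np.maximum(T[None, pos] - held[:, pos], 0.0)
    obj = (short / T[None, pos]).sum(axis=1) + problem.tie_break * total_cost
    return float(obj[feas].min())


def random_instance(rng: np.random.Generator, objective: str) -> AllocationProblem:
    """Random small instance with enumerable assignment space.

    Sizes stay within 15 cells and 3 zones, jointly bounded so that
    (n_zones + 1)^n_cells is at most ~20k assignments.
    """
    nz = int(rng.integers(1, 4))
    max_cells = {1: 14, 2: 9, 3: 7}[nz]
    nc = int(rng.integers(1, max_cells + 1))
    nf = int(rng.integers(1, 5))
    zones = []
    for z in range(nz):
        cost = rng.uniform(0.5, 3.0, size=nc)
        amounts = rng.exponential(1.0, size=(nc, nf)) * (rng.random((nc, nf)) < 0.6)
        zones.append(Zone(f"z{z}", cost, sp.csr_matrix(amounts)))
    totals = np.sum([z.amounts.toarray() for z in zones], axis=(0, 1))
    targets = np.maximum(totals * rng.uniform(0.0, 1.3, size=nf), 0.0)
    locked_in = np.zeros((nz, nc), dtype=bool)
    locked_out = np.zeros((nz, nc), dtype=bool)
    if rng.random() < 0.3:
        locked_in[rng.integers(nz), rng.integers(nc)] = True
    if rng.random() < 0.3:
        z, i = rng.integers(nz), rng.integers(nc)
        if not locked_in[z, i]:
            locked_out[z, i] = True
    budget = None
    if objective == "min_shortfall":
        total_cost = sum(z.cost.sum() for z in zones)
        budget = float(rng.choice([0.0, rng.uniform(0.2, 0.8) * total_cost, total_cost + 1.0]))
        if locked_in.any():
            budget = max(budget, float(total_cost))  # keep locks affordable
    return AllocationProblem(
        cell_ids=np.arange(nc),
        zones=zones,
        feature_names=[f"f{j}" for j in range(nf)],
        targets=targets,
        locked_in=locked_in,
        locked_out=locked_out,
        objective=objective,
        budget=budget,
        mip_gap=0.0,
    )
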