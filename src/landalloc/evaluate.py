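"""Scenario evaluation: targets met, land efficiency, exposure, conflict.

All achievement metrics are computed against the original (un-scaled,
un-decremented) targets. Species targets are assessed at the species level
— the sum of held habitat across countries against the sum of country
targets — while NCP, carbon and development targets are assessed per
country.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids_io import ConformityError, Layer, PlanningGrid
from .scenarios import SECTOR_CODES, ScenarioConfig, ScenarioResult
from .targets import TargetSet

__all__ = [
    "EvaluationReport",
    "ConflictMap",
    "CONFLICT_CLASSES",
    "targets_met",
    "land_efficiency",
    "species_exposure",
    "carbon_exposure",
    "conflict_overlay",
    "colocation_overlap",
    "evaluate_scenario",
]

_REL_TOL = 1e-9

CONFLICT_CLASSES = {
    "none": 0,
    "existing_conservation": 1,
    "conservation_30": 2,
    "conservation_full": 3,
    "development": 4,
    "conflict_30_or_pa": 5,
    "conflict_full": 6,
}


@dataclass
class EvaluationReport:
    """Derived metrics for one scenario run."""

    targets: pd.DataFrame  # per-row achievement (species rows are global)
    summary: dict  # fraction of targets met by kind
    land_km2: dict  # per category
    efficiency: pd.DataFrame  # sector, area_km2, production, km2_per_unit
    exposure: pd.DataFrame  # per-species overlap and exposed flag
    exposure_counts: dict  # by IUCN category
    carbon_exposed_mt: float


@dataclass
class ConflictMap:
    class_map: np.ndarray  # int16 grid
    legend: dict
    areas_km2: dict


def targets_met(result: ScenarioResult, original_targets: TargetSet) -> pd.DataFrame:
    """Achievement per target row against the original targets.

    Species rows are aggregated globally (held and target summed over
    countries) and reported once per species with country set to NaN; NCP,
    carbon and sector rows stay per country. ``met`` uses held >= target
    with a tiny relative tolerance; zero targets are trivially met.
    """
    held = result.held.copy()
    if not len(held):
        return held
    sp_rows = held[held["kind"] == "species"]
    other = held[held["kind"] != "species"].copy()
    if len(sp_rows):
        agg = sp_rows.groupby("feature", as_index=False).agg(
            kind=("kind", "first"),
            units=("units", "first"),
            target=("target", "sum"),
            held=("held", "sum"),
        )
        agg.insert(0, "country", np.nan)
        rows = pd.concat([agg, other], ignore_index=True)
    else:
        rows = other
    tol = _REL_TOL * np.maximum(rows["target"], 1.0)
    rows["met"] = (rows["held"] >= rows["target"] - tol) | (rows["target"] <= 0)
    rows["fraction"] = np.where(
        rows["target"] > 0, np.minimum(rows["held"] / rows["target"], 1.0), 1.0
    )
    return rows


def land_efficiency(result: ScenarioResult, per_country: bool = False) -> pd.DataFrame:
    """Land allocated per unit of achieved production, by sector.

    Pooled by default: the sector's total allocated area divided by its
    total achieved production (GW or tonnes); ``per_country`` splits both
    by country. Sectors with zero achieved production are reported with NaN
    efficiency and a reason, never a division by zero.
    """
    grid = result.grid
    rows = []
    country_groups = grid.countries if per_country else [None]
    for sector, code in SECTOR_CODES.items():
        for country in country_groups:
            sel = result.category_map == code
            if country is not None:
                sel &= grid.country_mask(country)
            area = float(sel.sum()) * grid.cell_area_km2
            prod = 0.0
            for (c, _step), alloc in result.allocations.items():
                if country is not None and c != country:
                    continue
                if sector in alloc.feature_names:
                    prod += alloc.held_for(sector)
            note = "" if prod > 0 else "no achieved production"
            eff = area / prod if prod > 0 else np.nan
            rows.append((country, sector, area, prod, eff, note))
    return pd.DataFrame(
        rows,
        columns=["country", "sector", "area_km2", "production", "km2_per_unit", "note"],
    )


def species_exposure(
    dev_mask: np.ndarray,
    species_features: list,
    grid: PlanningGrid,
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-species overlap of habitat with the development footprint.

    overlap_frac = habitat area inside development cells / global range; a
    species is exposed when overlap_frac is at least ``threshold`` (10% of
    its range, boundary inclusive).
    """
    if dev_mask.shape != grid.shape:
        raise ConformityError("development mask does not match the grid")
    rows = []
    for spf in species_features:
        overlap = spf.habitat.masked_sum(dev_mask)
        frac = overlap / spf.global_range_km2
        rows.append(
            (spf.id, spf.iucn_category, overlap, frac, frac >= threshold - _REL_TOL)
        )
    return pd.DataFrame(
        rows, columns=["species", "iucn_category", "overlap_km2", "overlap_frac", "exposed"]
    )


def exposure_counts(exposure: pd.DataFrame, mean_over: str = "exposed") -> dict:
    """Exposed-species counts and mean overlap by IUCN category.

    Mean overlap is over exposed species by default (set ``mean_over`` to
    'all' to average over every species).
    """
    out = {}
    for cat in ("NT", "VU", "EN", "CR"):
        sub = exposure[exposure["iucn_category"] == cat]
        exp = sub[sub["exposed"]]
        pool = exp if mean_over == "exposed" else sub
        out[cat] = {
            "n_exposed": int(exp["exposed"].sum()),
            "mean_overlap_frac": float(pool["overlap_frac"].mean()) if len(pool) else np.nan,
        }
    out["total_exposed"] = int(exposure["exposed"].sum())
    return out


def carbon_exposure(dev_mask: np.ndarray, carbon_layer: Layer) -> float:
    """Total carbon (Mt) on cells allocated to development."""
    return carbon_layer.masked_sum(dev_mask)


def conflict_overlay(
    prod_first_30: ScenarioResult,
    nature_first_30: ScenarioResult,
    prod_first_full: ScenarioResult,
    nature_first_full: ScenarioResult,
    pa_mask: Layer,
) -> ConflictMap:
    """Four-way overlay of development vs conservation allocations.

    Development cells (the union of the two Production-First footprints)
    overlapping Nature-First-30% conservation or existing protected areas
    are the strongest conflict class; those overlapping only the
    unconstrained Nature-First conservation are the weaker class. Cells
    claimed by one side only keep their single class. Classes partition the
    grid.
    """
    shapes = {
        r.grid.shape for r in (prod_first_30, nature_first_30, prod_first_full, nature_first_full)
    }
    if len(shapes) != 1 or pa_mask.values.shape not in shapes:
        raise ConformityError("scenario results are not on one world")
    grid = prod_first_30.grid
    dev = prod_first_30.dev_mask() | prod_first_full.dev_mask()
    cons30 = nature_first_30.new_conservation_mask()
    consfull = nature_first_full.new_conservation_mask()
    pa = pa_mask.values.astype(bool) & grid.land_mask

    cm = np.zeros(grid.shape, dtype=np.int16)
    cm[consfull] = CONFLICT_CLASSES["conservation_full"]
    cm[cons30] = CONFLICT_CLASSES["conservation_30"]
    cm[pa] = CONFLICT_CLASSES["existing_conservation"]
    cm[dev] = CONFLICT_CLASSES["development"]
    cm[dev & consfull] = CONFLICT_CLASSES["conflict_full"]
    cm[dev & (cons30 | pa)] = CONFLICT_CLASSES["conflict_30_or_pa"]
    cm[~grid.land_mask] = CONFLICT_CLASSES["none"]

    areas = {
        name: float((cm == code).sum()) * grid.cell_area_km2
        for name, code in CONFLICT_CLASSES.items()
    }
    return ConflictMap(cm, dict(CONFLICT_CLASSES), areas)


def colocation_overlap(
    world,
    targets: TargetSet,
    cfg: ScenarioConfig | None = None,
    footprints: dict | None = None,
) -> pd.DataFrame:
    """Overlap between independently prioritised single-use allocations.

    Solves three independent problems — crops (food plus energy), PV solar,
    and wind — with the production-first cost structure and no mutual
    exclusivity between them, then reports the pairwise footprint overlaps
    as a fraction of each side's area. Precomputed boolean ``footprints``
    (keys 'crops', 'pv_solar', 'wind') skip the solves.
    """
    from .scenarios import build_development_problem, decrement_demand_until_feasible

    cfg = cfg or ScenarioConfig(scenario="production_first")
    grid = world.grid
    groups = {
        "crops": ["food_crops", "energy_crops"],
        "pv_solar": ["pv_solar"],
        "wind": ["wind"],
    }
    if footprints is None:
        footprints = {}
        for name, sectors in groups.items():
            mask = np.zeros(grid.shape, dtype=bool)
            for country in grid.countries:
                problem = build_development_problem(
                    world, country, targets, cfg, "production_first",
                    objective="min_set", sectors=sectors,
                )
                if problem is None:
                    continue
                alloc = decrement_demand_until_feasible(
                    problem, cfg.demand_decrement
                ).allocation
                mask.ravel()[alloc.cell_ids[alloc.assignment >= 0]] = True
            footprints[name] = mask

    rows = []
    for a, b in (("crops", "pv_solar"), ("crops", "wind")):
        inter = float((footprints[a] & footprints[b]).sum()) * grid.cell_area_km2
        area_a = float(footprints[a].sum()) * grid.cell_area_km2
        area_b = float(footprints[b].sum()) * grid.cell_area_km2
        rows.append(
            (
                a,
                b,
                inter,
                100.0 * inter / area_a if area_a else 0.0,
                100.0 * inter / area_b if area_b else 0.0,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["a", "b", "overlap_km2", "pct_of_a", "pct_of_b"],
    )


def evaluate_scenario(result: ScenarioResult, world, original_targets: TargetSet) -> EvaluationReport:
    """Full metric suite for one scenario result."""
    rows = targets_met(result, original_targets)
    summary = {}
    for kind in ("species", "ncp", "carbon", "sector"):
        sub = rows[rows["kind"] == kind]
        if len(sub):
            summary[kind] = float(sub["met"].mean())
    dev = result.dev_mask()
    exposure = species_exposure(dev, world.species, world.grid)
    return EvaluationReport(
        targets=rows,
        summary=summary,
        land_km2=result.category_areas_km2(),
        efficiency=land_efficiency(result),
        exposure=exposure,
        exposure_counts=exposure_counts(exposure),
        carbon_exposed_mt=carbon_exposure(dev, world.carbon.layer),
    )
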