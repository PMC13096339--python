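"""Conservation features, demand tables, and country-level target setting.

Targets are absolute, per-country quantities in feature units:

* species — a percentage of the species' habitat retained under future
  climatic suitability within each country, with the percentage set globally
  from range size (100% for ranges below a lower threshold, 10% above an
  upper threshold, log-linear in between);
* carbon / NCP — 90% of the current country-level amount;
* development sectors — regional demand (GW of capacity or tonnes of dry
  matter) disaggregated to countries by market share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids_io import Layer, PlanningGrid, SparseAmounts

__all__ = [
    "SpeciesFeature",
    "AssetFeature",
    "SectorSpec",
    "DemandTable",
    "TargetSet",
    "species_pct_target",
    "country_conservation_targets",
    "disaggregate_demand",
    "build_targets",
    "feasibility_report",
    "SECTOR_UNITS",
]

IUCN_CATEGORIES = ("NT", "VU", "EN", "CR")

SECTOR_UNITS = {
    "food_crops": "tonnes",
    "energy_crops": "tonnes",
    "pv_solar": "GW",
    "csp": "GW",
    "wind": "GW",
    "hydro": "GW",
}


@dataclass
class SpeciesFeature:
    """One species: current habitat, climate-retained habitat, target rule.

    ``retained`` is habitat intersected with projected future climatic
    suitability; when that intersection is empty the full current habitat is
    carried instead (the fallback used for climate-displaced species).
    ``global_range_km2`` is the world total of current habitat.
    """

    id: str
    iucn_category: str
    habitat: Layer
    retained: Layer
    global_range_km2: float
    pct_target: float

    def __post_init__(self):
        if self.iucn_category not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {self.iucn_category!r}")
        if self.global_range_km2 <= 0:
            raise ValueError("global range must be positive")
        if not (0 < self.pct_target <= 1):
            raise ValueError("pct_target must lie in (0, 1]")


@dataclass
class AssetFeature:
    """A non-species conservation asset (vulnerable carbon or one NCP layer)."""

    id: str
    kind: str  # 'carbon' | 'ncp'
    layer: Layer
    pct_target: float = 0.9

    def __post_init__(self):
        if self.kind not in ("carbon", "ncp"):
            raise ValueError("asset kind must be 'carbon' or 'ncp'")


@dataclass
class SectorSpec:
    """A development sector: potential yield and development-potential index."""

    name: str
    yield_layer: Layer
    dpi: Layer
    unit: str = ""

    def __post_init__(self):
        if not self.unit:
            self.unit = SECTOR_UNITS.get(self.name, "")


@dataclass
class DemandTable:
    """Regional sector demand plus country market shares.

    ``demand`` is indexed by region with one column per sector (GW or
    tonnes); ``share`` is indexed by country. Within each region x sector the
    member countries' shares must sum to one.
    """

    demand: pd.DataFrame
    share: pd.DataFrame
    region_of_country: dict

    def validate(self, atol: float = 1e-6) -> None:
        if (self.demand.values < 0).any():
            raise ValueError("negative regional demand")
        if ((self.share.values < -atol) | (self.share.values > 1 + atol)).any():
            raise ValueError("shares must lie in [0, 1]")
        for region in self.demand.index:
            members = [c for c, r in self.region_of_country.items() if r == region]
            s = self.share.loc[members].sum(axis=0)
            bad = s[(s - 1.0).abs() > atol]
            if len(bad):
                raise ValueError(
                    f"shares in region {region!r} do not sum to 1 for {list(bad.index)}"
                )


@dataclass
class TargetSet:
    """Tidy table of absolute targets: one row per country x feature."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["country", "feature", "kind", "units", "target"]
        )
    )

    def __post_init__(self):
        if len(self.table) and (self.table["target"] < 0).any():
            raise ValueError("targets must be non-negative")

    def subset(self, country=None, kinds=None) -> pd.DataFrame:
        t = self.table
        if country is not None:
            t = t[t["country"] == country]
        if kinds is not None:
            t = t[t["kind"].isin(kinds)]
        return t

    def conservation(self, country) -> pd.DataFrame:
        return self.subset(country, kinds=["species", "carbon", "ncp"])

    def development(self, country) -> pd.DataFrame:
        return self.subset(country, kinds=["sector"])

    def scaled(self, factor: float, kinds=("species", "carbon", "ncp")) -> "TargetSet":
        t = self.table.copy()
        sel = t["kind"].isin(kinds)
        t.loc[sel, "target"] = t.loc[sel, "target"] * factor
        return TargetSet(t)


def species_pct_target(
    global_range_km2: float,
    lower_km2: float = 1000.0,
    upper_km2: float = 250000.0,
    cap_pct: float = 1.0,
    floor_pct: float = 0.1,
) -> float:
    """Percentage of a species' habitat to conserve, from global range size.

    Small-ranged species get the cap (100% by default), wide-ranged species
    the floor (10%), with log-linear interpolation between the two range
    thresholds. All four constants are configurable.
    """
    if global_range_km2 <= 0:
        raise ValueError("global range must be positive")
    if global_range_km2 <= lower_km2:
        return cap_pct
    if global_range_km2 >= upper_km2:
        return floor_pct
    frac = (np.log(global_range_km2) - np.log(lower_km2)) / (
        np.log(upper_km2) - np.log(lower_km2)
    )
    return float(cap_pct + (floor_pct - cap_pct) * frac)


def country_conservation_targets(
    species: list, assets: list, grid: PlanningGrid
) -> pd.DataFrame:
    """Absolute per-country targets for species and asset features.

    A species' target in country c is its percentage target applied to its
    retained habitat in c; carbon and NCP targets are 90% (the asset's
    ``pct_target``) of the current country amount. Countries where a feature
    is absent get no row.
    """
    cid = grid.country_id
    rows = []
    for spf in species:
        for c in grid.countries:
            amt = spf.retained.masked_sum(cid == c)
            if amt > 0:
                rows.append((c, spf.id, "species", "km2", spf.pct_target * amt))
    for a in assets:
        units = "Mt" if a.kind == "carbon" else "index"
        for c in grid.countries:
            amt = a.layer.masked_sum(cid == c)
            if amt > 0:
                rows.append((c, a.id, a.kind, units, a.pct_target * amt))
    return pd.DataFrame(rows, columns=["country", "feature", "kind", "units", "target"])


def disaggregate_demand(demand: DemandTable) -> pd.DataFrame:
    """Split regional demand into country targets by market share.

    dev_target[c][s] = demand[region(c)][s] * share[c][s]; region totals are
    preserved exactly because shares sum to one within each region.
    """
    demand.validate()
    rows = []
    for c, region in demand.region_of_country.items():
        for s in demand.demand.columns:
            t = float(demand.demand.loc[region, s]) * float(demand.share.loc[c, s])
            rows.append((c, s, "sector", SECTOR_UNITS.get(s, ""), t))
    return pd.DataFrame(rows, columns=["country", "feature", "kind", "units", "target"])


def build_targets(world) -> TargetSet:
    """Full target set for a world: conservation features plus sector demand."""
    cons = country_conservation_targets(world.species, world.assets, world.grid)
    dev = disaggregate_demand(world.demand)
    return TargetSet(pd.concat([cons, dev], ignore_index=True))


def feasibility_report(
    targets: TargetSet, amounts: SparseAmounts, grid: PlanningGrid
) -> pd.DataFrame:
    """Necessary-condition screen: is each target under the available total?

    Sums each feature's amount over available cells per country (ignoring
    the one-zone-per-cell exclusivity, so passing this screen does not prove
    the joint problem feasible) and flags targets that exceed it.
    """
    cell_country = grid.country_id.ravel()[amounts.cell_ids]
    avail = {}
    for _, row in targets.table.iterrows():
        key = (row["country"], row["feature"])
        if key in avail:
            continue
        j = (
            amounts.feature_names.index(row["feature"])
            if row["feature"] in amounts.feature_names
            else None
        )
        if j is None:
            avail[key] = 0.0
            continue
        zone = "conservation" if row["kind"] in ("species", "carbon", "ncp") else row["feature"]
        col = np.asarray(amounts.matrices[zone][:, j].todense()).ravel()
        avail[key] = float(col[cell_country == row["country"]].sum())
    out = targets.table.copy()
    out["available"] = [avail[(r["country"], r["feature"])] for _, r in out.iterrows()]
    out["feasible"] = out["available"] >= out["target"] - 1e-9
    return out
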