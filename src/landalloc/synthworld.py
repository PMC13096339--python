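"""Self-contained synthetic worlds for the land-allocation pipeline.

Real applications of this framework consume continental raster stacks:
species habitat filtered by future climatic suitability, vulnerable carbon,
NCP indices, per-sector potential yields and development-potential indices
(DPI), human modification, and protected areas, plus regional demand tables.
This module generates small worlds with the same statistical structure so
every downstream stage (targets, allocation, scenarios, evaluation) can be
exercised end to end:

* spatially autocorrelated non-negative asset surfaces (FFT-filtered
  Gaussian random fields, exponentiated);
* compact species ranges grown as randomised-BFS blobs with a heavy-tailed
  (log-normal by default) range-area distribution;
* [0, 1] suitability indices (DPI, human modification) as squashed fields;
* clumped binary protected-area masks hitting a configured land fraction;
* contiguous countries (multi-source flood fill) grouped into demand
  regions, with per-region demand calibrated to a configured fraction of
  feasible supply and country market shares summing to one.

Everything is driven by one integer seed through fixed per-component
substreams, so identical configs reproduce identical worlds bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids_io import Layer, PlanningGrid, availability_mask, read_layer, write_layer
from .targets import (
    AssetFeature,
    DemandTable,
    SECTOR_UNITS,
    SectorSpec,
    SpeciesFeature,
    species_pct_target,
)

__all__ = [
    "RangeSizeLaw",
    "HMParams",
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "generate_world",
    "generate_species",
    "generate_demand",
    "gaussian_random_field",
    "write_world",
    "read_world",
]

ALL_SECTORS = ("food_crops", "energy_crops", "pv_solar", "csp", "wind", "hydro")

# mean per-cell potential yield at cell_area = 25 km2 (GW of capacity for the
# energy sectors, tonnes of dry matter for the crop sectors)
SECTOR_YIELD_SCALE = {
    "food_crops": 2500.0,
    "energy_crops": 1800.0,
    "pv_solar": 0.030,
    "csp": 0.020,
    "wind": 0.015,
    "hydro": 0.004,
}

# fixed substream labels: reproducibility is unaffected by the order in
# which components are generated
_SUBSTREAMS = {
    "land": 0,
    "countries": 1,
    "hm": 2,
    "pa": 3,
    "carbon": 4,
    "ncp": 5,
    "species": 6,
    "sectors": 7,
    "demand": 8,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS[component],))
    )


@dataclass(frozen=True)
class RangeSizeLaw:
    """Heavy-tailed distribution of species range areas (km^2)."""

    dist: str = "lognormal"
    median_km2: float = 1500.0
    sigma_log: float = 1.2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist != "lognormal":
            raise ValueError(f"unsupported range-size law {self.dist!r}")
        return np.exp(rng.normal(np.log(self.median_km2), self.sigma_log, size=n))


@dataclass(frozen=True)
class HMParams:
    """Human-modification surface: target mean and spatial roughness."""

    mean: float = 0.25
    sd: float = 0.22
    correlation_length: float = 5.0


@dataclass(frozen=True)
class SyntheticWorldConfig:
    seed: int = 0
    n_rows: int = 40
    n_cols: int = 40
    cell_area_km2: float = 25.0
    n_countries: int = 3
    n_regions: int = 2
    n_species: int = 30
    n_ncp: int = 6
    range_size_law: RangeSizeLaw = field(default_factory=RangeSizeLaw)
    climate_overlap_frac: float = 0.7
    asset_correlation_length: float = 6.0
    pa_fraction: float = 0.12
    hm_params: HMParams = field(default_factory=HMParams)
    sectors: tuple = ALL_SECTORS
    land_fraction: float = 0.92
    demand_fraction: float = 0.10

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_regions > self.n_countries:
            raise ValueError("n_regions must not exceed n_countries")
        if self.n_countries < 1 or self.n_species < 0:
            raise ValueError("invalid counts")
        if not (0 <= self.climate_overlap_frac <= 1):
            raise ValueError("climate_overlap_frac must lie in [0, 1]")
        if not (0 <= self.pa_fraction < 1):
            raise ValueError("pa_fraction must lie in [0, 1)")
        if not (0 < self.land_fraction <= 1):
            raise ValueError("land_fraction must lie in (0, 1]")
        if self.asset_correlation_length <= 0 or self.cell_area_km2 <= 0:
            raise ValueError("lengths and areas must be positive")
        unknown = set(self.sectors) - set(ALL_SECTORS)
        if unknown:
            raise ValueError(f"unknown sectors: {sorted(unknown)}")


@dataclass
class SyntheticWorld:
    grid: PlanningGrid
    species: list
    assets: list
    sectors: list
    pa_mask: Layer
    hm: Layer
    demand: DemandTable
    config: SyntheticWorldConfig | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        g = self.grid
        for layer in [self.pa_mask, self.hm]:
            layer.conform(g)
        for spf in self.species:
            spf.habitat.conform(g)
            spf.retained.conform(g)
            if spf.habitat.values[g.land_mask].min() < 0:
                raise ValueError("negative habitat amount")
        for a in self.assets:
            a.layer.conform(g)
        for s in self.sectors:
            s.yield_layer.conform(g)
            s.dpi.conform(g)
        self.demand.validate()

    @property
    def carbon(self) -> AssetFeature:
        return next(a for a in self.assets if a.kind == "carbon")

    @property
    def ncp_layers(self) -> list:
        return [a for a in self.assets if a.kind == "ncp"]

    def availability(self, hm_threshold: float = 0.8) -> Layer:
        return availability_mask(self.hm, self.grid, hm_threshold)


def gaussian_random_field(
    shape: tuple, correlation_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardised Gaussian random field with ~Gaussian correlogram.

    White noise is filtered in Fourier space with a Gaussian spectral
    envelope; the correlogram decays monotonically on the scale of
    ``correlation_length`` cells.
    """
    noise = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    k2 = (2 * np.pi) ** 2 * (fy**2 + fx**2)
    envelope = np.exp(-k2 * correlation_length**2 / 4.0)
    f = np.fft.ifft2(np.fft.fft2(noise) * envelope).real
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _make_land(config: SyntheticWorldConfig) -> np.ndarray:
    if config.land_fraction >= 1.0:
        return np.ones((config.n_rows, config.n_cols), dtype=bool)
    rng = _rng(config.seed, "land")
    f = gaussian_random_field(
        (config.n_rows, config.n_cols), max(config.n_rows, config.n_cols) / 3.0, rng
    )
    thresh = np.quantile(f, 1.0 - config.land_fraction)
    return _largest_component(f >= thresh)


_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _flood_fill_countries(
    land: np.ndarray, n_countries: int, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous partition of land cells by randomised multi-source BFS."""
    n_land = int(land.sum())
    if n_countries > n_land:
        raise ValueError("n_countries exceeds the number of land cells")
    rows, cols = np.nonzero(land)
    order = rng.permutation(n_land)[:n_countries]
    cid = np.zeros(land.shape, dtype=np.int32)
    frontiers = []
    for k, idx in enumerate(order, start=1):
        cid[rows[idx], cols[idx]] = k
        frontiers.append([(rows[idx], cols[idx])])
    remaining = n_land - n_countries
    while remaining > 0:
        grew = False
        for k in rng.permutation(n_countries):
            frontier = frontiers[k]
            while frontier:
                i = rng.integers(len(frontier))
                r, c = frontier[i]
                nbrs = [
                    (r + dr, c + dc)
                    for dr, dc in _NEIGHBORS
                    if 0 <= r + dr < land.shape[0]
                    and 0 <= c + dc < land.shape[1]
                    and land[r + dr, c + dc]
                    and cid[r + dr, c + dc] == 0
                ]
                if not nbrs:
                    frontier[i] = frontier[-1]
                    frontier.pop()
                    continue
                rr, cc = nbrs[rng.integers(len(nbrs))]
                cid[rr, cc] = k + 1
                frontier.append((rr, cc))
                remaining -= 1
                grew = True
                break
        if not grew:
            # land disconnected from every seed (should not happen on a
            # single connected component); absorb leftovers into country 1
            cid[land & (cid == 0)] = 1
            remaining = 0
    return cid


def _positive_field(shape, corr, rng, mean_value: float) -> np.ndarray:
    f = np.exp(0.8 * gaussian_random_field(shape, corr, rng))
    return f * (mean_value / f.mean())


def _grow_blob(
    land: np.ndarray, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Compact connected blob of ``n_cells`` land cells (randomised BFS)."""
    rows, cols = np.nonzero(land)
    start = rng.integers(len(rows))
    blob = np.zeros(land.shape, dtype=bool)
    blob[rows[start], cols[start]] = True
    frontier = [(rows[start], cols[start])]
    size = 1
    while size < n_cells and frontier:
        i = rng.integers(len(frontier))
        r, c = frontier[i]
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in _NEIGHBORS
            if 0 <= r + dr < land.shape[0]
            and 0 <= c + dc < land.shape[1]
            and land[r + dr, c + dc]
            and not blob[r + dr, c + dc]
        ]
        if not nbrs:
            frontier[i] = frontier[-1]
            frontier.pop()
            continue
        rr, cc = nbrs[rng.integers(len(nbrs))]
        blob[rr, cc] = True
        frontier.append((rr, cc))
        size += 1
    return blob


def generate_species(
    grid: PlanningGrid,
    n: int,
    range_size_law: RangeSizeLaw,
    climate_overlap_frac: float,
    rng: np.random.Generator,
    suitability_correlation_length: float = 6.0,
) -> list:
    """Species with blob ranges and climate-filtered retained habitat.

    Each species' current habitat is a compact blob of occupied cells (area
    = cell_area per occupied cell); its retained layer is the intersection
    with a simulated future-suitability mask covering ``climate_overlap_frac``
    of the grid. Species whose intersection is empty keep their full current
    habitat as the retained layer.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    land = grid.land_mask
    n_land = int(land.sum())
    max_cells = max(1, int(0.4 * n_land))
    areas = range_size_law.sample(n, rng)
    cat_probs = {"NT": 0.35, "VU": 0.30, "EN": 0.22, "CR": 0.13}
    species = []
    for i in range(n):
        n_cells = int(np.clip(round(areas[i] / grid.cell_area_km2), 1, max_cells))
        blob = _grow_blob(land, n_cells, rng)
        habitat = blob.astype(np.float64) * grid.cell_area_km2
        if climate_overlap_frac >= 1.0:
            retained = habitat.copy()
        else:
            suit_field = gaussian_random_field(
                grid.shape, suitability_correlation_length, rng
            )
            thresh = np.quantile(suit_field, 1.0 - climate_overlap_frac)
            suitable = suit_field >= thresh
            inter = blob & suitable
            # climate-displaced species fall back to their current habitat
            retained = (
                (inter.astype(np.float64) * grid.cell_area_km2)
                if inter.any()
                else habitat.copy()
            )
        cat = rng.choice(list(cat_probs), p=list(cat_probs.values()))
        global_range = float(habitat.sum())
        species.append(
            SpeciesFeature(
                id=f"sp{i:04d}",
                iucn_category=str(cat),
                habitat=Layer(habitat, units="km2"),
                retained=Layer(retained, units="km2"),
                global_range_km2=global_range,
                pct_target=species_pct_target(global_range),
            )
        )
    return species


def generate_demand(
    world_or_parts,
    intensity_params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> DemandTable:
    """Regional demand calibrated against feasible supply, with shares.

    For each region and sector the demand equals ``fraction`` of the total
    potential yield on available cells in that region (fraction > 1 yields a
    deliberately demand-infeasible instance). Country market shares follow
    each country's supply share perturbed by noise and renormalised to sum
    to one within the region.
    """
    world = world_or_parts
    intensity = dict(intensity_params or {})
    fraction = intensity.get("fraction", 0.10)
    noise = intensity.get("share_noise", 0.1)
    if rng is None:
        rng = np.random.default_rng(0)
    grid = world.grid
    avail = world.availability().values.astype(bool)
    countries = grid.countries
    regions = sorted(set(grid.region_of_country.values()))
    sectors = [s.name for s in world.sectors]

    supply = pd.DataFrame(0.0, index=countries, columns=sectors)
    for s in world.sectors:
        vals = s.yield_layer.values
        for c in countries:
            supply.loc[c, s.name] = float(vals[avail & grid.country_mask(c)].sum())

    demand = pd.DataFrame(0.0, index=regions, columns=sectors)
    share = pd.DataFrame(0.0, index=countries, columns=sectors)
    for region in regions:
        members = [c for c in countries if grid.region_of_country[c] == region]
        for s in sectors:
            region_supply = float(supply.loc[members, s].sum())
            demand.loc[region, s] = max(fraction * region_supply, 1e-12)
            w = supply.loc[members, s].to_numpy(dtype=float)
            w = np.maximum(w, 1e-12) * np.exp(noise * rng.standard_normal(len(members)))
            w /= w.sum()
            for c, wi in zip(members, w):
                share.loc[c, s] = wi
    return DemandTable(demand, share, dict(grid.region_of_country))


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world from one config (deterministic)."""
    shape = (config.n_rows, config.n_cols)
    land = _make_land(config)
    cid = _flood_fill_countries(land, config.n_countries, _rng(config.seed, "countries"))
    region_names = [f"R{k+1}" for k in range(config.n_regions)]
    region_of_country = {
        c: region_names[(c - 1) % config.n_regions]
        for c in range(1, config.n_countries + 1)
    }
    grid = PlanningGrid(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        geotransform=(0.0, float(np.sqrt(config.cell_area_km2)), 0.0, 0.0, 0.0, -float(np.sqrt(config.cell_area_km2))),
        cell_area_km2=config.cell_area_km2,
        country_id=cid,
        region_of_country=region_of_country,
    )

    hp = config.hm_params
    hm_field = gaussian_random_field(shape, hp.correlation_length, _rng(config.seed, "hm"))
    hm_vals = np.clip(hp.mean + hp.sd * hm_field, 0.0, 1.0)
    hm_vals[~land] = 0.0
    hm = Layer(hm_vals, units="index")

    # clumped protected areas: top pa_fraction of a smooth field, exact count
    pa_vals = np.zeros(shape)
    n_pa = int(round(config.pa_fraction * land.sum()))
    if n_pa > 0:
        pa_field = gaussian_random_field(
            shape, config.asset_correlation_length, _rng(config.seed, "pa")
        )
        pa_field = np.where(land, pa_field, -np.inf)
        flat = np.argsort(pa_field, axis=None)[::-1][:n_pa]
        pa_vals.ravel()[flat] = 1.0
    pa_mask = Layer(pa_vals, units="binary")

    carbon_vals = _positive_field(
        shape, config.asset_correlation_length, _rng(config.seed, "carbon"), 0.08
    )
    carbon_vals[~land] = 0.0
    assets = [AssetFeature("carbon", "carbon", Layer(carbon_vals, units="Mt"))]
    ncp_rng = _rng(config.seed, "ncp")
    for k in range(config.n_ncp):
        v = _positive_field(shape, config.asset_correlation_length, ncp_rng, 1.0)
        v[~land] = 0.0
        assets.append(AssetFeature(f"ncp{k+1}", "ncp", Layer(v, units="index")))

    species = generate_species(
        grid,
        config.n_species,
        config.range_size_law,
        config.climate_overlap_frac,
        _rng(config.seed, "species"),
        suitability_correlation_length=config.asset_correlation_length,
    )

    sec_rng = _rng(config.seed, "sectors")
    sectors = []
    area_scale = config.cell_area_km2 / 25.0  # yields scale with cell area
    for name in config.sectors:
        dpi_field = gaussian_random_field(shape, config.asset_correlation_length, sec_rng)
        dpi_vals = 1.0 / (1.0 + np.exp(-dpi_field))
        dpi_vals[~land] = 0.0
        y = _positive_field(
            shape, config.asset_correlation_length, sec_rng,
            SECTOR_YIELD_SCALE[name] * area_scale,
        )
        if name == "hydro":
            # hydro potential is sparse: keep only the best fifth of cells
            cut = np.quantile(y[land], 0.8)
            y = np.where(y >= cut, y, 0.0)
        y[~land] = 0.0
        sectors.append(
            SectorSpec(name, Layer(y, units=SECTOR_UNITS[name]), Layer(dpi_vals, units="index"))
        )

    world = SyntheticWorld.__new__(SyntheticWorld)
    world.grid = grid
    world.species = species
    world.assets = assets
    world.sectors = sectors
    world.pa_mask = pa_mask
    world.hm = hm
    world.config = config
    world.demand = generate_demand(
        world,
        {"fraction": config.demand_fraction},
        _rng(config.seed, "demand"),
    )
    world.validate()
    return world


# ---------------------------------------------------------------------------
# world directory I/O


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_world(world: SyntheticWorld, path) -> None:
    """Write a world as a directory of TIFF layers, CSV tables and config."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    g = world.grid

    write_layer(Layer(g.country_id.astype(np.float64), units="id"), root / "country_id.tif", g)
    write_layer(world.hm, root / "hm.tif", g)
    write_layer(world.pa_mask, root / "pa_mask.tif", g)
    for a in world.assets:
        write_layer(a.layer, root / f"asset_{a.id}.tif", g)
    for spf in world.species:
        write_layer(spf.habitat, root / f"species_{spf.id}_habitat.tif", g)
        write_layer(spf.retained, root / f"species_{spf.id}_retained.tif", g)
    for s in world.sectors:
        write_layer(s.yield_layer, root / f"sector_{s.name}_yield.tif", g)
        write_layer(s.dpi, root / f"sector_{s.name}_dpi.tif", g)

    pd.DataFrame(
        [
            {
                "id": s.id,
                "iucn_category": s.iucn_category,
                "global_range_km2": s.global_range_km2,
                "pct_target": s.pct_target,
            }
            for s in world.species
        ]
    ).to_csv(root / "species.csv", index=False)
    pd.DataFrame(
        [{"id": a.id, "kind": a.kind, "pct_target": a.pct_target} for a in world.assets]
    ).to_csv(root / "assets.csv", index=False)
    pd.DataFrame(
        [{"name": s.name, "unit": s.unit} for s in world.sectors]
    ).to_csv(root / "sectors.csv", index=False)
    world.demand.demand.to_csv(root / "demand.csv")
    world.demand.share.to_csv(root / "shares.csv")
    pd.DataFrame(
        [{"country": c, "region": r} for c, r in g.region_of_country.items()]
    ).to_csv(root / "regions.csv", index=False)

    meta = {
        "geotransform": [float(v) for v in g.geotransform],
        "cell_area_km2": float(g.cell_area_km2),
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
    }
    cfg = {"grid": meta}
    if world.config is not None:
        cfg["config"] = asdict(world.config)
        cfg["config"]["sectors"] = list(world.config.sectors)
    (root / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    files = sorted(p.name for p in root.iterdir() if p.name != "manifest.json")
    manifest = {f: _sha256(root / f) for f in files}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_world(path) -> SyntheticWorld:
    """Read a world directory written by :func:`write_world`."""
    root = Path(path)
    cfg = yaml.safe_load((root / "config.yaml").read_text())
    meta = cfg["grid"]
    regions = pd.read_csv(root / "regions.csv")
    region_of_country = dict(zip(regions["country"].astype(int), regions["region"]))
    cid = read_layer(root / "country_id.tif").values.astype(np.int32)
    grid = PlanningGrid(
        n_rows=int(meta["n_rows"]),
        n_cols=int(meta["n_cols"]),
        geotransform=tuple(meta["geotransform"]),
        cell_area_km2=float(meta["cell_area_km2"]),
        country_id=cid,
        region_of_country=region_of_country,
    )
    hm = read_layer(root / "hm.tif", grid)
    pa = read_layer(root / "pa_mask.tif", grid)

    species = []
    sp_tab = pd.read_csv(root / "species.csv") if (root / "species.csv").stat().st_size else None
    if sp_tab is not None and len(sp_tab):
        for _, row in sp_tab.iterrows():
            species.append(
                SpeciesFeature(
                    id=row["id"],
                    iucn_category=row["iucn_category"],
                    habitat=read_layer(root / f"species_{row['id']}_habitat.tif", grid),
                    retained=read_layer(root / f"species_{row['id']}_retained.tif", grid),
                    global_range_km2=float(row["global_range_km2"]),
                    pct_target=float(row["pct_target"]),
                )
            )
    assets = []
    for _, row in pd.read_csv(root / "assets.csv").iterrows():
        assets.append(
            AssetFeature(
                row["id"], row["kind"],
                read_layer(root / f"asset_{row['id']}.tif", grid),
                pct_target=float(row["pct_target"]),
            )
        )
    sectors = []
    for _, row in pd.read_csv(root / "sectors.csv").iterrows():
        sectors.append(
            SectorSpec(
                row["name"],
                read_layer(root / f"sector_{row['name']}_yield.tif", grid),
                read_layer(root / f"sector_{row['name']}_dpi.tif", grid),
                unit=row["unit"],
            )
        )
    demand = pd.read_csv(root / "demand.csv", index_col=0)
    share = pd.read_csv(root / "shares.csv", index_col=0)
    share.index = share.index.astype(int)
    table = DemandTable(demand, share, region_of_country)
    return SyntheticWorld(grid, species, assets, sectors, pa, hm, table)
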