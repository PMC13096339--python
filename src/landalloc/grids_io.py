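"""Gridded planning-unit containers and raster/table I/O.

The planning frame is a regular grid of square cells (planning units). Every
spatial input — species habitat, carbon, NCP indices, sector yields, the
development-potential index (DPI), human modification (HM), protected areas —
is a single-band layer aligned to that grid. Layers are stored on disk as
single-band float32 TIFFs whose geotransform and units travel in a JSON
ImageDescription tag; in memory everything is float64.

Coordinate convention: row-major, 0-based flat cell indices; cell (0, 0) sits
at the geotransform origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import sparse as sp

NODATA = -9999.0

__all__ = [
    "NODATA",
    "PlanningGrid",
    "Layer",
    "SparseAmounts",
    "ConformityError",
    "read_layer",
    "write_layer",
    "availability_mask",
    "build_sparse",
]


class ConformityError(ValueError):
    """A layer does not align with the enclosing planning grid."""


@dataclass(frozen=True)
class PlanningGrid:
    """Spatial frame: cell geometry, country membership, region lookup.

    ``country_id`` is an integer raster; 0 marks non-land (ocean) cells and
    every land cell carries a country id >= 1. ``region_of_country`` maps each
    country id to the demand region it belongs to.
    """

    n_rows: int
    n_cols: int
    geotransform: tuple
    cell_area_km2: float
    country_id: np.ndarray
    region_of_country: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive")
        cid = np.asarray(self.country_id, dtype=np.int32)
        if cid.shape != (self.n_rows, self.n_cols):
            raise ConformityError("country_id shape does not match grid")
        object.__setattr__(self, "country_id", cid)
        missing = set(np.unique(cid[cid > 0]).tolist()) - set(self.region_of_country)
        if missing:
            raise ValueError(f"countries without a region: {sorted(missing)}")

    @property
    def shape(self) -> tuple:
        return (self.n_rows, self.n_cols)

    @property
    def land_mask(self) -> np.ndarray:
        return self.country_id > 0

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    @property
    def countries(self) -> list:
        return np.unique(self.country_id[self.country_id > 0]).tolist()

    def country_mask(self, country: int) -> np.ndarray:
        return self.country_id == country

    def country_cells(self, country: int) -> np.ndarray:
        """Flat (row-major) indices of the cells belonging to ``country``."""
        return np.flatnonzero(self.country_id.ravel() == country)

    def country_land_km2(self, country: int) -> float:
        return float(self.country_mask(country).sum()) * self.cell_area_km2


@dataclass
class Layer:
    """A single-band real-valued grid aligned to a :class:`PlanningGrid`."""

    values: np.ndarray
    units: str = ""
    nodata: float = NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConformityError("layer must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def conform(self, grid: PlanningGrid) -> "Layer":
        if self.shape != grid.shape:
            raise ConformityError(
                f"layer shape {self.shape} != grid shape {grid.shape}"
            )
        land = grid.land_mask
        vals = self.values[land]
        vals = vals[vals != self.nodata]
        if not np.all(np.isfinite(vals)):
            raise ConformityError("layer has non-finite values on land cells")
        return self

    def valid_mask(self, grid: PlanningGrid | None = None) -> np.ndarray:
        """Cells carrying data: not nodata, finite, and (if grid given) land."""
        m = (self.values != self.nodata) & np.isfinite(self.values)
        if grid is not None:
            m &= grid.land_mask
        return m

    def masked_sum(self, mask: np.ndarray) -> float:
        m = mask & (self.values != self.nodata) & np.isfinite(self.values)
        return float(self.values[m].sum())

    def copy(self) -> "Layer":
        return Layer(self.values.copy(), self.units, self.nodata)


def write_layer(layer: Layer, path, grid: PlanningGrid | None = None) -> None:
    """Write ``layer`` as a single-band float32 TIFF.

    Geotransform, units and the nodata sentinel are embedded as JSON in the
    ImageDescription tag so the round trip preserves them exactly.
    """
    meta = {"units": layer.units, "nodata": layer.nodata}
    if grid is not None:
        meta["geotransform"] = list(grid.geotransform)
        meta["cell_area_km2"] = grid.cell_area_km2
    tifffile.imwrite(
        str(path),
        layer.values.astype(np.float32),
        description=json.dumps(meta),
    )


def read_layer(path, grid: PlanningGrid | None = None) -> Layer:
    """Read a single-band TIFF back into a :class:`Layer`.

    When ``grid`` is given the layer is checked for shape and geotransform
    conformity and a :class:`ConformityError` is raised on mismatch.
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(np.float64)
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    layer = Layer(values, units=meta.get("units", ""), nodata=meta.get("nodata", NODATA))
    if grid is not None:
        if layer.shape != grid.shape:
            raise ConformityError(
                f"layer shape {layer.shape} != grid shape {grid.shape}"
            )
        gt = meta.get("geotransform")
        if gt is not None and tuple(gt) != tuple(grid.geotransform):
            raise ConformityError("geotransform mismatch with enclosing grid")
    return layer


def availability_mask(hm: Layer, grid: PlanningGrid, threshold: float = 0.8) -> Layer:
    """Binary layer of cells available to allocation.

    A cell is available iff it is land and its human-modification value does
    not exceed ``threshold`` (cells with HM strictly greater than 80% are
    dense existing development and are excluded).
    """
    hm.conform(grid)
    land = grid.land_mask
    vals = hm.values
    on_land = vals[land & (vals != hm.nodata)]
    if on_land.size and (on_land.min() < 0 or on_land.max() > 1):
        raise ValueError("human-modification values must lie in [0, 1] on land")
    avail = land & (vals != hm.nodata) & (vals <= threshold)
    return Layer(avail.astype(np.float64), units="binary")


@dataclass
class SparseAmounts:
    """Per-zone sparse cell x feature contribution matrices.

    Only available cells appear. ``matrices[zone]`` is an ``(n_cells,
    n_features)`` CSR matrix whose entry (i, j) is the amount of feature j
    held when cell ``cell_ids[i]`` is assigned to ``zone``; sector zones
    contribute only to their own sector's column.
    """

    cell_ids: np.ndarray
    feature_names: list
    zone_names: list
    matrices: dict

    def __post_init__(self):
        n = len(self.cell_ids)
        for z, m in self.matrices.items():
            if m.shape != (n, len(self.feature_names)):
                raise ConformityError(f"zone {z!r} matrix has wrong shape")
            if m.nnz and m.data.min() < 0:
                raise ValueError(f"zone {z!r} has negative amounts")

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def column_sum(self, zone: str, feature: str) -> float:
        j = self.feature_index(feature)
        return float(self.matrices[zone][:, j].sum())


def build_sparse(world, availability: Layer) -> SparseAmounts:
    """Convert a world's layers into sparse cell x feature matrices.

    Zones are ``conservation`` plus one zone per development sector. The
    conservation zone contributes each species' retained habitat area, carbon
    and every NCP layer; each sector zone contributes its potential yield to
    its own (single) sector feature.
    """
    avail = availability.values.astype(bool).ravel()
    cell_ids = np.flatnonzero(avail)
    feature_names = (
        [s.id for s in world.species]
        + [a.id for a in world.assets]
        + [sec.name for sec in world.sectors]
    )
    n, nf = len(cell_ids), len(feature_names)

    def col(layer: Layer) -> np.ndarray:
        v = layer.values.ravel()[cell_ids]
        v = np.where((v == layer.nodata) | ~np.isfinite(v), 0.0, v)
        if v.min() < 0:
            raise ValueError("negative amounts in feature layer")
        return v

    cols = {}
    for j, spf in enumerate(world.species):
        cols[j] = col(spf.retained)
    off = len(world.species)
    for j, a in enumerate(world.assets):
        cols[off + j] = col(a.layer)
    cons = sp.lil_matrix((n, nf))
    for j, v in cols.items():
        cons[:, j] = v.reshape(-1, 1)
    matrices = {"conservation": cons.tocsr()}

    off = len(world.species) + len(world.assets)
    for j, sec in enumerate(world.sectors):
        m = sp.lil_matrix((n, nf))
        m[:, off + j] = col(sec.yield_layer).reshape(-1, 1)
        matrices[sec.name] = m.tocsr()

    zone_names = ["conservation"] + [s.name for s in world.sectors]
    return SparseAmounts(cell_ids, feature_names, zone_names, matrices)
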