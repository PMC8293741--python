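"""Common analysis grid and raster/vector primitives.

Every downstream stage works on a single planar, equal-area grid
(:class:`GridSpec`) with cell-center registration, row-major from the
north-west corner.  Layers (:class:`RasterLayer`) are 2-D float arrays with
``NaN`` as the explicit missing value; any arithmetic with missing yields
missing unless an operation documents otherwise.

Rasters are persisted as ESRI ASCII grids (plain text, GDAL/QGIS readable);
vector features as GeoJSON handled through :mod:`shapely`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "RasterLayer",
    "PolygonSet",
    "resample_to_grid",
    "buffer_mask",
    "rasterize",
    "rasterize_lines",
    "apply_urban_mask",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geojson",
    "write_geojson",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular analysis grid in a projected equal-area CRS.

    ``origin_x``/``origin_y`` are the coordinates (m) of the north-west
    *corner* of the grid; rows run southwards.  ``cell_size`` defaults to the
    5-km analysis resolution; cell area is ``cell_size**2`` and is used for
    all km^2 reporting.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 5000.0
    crs_id: str = "local-equal-area"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def x_edges(self) -> np.ndarray:
        return self.origin_x + self.cell_size * np.arange(self.n_cols + 1)

    def y_edges(self) -> np.ndarray:
        """Northing of row boundaries, decreasing from the NW corner."""
        return self.origin_y - self.cell_size * np.arange(self.n_rows + 1)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) 2-D arrays of cell-center coordinates."""
        xs = self.origin_x + self.cell_size * (np.arange(self.n_cols) + 0.5)
        ys = self.origin_y - self.cell_size * (np.arange(self.n_rows) + 0.5)
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cell containing (x, y); may be out of range."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def center_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_x + self.cell_size * (np.asarray(col) + 0.5)
        y = self.origin_y - self.cell_size * (np.asarray(row) + 0.5)
        return x, y


@dataclass
class RasterLayer:
    """Single-band layer on a :class:`GridSpec`; NaN marks missing cells."""

    grid: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self, values: np.ndarray | None = None, name: str | None = None) -> "RasterLayer":
        return RasterLayer(
            self.grid,
            self.values.copy() if values is None else values,
            self.name if name is None else name,
        )

    def same_grid(self, other: "RasterLayer") -> bool:
        return self.grid == other.grid


def _require_same_grid(*layers: RasterLayer) -> None:
    g0 = layers[0].grid
    for lay in layers[1:]:
        if lay.grid != g0:
            raise ValueError(
                f"grid mismatch: {layers[0].name!r} vs {lay.name!r} "
                f"({g0.shape} vs {lay.grid.shape})"
            )


@dataclass
class PolygonSet:
    """Named polygon/multipolygon features in the grid CRS.

    Invalid geometries are repaired on construction (``make_valid``); ids must
    be unique.
    """

    features: list[tuple[str, BaseGeometry, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [fid for fid, _, _ in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("feature ids must be unique")
        repaired = []
        for fid, geom, attrs in self.features:
            if not geom.is_valid:
                geom = shapely.make_valid(geom)
            repaired.append((fid, geom, dict(attrs)))
        self.features = repaired

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def union(self) -> BaseGeometry:
        return shapely.union_all([g for _, g, _ in self.features])


# ---------------------------------------------------------------------------
# raster algebra primitives
# ---------------------------------------------------------------------------


def _overlap_matrix(src_edges: np.ndarray, tgt_edges: np.ndarray) -> np.ndarray:
    """1-D interval-overlap lengths between source and target cell edges.

    Returns an (n_tgt, n_src) matrix whose [i, j] entry is the length of the
    overlap between target interval i and source interval j.  Edges may be
    increasing (x) or decreasing (y).
    """
    s_lo = np.minimum(src_edges[:-1], src_edges[1:])
    s_hi = np.maximum(src_edges[:-1], src_edges[1:])
    t_lo = np.minimum(tgt_edges[:-1], tgt_edges[1:])
    t_hi = np.maximum(tgt_edges[:-1], tgt_edges[1:])
    lo = np.maximum(t_lo[:, None], s_lo[None, :])
    hi = np.minimum(t_hi[:, None], s_hi[None, :])
    return np.clip(hi - lo, 0.0, None)


def resample_to_grid(src: RasterLayer, target: GridSpec, method: str = "area_weighted_mean") -> RasterLayer:
    """Resample ``src`` onto ``target``.

    ``area_weighted_mean`` gives each target cell the overlap-area-weighted
    mean of the intersecting non-missing source cells (exact for axis-aligned
    rectangular cells in the shared planar CRS); a target cell with no
    overlapping non-missing source area becomes missing.  ``nearest`` copies
    the value of the source cell containing each target cell center.
    """
    if src.values.size == 0:
        raise ValueError("empty source raster")
    if method == "area_weighted_mean":
        w_row = _overlap_matrix(src.grid.y_edges(), target.y_edges())
        w_col = _overlap_matrix(src.grid.x_edges(), target.x_edges())
        vals = src.values
        valid = np.isfinite(vals)
        num = w_row @ np.where(valid, vals, 0.0) @ w_col.T
        den = w_row @ valid.astype(float) @ w_col.T
        with np.errstate(invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return RasterLayer(target, out, src.name)
    if method == "nearest":
        cx, cy = target.cell_centers()
        row, col = src.grid.cell_of(cx, cy)
        inside = (row >= 0) & (row < src.grid.n_rows) & (col >= 0) & (col < src.grid.n_cols)
        out = np.full(target.shape, np.nan)
        out[inside] = src.values[row[inside], col[inside]]
        return RasterLayer(target, out, src.name)
    raise ValueError(f"unknown resampling method {method!r}")


def buffer_mask(binary: RasterLayer, distance: float) -> RasterLayer:
    """Dilate the 1-set of a {0,1,missing} layer by a center-to-center radius.

    A cell becomes 1 iff its center lies within ``distance`` (Euclidean, in
    grid CRS units, inclusive) of the center of any 1-cell; other cells keep
    their original value.  ``distance=0`` returns the layer unchanged.
    """
    if distance < 0:
        raise ValueError("buffer distance must be non-negative")
    vals = binary.values
    finite = vals[np.isfinite(vals)]
    if not np.all(np.isin(finite, (0.0, 1.0))):
        raise ValueError("buffer_mask requires a binary {0,1,missing} layer")
    ones = vals == 1.0
    if distance == 0 or not ones.any():
        return binary.copy()
    cs = binary.grid.cell_size
    # exact center-to-center Euclidean distances on the lattice
    dist = ndimage.distance_transform_edt(~ones, sampling=(cs, cs))
    out = vals.copy()
    out[dist <= distance * (1.0 + 1e-12)] = 1.0
    return binary.copy(values=out)


def rasterize(polys: PolygonSet, grid: GridSpec, attribute: str | None = None) -> RasterLayer:
    """Burn polygons onto the grid by cell-center containment.

    With ``attribute=None`` the output is a 0/1 membership layer; otherwise
    each covered cell takes the named attribute of the containing polygon.
    Overlaps resolve last-listed-wins (logged).  Cells in no polygon are 0
    for membership and missing for attribute rasters.
    """
    cx, cy = grid.cell_centers()
    pts = shapely.points(cx.ravel(), cy.ravel())
    if attribute is None:
        out = np.zeros(grid.shape, dtype=float)
        fill = 1.0
    else:
        out = np.full(grid.shape, np.nan)
    covered = np.zeros(grid.shape, dtype=bool)
    for fid, geom, attrs in polys:
        if attribute is not None:
            if attribute not in attrs:
                raise KeyError(f"feature {fid!r} lacks attribute {attribute!r}")
            fill = float(attrs[attribute])
        member = shapely.covers(geom, pts).reshape(grid.shape)
        overlap = member & covered
        if overlap.any():
            logger.info("rasterize: %d cells re-assigned to later feature %r", int(overlap.sum()), fid)
        out[member] = fill
        covered |= member
    return RasterLayer(grid, out, name=attribute or "membership")


def rasterize_lines(lines: Sequence[BaseGeometry], grid: GridSpec) -> RasterLayer:
    """0/1 layer marking cells whose center lies within half a cell of a line."""
    cx, cy = grid.cell_centers()
    pts = shapely.points(cx.ravel(), cy.ravel())
    out = np.zeros(grid.shape, dtype=float)
    half = grid.cell_size / 2.0
    for line in lines:
        d = shapely.distance(pts, line).reshape(grid.shape)
        out[d <= half] = 1.0
    return RasterLayer(grid, out, name="lines")


def apply_urban_mask(layer: RasterLayer, urban: RasterLayer) -> RasterLayer:
    """Set cells with urban=1 to missing; urban areas carry no natural habitat."""
    _require_same_grid(layer, urban)
    uvals = urban.values
    finite = uvals[np.isfinite(uvals)]
    if not np.all(np.isin(finite, (0.0, 1.0))):
        raise ValueError("urban mask must be a {0,1} layer")
    out = layer.values.copy()
    out[uvals == 1.0] = np.nan
    return layer.copy(values=out)


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and GeoJSON
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    g = layer.grid
    vals = np.where(np.isfinite(layer.values), layer.values, _NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, crs_id: str = "local-equal-area", name: str | None = None) -> RasterLayer:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        crs_id=crs_id,
    )
    return RasterLayer(grid, vals, name=name or Path(path).stem)


def write_geojson(polys: PolygonSet, path: str | Path) -> None:
    import json

    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "id": fid,
                "properties": {"id": fid, **attrs},
                "geometry": geom_mapping(geom),
            }
            for fid, geom, attrs in polys
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> PolygonSet:
    import json

    fc = json.loads(Path(path).read_text())
    feats = []
    for i, feat in enumerate(fc["features"]):
        props = dict(feat.get("properties") or {})
        fid = str(feat.get("id", props.get("id", i)))
        props.pop("id", None)
        feats.append((fid, geom_shape(feat["geometry"]), props))
    return PolygonSet(feats)
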