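"""Planar raster grid container, raster/vector I/O, and rasterisation helpers.

All spatial layers in the package live on a shared planar metric grid: a 2-D
array whose row 0 is the northern edge, with square cells of ``cell_size``
metres and an ``origin`` at the top-left *corner* of the raster. Rasters are
persisted as single-band TIFF files carrying the grid metadata as JSON in the
ImageDescription tag; vector layers are persisted as GeoJSON feature
collections with planar coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping as _shp_mapping
from shapely.geometry import shape as _shp_shape
from shapely.geometry.base import BaseGeometry


class GridError(ValueError):
    """Raised for inconsistent grid geometry or metadata."""


@dataclass(frozen=True)
class RasterGrid:
    """A 2-D raster on a planar metric grid.

    Parameters
    ----------
    data
        2-D array; row 0 is the northern edge of the region.
    cell_size
        Cell edge length in metres (> 0).
    origin
        (x, y) of the top-left corner of the raster, metres.
    """

    data: np.ndarray
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise GridError(f"raster data must be 2-D, got shape {arr.shape}")
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    # -- geometry ----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        x0, y0 = self.origin
        return (x0, y0 - self.n_rows * self.cell_size, x0 + self.n_cols * self.cell_size, y0)

    def like(self, data: np.ndarray) -> "RasterGrid":
        """New raster with the same geometry and different data."""
        data = np.asarray(data)
        if data.shape != self.shape:
            raise GridError(f"shape {data.shape} does not match grid {self.shape}")
        return RasterGrid(data, self.cell_size, self.origin)

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def require_same_grid(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.same_grid(other):
            raise GridError(
                f"{what} grid mismatch: {self.shape}@{self.cell_size}m{self.origin}"
                f" vs {other.shape}@{other.cell_size}m{other.origin}"
            )

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int) -> tuple[Any, Any]:
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of all cell-center coordinates, shape = grid shape."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def contains_rowcol(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


# -- raster I/O ------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write a single-band TIFF with grid metadata in the description tag."""
    path = Path(path)
    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "crs": "planar-metres",
    }
    tifffile.imwrite(path, grid.data, description=json.dumps(meta))
    return path


def read_raster(path: str | Path) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise GridError(f"{path}: missing grid metadata in ImageDescription tag")
        meta = json.loads(desc.value)
    return RasterGrid(data, float(meta["cell_size"]), tuple(meta["origin"]))


# -- vector features and GeoJSON I/O ---------------------------------------

@dataclass
class Feature:
    """A vector feature: a shapely geometry plus a property mapping."""

    geometry: BaseGeometry
    properties: dict[str, Any] = field(default_factory=dict)


def write_geojson(features: Iterable[Feature], path: str | Path) -> Path:
    path = Path(path)
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": _shp_mapping(f.geometry),
                "properties": f.properties,
            }
            for f in features
        ],
    }
    path.write_text(json.dumps(fc))
    return path


def read_geojson(path: str | Path) -> list[Feature]:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise GridError(f"{path}: not a GeoJSON FeatureCollection")
    return [
        Feature(_shp_shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in fc["features"]
    ]


# -- rasterisation ---------------------------------------------------------

def _line_parts(geom: BaseGeometry) -> list[BaseGeometry]:
    if geom.geom_type == "LineString":
        return [geom]
    if geom.geom_type == "MultiLineString":
        return list(geom.geoms)
    raise GridError(f"expected (Multi)LineString, got {geom.geom_type}")


def rasterize_lines(
    grid: RasterGrid,
    geoms: Sequence[BaseGeometry],
    values: Sequence[float] | None = None,
    background: float = 0.0,
) -> np.ndarray:
    """Burn polylines into the grid.

    A cell is burned when its square intersects the polyline. Where several
    lines cross one cell the largest value wins (so e.g. the fastest road
    class takes precedence).
    """
    out = np.full(grid.shape, background, dtype=float)
    if values is None:
        values = [1.0] * len(geoms)
    cs = grid.cell_size
    x0, y0 = grid.origin
    order = np.argsort(np.asarray(values, dtype=float))  # burn high values last
    for gi in order:
        geom, value = geoms[gi], float(values[gi])
        for part in _line_parts(geom):
            xmin, ymin, xmax, ymax = part.bounds
            c0 = max(0, int(np.floor((xmin - x0) / cs)) - 1)
            c1 = min(grid.n_cols - 1, int(np.floor((xmax - x0) / cs)) + 1)
            r0 = max(0, int(np.floor((y0 - ymax) / cs)) - 1)
            r1 = min(grid.n_rows - 1, int(np.floor((y0 - ymin) / cs)) + 1)
            if c1 < c0 or r1 < r0:
                continue
            rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
            xc, yc = grid.cell_center(rows, cols)
            # cheap prefilter: the cell square can only intersect if the
            # center is within half a diagonal of the line
            near = shapely.dwithin(part, shapely.points(xc, yc), cs * 0.7072)
            rr, cc = rows[near], cols[near]
            if rr.size == 0:
                continue
            boxes = shapely.box(
                x0 + cc * cs, y0 - (rr + 1) * cs, x0 + (cc + 1) * cs, y0 - rr * cs
            )
            hit = shapely.intersects(part, boxes)
            sel = (rr[hit], cc[hit])
            out[sel] = np.where(out[sel] == background, value, np.maximum(out[sel], value))
    return out


def rasterize_polygons(
    grid: RasterGrid,
    geoms: Sequence[BaseGeometry],
    values: Sequence[float] | None = None,
    background: float = 0.0,
) -> np.ndarray:
    """Burn polygons into the grid by cell-center containment (later wins)."""
    out = np.full(grid.shape, background, dtype=float)
    if values is None:
        values = [1.0] * len(geoms)
    X, Y = grid.cell_centers()
    for geom, value in zip(geoms, values):
        mask = shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(grid.shape)
        out[mask] = float(value)
    return out
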