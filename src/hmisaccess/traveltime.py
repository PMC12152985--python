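"""Multimodal friction surface and least-cost travel-time accumulation.

The friction surface assigns each 100 m cell a traversal cost in seconds
per metre: land-cover walking speed moderated by the slope-dependent hiking
factor, overridden by mechanised road speed on road cells (roads bridge
water), with water cells otherwise impassable (infinite cost). Travel time
to the nearest source facility is the exact multi-source shortest path over
the 8-connected cell graph, with the step time between adjacent cells equal
to the step distance times the mean of the two cells' per-metre costs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .config import DEFAULT_BAND_BREAKS, ConfigError, SpeedConfig
from .grid import Feature, RasterGrid, rasterize_lines, rasterize_polygons

logger = logging.getLogger(__name__)


class NoSourceError(ValueError):
    """No usable source cell (all sources off-grid or unsnappable)."""


# ---------------------------------------------------------------------------
# Slope and the hiking factor
# ---------------------------------------------------------------------------

def slope_magnitude(dem: RasterGrid) -> np.ndarray:
    """Isotropic slope magnitude (rise/run) from DEM central differences."""
    d_row, d_col = np.gradient(dem.data.astype(float), dem.cell_size)
    return np.hypot(d_row, d_col)


def tobler_factor(slope: np.ndarray | float) -> np.ndarray | float:
    """Slope-dependent walking-speed factor, normalised to 1 on flat ground.

    Tobler's hiking function ``6 e^{-3.5 |s + 0.05|}`` km/h divided by its
    flat-ground value, so it scales a land-cover walking speed
    multiplicatively. Maximum ``e^{0.175}`` ≈ 1.19 on a gentle −5% descent;
    isotropic in slope magnitude.
    """
    return np.exp(-3.5 * np.abs(np.asarray(slope) + 0.05)) / np.exp(-3.5 * 0.05)


# ---------------------------------------------------------------------------
# Friction surface
# ---------------------------------------------------------------------------

def build_friction(
    landcover: RasterGrid,
    dem: RasterGrid,
    roads: list[Feature],
    water: list[Feature],
    cfg: SpeedConfig,
) -> RasterGrid:
    """Per-cell traversal cost in seconds per metre (+inf = impassable).

    Rasterisation priority: water < land cover < roads — a road crossing
    water is a bridge and keeps its road speed; water without a road is an
    obstacle when ``cfg.water_impassable``.
    """
    landcover.require_same_grid(dem, "dem")
    classes = np.unique(landcover.data)
    unknown = [int(c) for c in classes if int(c) not in cfg.walk_speed_kmh]
    if unknown:
        raise ConfigError(f"no walking speed configured for land-cover class(es) {unknown}")

    speed_kmh = np.zeros(landcover.shape, dtype=float)
    for cls, kmh in cfg.walk_speed_kmh.items():
        speed_kmh[landcover.data == cls] = kmh
    speed_kmh *= tobler_factor(slope_magnitude(dem))

    water_mask = np.zeros(landcover.shape, dtype=bool)
    if water and cfg.water_impassable:
        lines = [f.geometry for f in water if f.geometry.geom_type.endswith("LineString")]
        polys = [f.geometry for f in water if f.geometry.geom_type.endswith("Polygon")]
        if lines:
            water_mask |= rasterize_lines(landcover, lines) > 0
        if polys:
            water_mask |= rasterize_polygons(landcover, polys) > 0

    road_speed = np.zeros(landcover.shape, dtype=float)
    if roads:
        values = []
        for f in roads:
            cls = f.properties.get("speed_class")
            if cls not in cfg.road_speed_kmh:
                raise ConfigError(f"no speed configured for road class {cls!r}")
            values.append(cfg.road_speed_kmh[cls])
        road_speed = rasterize_lines(landcover, [f.geometry for f in roads], values)

    speed_kmh[water_mask] = 0.0
    on_road = road_speed > 0
    speed_kmh[on_road] = road_speed[on_road]  # mechanised travel, no slope adjustment

    with np.errstate(divide="ignore"):
        cost = np.where(speed_kmh > 0, 3600.0 / (speed_kmh * 1000.0), np.inf)
    return landcover.like(cost)


# ---------------------------------------------------------------------------
# Multi-source least-cost accumulation
# ---------------------------------------------------------------------------

def _snap_source(
    friction: RasterGrid, row: int, col: int, snap_radius_m: float
) -> tuple[int, int] | None:
    """Nearest finite-cost cell (by center distance) within the snap radius."""
    if np.isfinite(friction.data[row, col]):
        return row, col
    max_cells = int(np.ceil(snap_radius_m / friction.cell_size))
    best = None
    best_d2 = (snap_radius_m / friction.cell_size) ** 2
    for dr in range(-max_cells, max_cells + 1):
        for dc in range(-max_cells, max_cells + 1):
            r, c = row + dr, col + dc
            if not friction.contains_rowcol(r, c) or not np.isfinite(friction.data[r, c]):
                continue
            d2 = dr * dr + dc * dc
            if d2 <= best_d2 and (best is None or d2 < best_d2):
                best, best_d2 = (r, c), d2
    return best


def cumulative_travel_time(
    friction: RasterGrid,
    sources_xy: np.ndarray | list,
    snap_radius_m: float = 500.0,
) -> RasterGrid:
    """Minutes to the nearest source over the least-cost 8-connected path.

    ``sources_xy`` is an (n, 2) array of facility coordinates in metres.
    Sources on impassable cells are snapped to the nearest passable cell
    within ``snap_radius_m`` (dropped with a warning otherwise); sources
    off the grid are dropped with a warning. The accumulation is an exact
    multi-source Dijkstra; step time between adjacent cells a, b is
    ``d(a,b) · (cost_a + cost_b) / 2`` with d = cell_size orthogonally and
    cell_size·√2 diagonally.
    """
    xy = np.atleast_2d(np.asarray(sources_xy, dtype=float))
    if xy.size == 0 or xy.shape[1] != 2:
        raise NoSourceError("no source coordinates supplied")

    cells: set[tuple[int, int]] = set()
    n_dropped = 0
    for x, y in xy:
        row, col = friction.xy_to_rowcol(x, y)
        if not friction.contains_rowcol(row, col):
            n_dropped += 1
            continue
        snapped = _snap_source(friction, row, col, snap_radius_m)
        if snapped is None:
            n_dropped += 1
            continue
        cells.add(snapped)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} source(s) off-grid or unsnappable", stacklevel=2)
    if not cells:
        raise NoSourceError("no usable source cell after snapping")

    cost = friction.data
    finite = np.isfinite(cost)
    node_id = np.full(friction.shape, -1, dtype=np.int64)
    n_nodes = int(finite.sum())
    node_id[finite] = np.arange(n_nodes)

    rows_i, cols_i, weights = [], [], []
    cs = friction.cell_size
    R, C = np.nonzero(finite)
    # each undirected 8-neighbour edge once: east, south, south-east, south-west
    for dr, dc, dist in ((0, 1, cs), (1, 0, cs), (1, 1, cs * np.sqrt(2.0)), (1, -1, cs * np.sqrt(2.0))):
        r1, c1 = R + dr, C + dc
        ok = (r1 >= 0) & (r1 < friction.n_rows) & (c1 >= 0) & (c1 < friction.n_cols)
        r0, c0, r1, c1 = R[ok], C[ok], r1[ok], c1[ok]
        nb = finite[r1, c1]
        r0, c0, r1, c1 = r0[nb], c0[nb], r1[nb], c1[nb]
        rows_i.append(node_id[r0, c0])
        cols_i.append(node_id[r1, c1])
        weights.append(dist * (cost[r0, c0] + cost[r1, c1]) / 2.0)

    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n_nodes, n_nodes),
    ).tocsr()
    src_nodes = np.array(sorted(node_id[r, c] for r, c in cells))
    seconds = dijkstra(graph, directed=False, indices=src_nodes, min_only=True)

    minutes = np.full(friction.shape, np.inf)
    minutes[finite] = seconds / 60.0
    return friction.like(minutes)


# ---------------------------------------------------------------------------
# Bands and change
# ---------------------------------------------------------------------------

def band_classify(
    tt: RasterGrid, breaks: tuple[float, ...] = DEFAULT_BAND_BREAKS
) -> RasterGrid:
    """Classify minutes into travel-time bands 1..len(breaks)+1.

    Band edges are inclusive above: with the default breaks the bands are
    [0, 30], (30, 60], (60, 120], (120, ∞); unreachable (infinite) cells
    fall in the last band.
    """
    br = list(breaks)
    if br != sorted(set(br)) or len(br) == 0:
        raise ValueError(f"breaks must be strictly increasing, got {breaks}")
    bands = np.digitize(tt.data, br, right=True) + 1
    return tt.like(bands.astype(np.uint8))


@dataclass
class TravelTimeChange:
    """Signed travel-time difference with reachability-transition flags.

    ``change`` holds minutes (end − start); cells unreachable in either year
    are NaN in ``change`` and flagged in the masks instead of carrying
    signed infinities.
    """

    change: RasterGrid
    became_reachable: np.ndarray
    became_unreachable: np.ndarray
    unreachable_both: np.ndarray


def travel_time_change(tt_start: RasterGrid, tt_end: RasterGrid) -> TravelTimeChange:
    """Change surface ``tt_end − tt_start`` on a shared grid."""
    tt_start.require_same_grid(tt_end, "travel-time change")
    a, b = tt_start.data, tt_end.data
    fin_a, fin_b = np.isfinite(a), np.isfinite(b)
    with np.errstate(invalid="ignore"):
        change = np.where(fin_a & fin_b, b - a, np.nan)
    return TravelTimeChange(
        change=tt_start.like(change),
        became_reachable=~fin_a & fin_b,
        became_unreachable=fin_a & ~fin_b,
        unreachable_both=~fin_a & ~fin_b,
    )
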