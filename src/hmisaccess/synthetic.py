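"""Seeded generator of a synthetic study region and routine HMIS archive.

Emulates the inputs of the accessibility analysis — terrain, land cover, a
water barrier, a connected road network, a clustered gridded population,
rectangular districts, a facility registry with injected coordinate errors,
and seven years of facility/indicator service counts — together with
ground-truth labels (functional archetype per facility, coordinate-error
kind per facility) so downstream recovery can be tested exactly.

All generators are deterministic under ``RegionConfig.seed``; each layer
draws from its own independent random stream so switching one layer off
never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box
from shapely.geometry.base import BaseGeometry

from .config import (
    ARCHETYPES,
    INDICATORS,
    YEARS,
    ConfigError,
    RegionConfig,
    LANDCOVER_BUILTUP,
    LANDCOVER_DENSE_VEGETATION,
    LANDCOVER_OPEN,
)
from .grid import Feature, RasterGrid, write_geojson, write_raster
from .hmis_io import RegionData, REGION_FILES, resolve_point

# independent random streams per layer
_STREAM_TERRAIN = 1
_STREAM_ROADS = 2
_STREAM_POPULATION = 3
_STREAM_FACILITIES = 4
_STREAM_HISTORIES = 5

#: Service pools per facility type, ordered by the onboarding sequence
#: (immunisation first, then minor-illness care, then midwife services);
#: caesarean care is restricted to hospitals.
SERVICE_POOLS: dict[str, tuple[str, ...]] = {
    "CHPS": ("pentavalent1", "outpatient", "malaria", "antenatal", "birth"),
    "HealthCentre": ("pentavalent1", "outpatient", "malaria", "antenatal", "birth"),
    "Hospital": ("pentavalent1", "outpatient", "malaria", "antenatal", "birth", "caesarean"),
    "MaternityHome": ("antenatal", "birth"),
}

#: Mean yearly service volume per provided indicator, by facility type.
#: Ordered hospital >> health centre > CHPS > maternity home.
POISSON_MEANS: dict[str, float] = {
    "Hospital": 2000.0,
    "HealthCentre": 500.0,
    "CHPS": 120.0,
    "MaternityHome": 60.0,
}


def _rng(config: RegionConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Terrain, water, districts
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")


def generate_terrain(
    config: RegionConfig,
) -> tuple[RasterGrid, RasterGrid, list[Feature]]:
    """Generate (dem, landcover, water features) on the scenario grid.

    The DEM is a smoothed random field scaled to 0–300 m; land cover is a
    three-class legend (open, dense vegetation, built-up) from a second
    smoothed field; water is a river polyline crossing the region
    north–south plus a small lake, forming a connected travel barrier.
    """
    shape = (config.n_rows, config.n_cols)
    origin = (0.0, config.height)
    rng = _rng(config, _STREAM_TERRAIN)

    relief = _smooth_field(rng, shape, sigma=max(4.0, config.n_rows / 25))
    lo, hi = relief.min(), relief.max()
    dem_data = (relief - lo) / (hi - lo or 1.0) * 300.0
    dem = RasterGrid(dem_data, config.cell_size, origin)

    veg = _smooth_field(rng, shape, sigma=max(3.0, config.n_rows / 40))
    q30, q95 = np.quantile(veg, [0.30, 0.95])
    lc = np.full(shape, LANDCOVER_OPEN, dtype=np.int16)
    lc[veg < q30] = LANDCOVER_DENSE_VEGETATION
    lc[veg > q95] = LANDCOVER_BUILTUP
    landcover = RasterGrid(lc, config.cell_size, origin)

    water: list[Feature] = []
    if config.water:
        # a meandering river from the north to the south edge
        n_pts = 12
        ys = np.linspace(config.height, 0.0, n_pts)
        x_base = rng.uniform(0.25, 0.75) * config.width
        xs = x_base + np.cumsum(rng.normal(0.0, config.width * 0.03, n_pts))
        xs = np.clip(xs, config.cell_size, config.width - config.cell_size)
        river = LineString(np.column_stack([xs, ys]))
        water.append(Feature(river, {"kind": "river"}))
        # a lake off to one side
        cx = rng.uniform(0.1, 0.9) * config.width
        cy = rng.uniform(0.1, 0.9) * config.height
        r = config.cell_size * max(3.0, config.n_rows / 40)
        water.append(Feature(Point(cx, cy).buffer(r, quad_segs=8), {"kind": "lake"}))
    return dem, landcover, water


def generate_districts(config: RegionConfig) -> list[Feature]:
    """Rectangular districts that exactly partition the region."""
    nr, nc = config.n_districts
    xs = np.linspace(0.0, config.width, nc + 1)
    ys = np.linspace(0.0, config.height, nr + 1)
    feats = []
    for i in range(nr):
        for j in range(nc):
            geom = box(xs[j], ys[i], xs[j + 1], ys[i + 1])
            feats.append(Feature(geom, {"district_id": f"D{i * nc + j + 1:02d}"}))
    return feats


# ---------------------------------------------------------------------------
# Roads
# ---------------------------------------------------------------------------

def generate_roads(config: RegionConfig) -> list[Feature]:
    """A connected road network touching at least two region edges.

    One primary west–east trunk road plus secondary/tertiary branches from
    trunk points to the north and south edges. Independent of the facility
    layer.
    """
    rng = _rng(config, _STREAM_ROADS)
    w, h = config.width, config.height

    n_pts = 8
    xs = np.linspace(0.0, w, n_pts)
    y_base = rng.uniform(0.3, 0.7) * h
    ys = np.clip(y_base + np.cumsum(rng.normal(0, h * 0.03, n_pts)),
                 config.cell_size, h - config.cell_size)
    trunk_pts = np.column_stack([xs, ys])
    feats = [Feature(LineString(trunk_pts), {"road_id": "R1", "speed_class": "primary"})]

    # branches to the north and south edges from interior trunk vertices
    branch_classes = ["secondary", "tertiary"]
    for k, edge_y in enumerate((h, 0.0)):
        vi = rng.integers(1, n_pts - 1)
        x0, y0 = trunk_pts[vi]
        x1 = float(np.clip(x0 + rng.normal(0, w * 0.1), 0.0, w))
        mid = ((x0 + x1) / 2 + rng.normal(0, w * 0.02), (y0 + edge_y) / 2)
        feats.append(
            Feature(
                LineString([(x0, y0), mid, (x1, edge_y)]),
                {"road_id": f"R{k + 2}", "speed_class": branch_classes[k]},
            )
        )
    return feats


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def generate_population(config: RegionConfig) -> RasterGrid:
    """Baseline-year gridded population: clustered around a handful of
    town centres over a light uniform background, summing to
    ``total_population`` exactly (up to float round-off)."""
    rng = _rng(config, _STREAM_POPULATION)
    shape = (config.n_rows, config.n_cols)
    rows, cols = np.mgrid[0 : config.n_rows, 0 : config.n_cols]

    density = np.full(shape, 0.05)
    sigma_cells = max(3.0, config.n_rows / 15)
    for _ in range(config.n_population_centres):
        cr = rng.uniform(0, config.n_rows)
        cc = rng.uniform(0, config.n_cols)
        weight = rng.uniform(0.5, 2.0)
        density += weight * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma_cells**2))
    pop = density / density.sum() * config.total_population
    return RasterGrid(pop, config.cell_size, (0.0, config.height))


# ---------------------------------------------------------------------------
# Facilities
# ---------------------------------------------------------------------------

def _apply_corruption(
    kind: str, ordinate: int, x: float, y: float
) -> tuple[float, float]:
    if kind == "swapped":
        return y, x
    if kind == "decimal_shift":
        return (x * 10.0, y) if ordinate == 0 else (x, y * 10.0)
    raise ConfigError(f"unknown corruption kind {kind!r}")


def generate_facilities(
    config: RegionConfig, districts: list[Feature]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the facility registry and coordinate-error ground truth.

    Each facility receives true coordinates strictly inside one district; a
    ``coord_error_rate`` fraction (rounded) get corrupted *published*
    coordinates — ordinate swap or a ×10 decimal shift of one ordinate. The
    generator verifies against the QA candidate order that every injected
    corruption is detectable and uniquely repairable to the true
    coordinates, re-drawing the corruption kind otherwise, so repair
    round-trips are exact by construction.
    """
    if not districts:
        raise ConfigError("empty district set")
    rng = _rng(config, _STREAM_FACILITIES)
    n = config.n_facilities

    types = rng.choice(list(config.type_mix), size=n, p=list(config.type_mix.values()))
    owners = rng.choice(
        list(config.ownership_mix), size=n, p=list(config.ownership_mix.values())
    )

    dist_geoms = [f.geometry for f in districts]
    dist_ids = [f.properties["district_id"] for f in districts]

    xs = np.empty(n)
    ys = np.empty(n)
    district_of = []
    for i in range(n):
        while True:
            x = rng.uniform(0.0, config.width)
            y = rng.uniform(0.0, config.height)
            hit = next(
                (k for k, g in enumerate(dist_geoms) if g.contains(Point(x, y))), None
            )
            if hit is not None:
                xs[i], ys[i] = x, y
                district_of.append(dist_ids[hit])
                break

    n_corrupt = int(round(config.coord_error_rate * n))
    error_kind = np.array(["none"] * n, dtype=object)
    pub_x, pub_y = xs.copy(), ys.copy()
    candidates = rng.permutation(n)
    corrupted = 0
    for i in candidates:
        if corrupted >= n_corrupt:
            break
        geom = dist_geoms[dist_ids.index(district_of[i])]
        options = [("swapped", 0), ("decimal_shift", 0), ("decimal_shift", 1)]
        rng.shuffle(options)
        for kind, ordinate in options:
            cx, cy = _apply_corruption(kind, ordinate, xs[i], ys[i])
            status, fx, fy = resolve_point(cx, cy, geom, tolerance=0.0)
            if status.startswith("repaired_") and abs(fx - xs[i]) < 1e-9 and abs(fy - ys[i]) < 1e-9:
                pub_x[i], pub_y[i] = cx, cy
                error_kind[i] = kind
                corrupted += 1
                break
    if corrupted < n_corrupt:
        raise ConfigError(
            f"could only inject {corrupted}/{n_corrupt} recoverable coordinate errors"
        )

    ids = [f"F{i + 1:04d}" for i in range(n)]
    registry = pd.DataFrame(
        {
            "facility_id": ids,
            "name": [f"Synthetic {t} {i + 1}" for i, t in enumerate(types)],
            "type": types,
            "ownership": owners,
            "district_id": district_of,
            "x": pub_x,
            "y": pub_y,
        }
    )
    truth = pd.DataFrame(
        {
            "facility_id": ids,
            "coord_error": error_kind,
            "x_true": xs,
            "y_true": ys,
        }
    )
    return registry, truth


# ---------------------------------------------------------------------------
# Service histories
# ---------------------------------------------------------------------------

def _prefix_sizes(
    rng: np.random.Generator, archetype: str, pool_size: int, k_lo: int = 1
) -> list[int]:
    """Yearly onboarding-prefix size (0 = not operational) per study year.

    ``k_lo`` floors the base prefix draw for steady archetypes; hospitals
    use a floor near the full pool since they offer most of the service
    range, including surgery.
    """
    n_years = len(YEARS)
    if archetype == "no_service":
        return [0] * n_years
    if archetype == "closed":
        k = int(rng.integers(k_lo, pool_size + 1))
        t_close = int(rng.integers(1, n_years))  # index of first all-zero year
        return [k if t < t_close else 0 for t in range(n_years)]
    if archetype == "newly_operational":
        t_start = int(rng.integers(1, n_years))
        sizes = [0] * n_years
        k = 1
        for t in range(t_start, n_years):
            sizes[t] = k
            k = min(pool_size, k + int(rng.integers(0, 2)))
        return sizes
    if archetype == "oscillating":
        k = int(rng.integers(k_lo, pool_size + 1))
        middle = np.arange(1, n_years - 1)
        on = rng.choice(middle, size=int(rng.integers(1, len(middle) + 1)), replace=False)
        return [k if t in set(on.tolist()) else 0 for t in range(n_years)]
    if archetype == "existing_unchanged":
        k = int(rng.integers(k_lo, pool_size + 1))
        return [k] * n_years
    if archetype == "existing_increased":
        k16 = int(rng.integers(1, pool_size))
        k22 = int(rng.integers(k16 + 1, pool_size + 1))
        middle = np.sort(rng.integers(k16, k22 + 1, size=n_years - 2))
        return [k16, *middle.tolist(), k22]
    if archetype == "existing_decreased":
        k22 = int(rng.integers(1, pool_size))
        k16 = int(rng.integers(k22 + 1, pool_size + 1))
        middle = np.sort(rng.integers(k22, k16 + 1, size=n_years - 2))[::-1]
        return [k16, *middle.tolist(), k22]
    if archetype == "existing_varying":
        k = int(rng.integers(k_lo, pool_size + 1))
        sizes = [k] * n_years
        t_mid = int(rng.integers(1, n_years - 1))
        sizes[t_mid] = k + 1 if k < pool_size else k - 1
        return sizes
    raise ConfigError(f"unknown archetype {archetype!r}")


def generate_service_histories(
    registry: pd.DataFrame, config: RegionConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the 2016–2022 service-record table and archetype truth.

    Each facility is assigned a functional archetype from
    ``config.archetype_mix``; its yearly indicator-presence pattern follows
    the archetype exactly (over its type's service pool, in onboarding
    order), and counts for provided services are Poisson with a
    type-dependent mean, truncated to ≥ 1.
    """
    if len(registry) == 0:
        raise ConfigError("registry is empty")
    unknown = set(config.archetype_mix) - set(ARCHETYPES)
    if unknown:
        raise ConfigError(f"unknown archetype(s) {sorted(unknown)}")
    rng = _rng(config, _STREAM_HISTORIES)

    labels = rng.choice(
        list(config.archetype_mix),
        size=len(registry),
        p=list(config.archetype_mix.values()),
    )

    rows: list[tuple[str, int, str, int]] = []
    for (rec, archetype) in zip(registry.itertuples(index=False), labels):
        pool = SERVICE_POOLS[rec.type]
        mean = POISSON_MEANS[rec.type]
        k_lo = max(1, len(pool) - 1) if rec.type == "Hospital" else 1
        sizes = _prefix_sizes(rng, archetype, len(pool), k_lo=k_lo)
        for year, k in zip(YEARS, sizes):
            for indicator in pool[:k]:
                count = max(1, int(rng.poisson(mean)))
                rows.append((rec.facility_id, year, indicator, count))

    records = pd.DataFrame(rows, columns=["facility_id", "year", "indicator", "count"])
    truth = pd.DataFrame(
        {"facility_id": registry["facility_id"].to_numpy(), "archetype": labels}
    )
    return records, truth


# ---------------------------------------------------------------------------
# Scenario bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticRegion(RegionData):
    """A generated region bundle plus its scenario and ground truth."""

    config: RegionConfig = None  # type: ignore[assignment]
    ground_truth: pd.DataFrame = None  # type: ignore[assignment]


def generate_region(config: RegionConfig) -> SyntheticRegion:
    """Run every generator and assemble the full synthetic scenario."""
    dem, landcover, water = generate_terrain(config)
    districts = generate_districts(config)
    roads = generate_roads(config)
    population = generate_population(config)
    registry, coord_truth = generate_facilities(config, districts)
    records, arch_truth = generate_service_histories(registry, config)
    truth = coord_truth.merge(arch_truth, on="facility_id")
    return SyntheticRegion(
        dem=dem,
        landcover=landcover,
        population=population,
        roads=roads,
        water=water,
        districts={f.properties["district_id"]: f.geometry for f in districts},
        registry=registry,
        records=records,
        config=config,
        ground_truth=truth,
    )


def write_scenario(region: SyntheticRegion, out_dir: str | Path) -> Path:
    """Persist a synthetic scenario as the canonical region file set plus
    ground truth and the scenario YAML."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_raster(region.dem, d / REGION_FILES["dem"])
    write_raster(region.landcover, d / REGION_FILES["landcover"])
    write_raster(region.population, d / REGION_FILES["population"])
    write_geojson(region.roads, d / REGION_FILES["roads"])
    write_geojson(region.water, d / REGION_FILES["water"])
    write_geojson(region.district_features, d / REGION_FILES["districts"])
    region.registry.to_csv(d / REGION_FILES["registry"], index=False)
    region.records.to_csv(d / REGION_FILES["records"], index=False)
    region.ground_truth.to_csv(d / "ground_truth.csv", index=False)
    cfg = region.config
    scenario = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()}
    (d / "scenario.yaml").write_text(yaml.safe_dump(scenario, sort_keys=True))
    return d
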