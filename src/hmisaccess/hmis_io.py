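"""Reading, validation and QA of HMIS tables and geospatial layers.

The service-record and facility-registry CSV schemas follow the long-format
extracts a DHIS2-style routine system produces after yearly aggregation.
Facility coordinates from such registries contain recognisable error kinds —
transposed ordinates and misplaced decimal points — which
:func:`qa_locations` detects against district polygons and repairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .config import FACILITY_TYPES, INDICATORS, OWNERSHIPS, YEARS
from .grid import Feature, RasterGrid, read_geojson, read_raster

logger = logging.getLogger(__name__)

REGISTRY_COLUMNS = ("facility_id", "name", "type", "ownership", "district_id", "x", "y")
RECORD_COLUMNS = ("facility_id", "year", "indicator", "count")

QA_STATUSES = ("ok", "repaired_swap", "repaired_decimal", "boundary_tolerated", "unresolved")


class DataError(ValueError):
    """Base class for input-data problems."""


class SchemaError(DataError):
    """A required column is missing or mistyped."""


class ValidationError(DataError):
    """A cell value violates the schema contract."""


class UnknownReferenceError(DataError):
    """A foreign key (facility or district id) has no referent."""


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_service_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format facility/year/indicator count table.

    Duplicate (facility_id, year, indicator) rows are summed; rows for years
    outside the study span are dropped with a logged count; unknown
    indicators or negative counts raise.
    """
    df = pd.read_csv(path, dtype={"facility_id": str})
    _require_columns(df, RECORD_COLUMNS, "service records")
    df = df.loc[:, list(RECORD_COLUMNS)].copy()
    if len(df) == 0:
        return df.astype({"year": int, "count": int})

    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    df["count"] = pd.to_numeric(df["count"], errors="raise")
    negative = df.index[df["count"] < 0]
    if len(negative):
        row = df.loc[negative[0]]
        raise ValidationError(
            f"negative count {row['count']} for facility {row['facility_id']}, "
            f"year {row['year']}, indicator {row['indicator']} (row {negative[0]})"
        )
    df["count"] = df["count"].astype(int)

    unknown = sorted(set(df["indicator"]) - set(INDICATORS))
    if unknown:
        raise ValidationError(f"unknown indicator(s) {unknown}; expected one of {list(INDICATORS)}")

    in_span = df["year"].isin(YEARS)
    if (~in_span).any():
        logger.warning("dropping %d record row(s) outside years %d-%d",
                       int((~in_span).sum()), YEARS[0], YEARS[-1])
        df = df[in_span]

    df = (
        df.groupby(["facility_id", "year", "indicator"], as_index=False)["count"]
        .sum()
        .sort_values(["facility_id", "year", "indicator"], ignore_index=True)
    )
    return df


def read_facility_registry(path: str | Path) -> pd.DataFrame:
    """Read and validate the facility registry CSV."""
    df = pd.read_csv(path, dtype={"facility_id": str, "district_id": str})
    _require_columns(df, REGISTRY_COLUMNS, "facility registry")
    df = df.loc[:, list(REGISTRY_COLUMNS)].copy()

    dup = df["facility_id"][df["facility_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate facility_id(s): {sorted(set(dup))}")
    bad_type = sorted(set(df["type"]) - set(FACILITY_TYPES))
    if bad_type:
        raise ValidationError(f"unknown facility type(s) {bad_type}; expected {list(FACILITY_TYPES)}")
    bad_own = sorted(set(df["ownership"]) - set(OWNERSHIPS))
    if bad_own:
        raise ValidationError(f"unknown ownership value(s) {bad_own}; expected {list(OWNERSHIPS)}")
    df["x"] = pd.to_numeric(df["x"], errors="raise").astype(float)
    df["y"] = pd.to_numeric(df["y"], errors="raise").astype(float)
    return df.reset_index(drop=True)


def read_districts(path: str | Path) -> dict[str, BaseGeometry]:
    """Read district polygons keyed by their ``district_id`` property."""
    out: dict[str, BaseGeometry] = {}
    for feat in read_geojson(path):
        did = feat.properties.get("district_id")
        if did is None:
            raise SchemaError(f"{path}: district feature without a district_id property")
        out[str(did)] = feat.geometry
    if not out:
        raise ValidationError(f"{path}: empty district set")
    return out


# ---------------------------------------------------------------------------
# Coordinate QA
# ---------------------------------------------------------------------------

#: Decimal-shift repair candidates: scale factors applied to (x, y).
#: Division by ten is tried before multiplication, single ordinates before
#: joint shifts; the first candidate landing inside the district wins.
DECIMAL_CANDIDATE_FACTORS: tuple[tuple[float, float], ...] = (
    (0.1, 1.0), (1.0, 0.1), (0.1, 0.1),
    (10.0, 1.0), (1.0, 10.0), (10.0, 10.0),
)


def resolve_point(
    x: float, y: float, district: BaseGeometry, tolerance: float
) -> tuple[str, float, float]:
    """Resolve one published coordinate pair against its district polygon.

    Returns (status, final_x, final_y). Candidate order: as-is, ordinate
    swap, decimal shifts, then boundary tolerance; facilities still outside
    are flagged unresolved with coordinates unchanged.
    """
    if district.covers(Point(x, y)):
        return "ok", x, y
    if district.covers(Point(y, x)):
        return "repaired_swap", y, x
    for fx, fy in DECIMAL_CANDIDATE_FACTORS:
        cx, cy = x * fx, y * fy
        if district.covers(Point(cx, cy)):
            return "repaired_decimal", cx, cy
    if district.distance(Point(x, y)) <= tolerance:
        return "boundary_tolerated", x, y
    return "unresolved", x, y


def qa_locations(
    registry: pd.DataFrame,
    districts: dict[str, BaseGeometry],
    tolerance: float = 2000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QA facility coordinates against their districts; repair where possible.

    Returns ``(qa_report, corrected_registry)``. The corrected registry keeps
    every facility (unresolved ones retain their published coordinates; they
    are excluded from travel-time sourcing downstream, not from the registry).
    """
    missing = sorted(set(registry["district_id"]) - set(districts))
    if missing:
        raise UnknownReferenceError(f"district_id(s) not in district layer: {missing}")

    rows = []
    finals_x, finals_y = [], []
    for rec in registry.itertuples(index=False):
        status, fx, fy = resolve_point(rec.x, rec.y, districts[rec.district_id], tolerance)
        rows.append(
            {
                "facility_id": rec.facility_id,
                "status": status,
                "x_original": rec.x,
                "y_original": rec.y,
                "x_final": fx,
                "y_final": fy,
            }
        )
        finals_x.append(fx)
        finals_y.append(fy)

    qa = pd.DataFrame(rows)
    n_unres = int((qa["status"] == "unresolved").sum())
    if n_unres:
        logger.warning(
            "%d facility location(s) unresolved; excluded from travel-time sourcing", n_unres
        )
    corrected = registry.copy()
    corrected["x"] = finals_x
    corrected["y"] = finals_y
    return qa, corrected


# ---------------------------------------------------------------------------
# Region bundle
# ---------------------------------------------------------------------------

@dataclass
class RegionData:
    """All input layers and tables for one study region."""

    dem: RasterGrid
    landcover: RasterGrid
    population: RasterGrid  # baseline-year gridded population
    roads: list[Feature]
    water: list[Feature]
    districts: dict[str, BaseGeometry]
    registry: pd.DataFrame
    records: pd.DataFrame

    @property
    def district_features(self) -> list[Feature]:
        return [Feature(geom, {"district_id": did}) for did, geom in self.districts.items()]


#: Canonical file names inside a region input/scenario directory.
REGION_FILES = {
    "dem": "dem.tif",
    "landcover": "landcover.tif",
    "population": "population_baseline.tif",
    "roads": "roads.geojson",
    "water": "water.geojson",
    "districts": "districts.geojson",
    "registry": "facility_registry.csv",
    "records": "service_records.csv",
}


def load_region(directory: str | Path) -> RegionData:
    """Load a directory of region layers written by the synthetic generator
    or prepared from real data (see :data:`REGION_FILES` for file names)."""
    d = Path(directory)
    for key, fname in REGION_FILES.items():
        if not (d / fname).exists():
            raise DataError(f"region directory {d} is missing {fname} ({key})")
    return RegionData(
        dem=read_raster(d / REGION_FILES["dem"]),
        landcover=read_raster(d / REGION_FILES["landcover"]),
        population=read_raster(d / REGION_FILES["population"]),
        roads=read_geojson(d / REGION_FILES["roads"]),
        water=read_geojson(d / REGION_FILES["water"]),
        districts=read_districts(d / REGION_FILES["districts"]),
        registry=read_facility_registry(d / REGION_FILES["registry"]),
        records=read_service_records(d / REGION_FILES["records"]),
    )
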