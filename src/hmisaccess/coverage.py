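"""Population coverage by travel-time band, per service and year.

Combines the travel-time band rasters with the projected sub-group
population rasters: each service indicator is mapped to its target
sub-group (general population for outpatient and malaria care, women of
childbearing age for antenatal/birth/caesarean care, children under five
for first-dose pentavalent vaccination), the sub-group population is
summed per band, and percentages are taken of the sub-group regional
total.
"""

from __future__ import annotations

import logging
import warnings

import matplotlib
import numpy as np
import pandas as pd
import xarray as xr

from .config import (
    DEFAULT_BAND_BREAKS,
    ELIGIBLE_TYPES,
    INDICATORS,
    SERVICE_SUBGROUP,
    ProjectionConfig,
    SpeedConfig,
)
from .grid import GridError, RasterGrid
from .hmis_io import RegionData
from .projection import project_population, subgroup_raster
from .traveltime import NoSourceError, band_classify, build_friction, cumulative_travel_time

logger = logging.getLogger(__name__)


def coverage_by_band(
    bands: RasterGrid,
    population: RasterGrid,
    n_bands: int | None = None,
    indicator: str | None = None,
    year: int | None = None,
) -> pd.DataFrame:
    """Population and percent of the sub-group total per travel-time band.

    Band sums conserve the regional total exactly (a partition of the
    cells); a zero-population region yields NaN percents with a warning.
    """
    bands.require_same_grid(population, "coverage")
    band_vals = bands.data.astype(np.int64)
    if band_vals.min() < 1:
        raise GridError("band raster must contain bands numbered from 1")
    n_bands = n_bands or int(band_vals.max())
    sums = np.bincount(
        band_vals.ravel(), weights=population.data.ravel(), minlength=n_bands + 1
    )[1 : n_bands + 1]
    total = float(population.data.sum())
    if total <= 0:
        warnings.warn("zero total population; coverage percents undefined", stacklevel=2)
        pct = np.full(n_bands, np.nan)
    else:
        pct = 100.0 * sums / total
    df = pd.DataFrame(
        {"band": np.arange(1, n_bands + 1), "population": sums, "percent": pct}
    )
    if indicator is not None:
        df.insert(0, "indicator", indicator)
    if year is not None:
        df.insert(1 if indicator is not None else 0, "year", year)
    return df


def providing_sources(
    cube: xr.DataArray,
    registry: pd.DataFrame,
    indicator: str,
    year: int,
    qa: pd.DataFrame | None = None,
) -> np.ndarray:
    """(n, 2) coordinates of facilities providing ``indicator`` in ``year``.

    Applies the service's facility-type eligibility filter and excludes
    facilities whose coordinates the QA step left unresolved.
    """
    provided = cube.sel(year=year, indicator=indicator)
    ids = [str(f) for f, v in zip(cube.coords["facility"].values, provided.values) if v]
    reg = registry[registry["facility_id"].isin(ids)]
    eligible = ELIGIBLE_TYPES.get(indicator)
    if eligible is not None:
        reg = reg[reg["type"].isin(eligible)]
    if qa is not None:
        unresolved = set(qa.loc[qa["status"] == "unresolved", "facility_id"])
        reg = reg[~reg["facility_id"].isin(unresolved)]
    return reg[["x", "y"]].to_numpy(dtype=float)


def coverage_trend(
    cube: xr.DataArray,
    registry: pd.DataFrame,
    region: RegionData,
    speed_cfg: SpeedConfig,
    proj_cfg: ProjectionConfig,
    years: tuple[int, ...] = (2016, 2022),
    indicators: tuple[str, ...] = INDICATORS,
    breaks: tuple[float, ...] = DEFAULT_BAND_BREAKS,
    qa: pd.DataFrame | None = None,
    snap_radius_m: float = 500.0,
    return_surfaces: bool = False,
):
    """Assemble the long coverage table over (indicator, year, band).

    For every indicator and year: sources are the facilities providing that
    service that year (hospitals only for caesarean care), a travel-time
    surface is accumulated over the region's friction surface, classified
    into bands, and the year's projected sub-group population is summed per
    band. Indicator-years with no usable source are logged and skipped.
    """
    friction = build_friction(region.landcover, region.dem, region.roads, region.water, speed_cfg)
    frames = []
    surfaces: dict[tuple[str, int], RasterGrid] = {}
    for year in years:
        pop_total = project_population(region.population, proj_cfg, year)
        pops = {
            sg: subgroup_raster(pop_total, proj_cfg, year, sg)
            for sg in sorted({SERVICE_SUBGROUP[i] for i in indicators})
        }
        for indicator in indicators:
            xy = providing_sources(cube, registry, indicator, year, qa=qa)
            if len(xy) == 0:
                logger.warning("no providing facility for %s in %d; skipped", indicator, year)
                continue
            try:
                tt = cumulative_travel_time(friction, xy, snap_radius_m=snap_radius_m)
            except NoSourceError as exc:
                logger.warning("travel time failed for %s in %d: %s", indicator, year, exc)
                continue
            bands = band_classify(tt, breaks)
            frames.append(
                coverage_by_band(
                    bands,
                    pops[SERVICE_SUBGROUP[indicator]],
                    n_bands=len(breaks) + 1,
                    indicator=indicator,
                    year=year,
                )
            )
            if return_surfaces:
                surfaces[(indicator, year)] = tt
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["indicator", "year", "band", "population", "percent"])
    )
    if return_surfaces:
        return table, surfaces
    return table


def coverage_change(
    table: pd.DataFrame, start_year: int = 2016, end_year: int = 2022
) -> pd.DataFrame:
    """Per (indicator, band) change in coverage percent between two years."""
    wide = table.pivot_table(index=["indicator", "band"], columns="year", values="percent")
    missing = [y for y in (start_year, end_year) if y not in wide.columns]
    if missing:
        raise ValueError(f"coverage table has no rows for year(s) {missing}")
    out = wide[[start_year, end_year]].reset_index()
    out.columns = ["indicator", "band", f"percent_{start_year}", f"percent_{end_year}"]
    out["change"] = out[f"percent_{end_year}"] - out[f"percent_{start_year}"]
    return out


def plot_coverage_trend(table: pd.DataFrame, path, band: int = 1) -> None:
    """Line plot of within-band coverage percent per indicator over years."""
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    sub = table[table["band"] == band]
    for indicator, grp in sub.groupby("indicator"):
        grp = grp.sort_values("year")
        ax.plot(grp["year"], grp["percent"], marker="o", label=indicator)
    ax.set_xlabel("year")
    ax.set_ylabel(f"% of target sub-group in band {band}")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
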