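"""Gridded population projection and sub-group extraction.

The baseline-year population raster is carried to other study years by
annual geometric growth: forward, each year multiplies by (1 + r_y/100);
backward, each year divides by the same factor, so a round trip is the
identity. Growth is spatially uniform, preserving the spatial pattern and
the rank order of cells exactly. Sub-group rasters (women of childbearing
age, children under five) are the projected total multiplied by the
year's census-derived proportion, applied spatially uniformly.
"""

from __future__ import annotations

from .config import YEARS, ConfigError, ProjectionConfig
from .grid import RasterGrid


def growth_factor(cfg: ProjectionConfig, target_year: int) -> float:
    """Cumulative multiplier from the baseline year to ``target_year``."""
    factor = 1.0
    if target_year > cfg.baseline_year:
        for y in range(cfg.baseline_year + 1, target_year + 1):
            factor *= 1.0 + cfg.rate_for(y) / 100.0
    else:
        for y in range(target_year + 1, cfg.baseline_year + 1):
            factor /= 1.0 + cfg.rate_for(y) / 100.0
    return factor


def project_population(
    baseline: RasterGrid, cfg: ProjectionConfig, target_year: int
) -> RasterGrid:
    """Project the baseline raster to ``target_year`` (within the study span)."""
    if target_year not in YEARS and target_year != cfg.baseline_year:
        raise ConfigError(
            f"target_year {target_year} outside study span {YEARS[0]}-{YEARS[-1]}"
        )
    return baseline.like(baseline.data * growth_factor(cfg, target_year))


def subgroup_raster(
    population: RasterGrid, cfg: ProjectionConfig, year: int, subgroup: str
) -> RasterGrid:
    """Sub-group population raster for ``year`` (``total`` is the identity)."""
    p = cfg.proportion_for(year, subgroup)
    if subgroup == "total":
        return population.like(population.data.copy())
    return population.like(population.data * p)
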