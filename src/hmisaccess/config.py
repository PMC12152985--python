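"""Configuration objects and shared vocabulary for the analysis pipeline.

The vocabulary (service indicators, facility types, ownership categories,
functional-class labels, study years) is fixed here and shared by every
module. Configuration dataclasses validate on construction and round-trip
through YAML for the command-line interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

# ---------------------------------------------------------------------------
# Study vocabulary
# ---------------------------------------------------------------------------

#: The seven study years of the facility service archive.
YEARS: tuple[int, ...] = tuple(range(2016, 2023))

#: The six routine service indicators analysed, in onboarding order:
#: immunisation outreach arrives first in a new facility, then minor-illness
#: care (outpatient + malaria), then midwife-led antenatal and birthing care,
#: and caesarean surgery only in hospitals.
INDICATORS: tuple[str, ...] = (
    "pentavalent1",
    "outpatient",
    "malaria",
    "antenatal",
    "birth",
    "caesarean",
)

FACILITY_TYPES: tuple[str, ...] = ("CHPS", "HealthCentre", "Hospital", "MaternityHome")
OWNERSHIPS: tuple[str, ...] = ("Government", "FaithBased", "Private")

#: Indicators only meaningful for a subset of facility types: caesarean
#: sections require hospital surgical capacity, so hospitals alone enter
#: both the numerator and the denominator of caesarean provision rates.
ELIGIBLE_TYPES: dict[str, tuple[str, ...]] = {"caesarean": ("Hospital",)}

#: Functional service-provision classes.  The residual ``other_intermittent``
#: (operational at both endpoints but with a gap year between) keeps the
#: classifier total.
FUNCTIONAL_CLASSES: tuple[str, ...] = (
    "closed",
    "newly_operational",
    "no_service",
    "oscillating",
    "existing_unchanged",
    "existing_increased",
    "existing_decreased",
    "existing_varying",
    "other_intermittent",
)

#: Archetypes the synthetic generator can assign (the classifiable subset).
ARCHETYPES: tuple[str, ...] = (
    "closed",
    "newly_operational",
    "no_service",
    "oscillating",
    "existing_unchanged",
    "existing_increased",
    "existing_decreased",
    "existing_varying",
)

#: Land-cover legend for the synthetic region and the friction model.
LANDCOVER_OPEN = 1
LANDCOVER_DENSE_VEGETATION = 2
LANDCOVER_BUILTUP = 3
LANDCOVER_CLASSES: tuple[int, ...] = (
    LANDCOVER_OPEN,
    LANDCOVER_DENSE_VEGETATION,
    LANDCOVER_BUILTUP,
)

#: Target population sub-group for each service indicator.
SERVICE_SUBGROUP: dict[str, str] = {
    "outpatient": "total",
    "malaria": "total",
    "antenatal": "wocba",
    "birth": "wocba",
    "caesarean": "wocba",
    "pentavalent1": "under5",
}

SUBGROUPS: tuple[str, ...] = ("total", "wocba", "under5")

#: Travel-time band edges in minutes; bands are [0,30], (30,60], (60,120], (120,inf).
DEFAULT_BAND_BREAKS: tuple[float, ...] = (30.0, 60.0, 120.0)


class ConfigError(ValueError):
    """Raised when a configuration object fails validation."""


def _check_prob_vector(name: str, mix: Mapping[str, float], keys: tuple[str, ...]) -> None:
    unknown = set(mix) - set(keys)
    if unknown:
        raise ConfigError(f"{name}: unknown categories {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {total!r}, expected 1")
    if any(v < 0 for v in mix.values()):
        raise ConfigError(f"{name}: negative probability")


# ---------------------------------------------------------------------------
# Synthetic region scenario
# ---------------------------------------------------------------------------

def _default_type_mix() -> dict[str, float]:
    # Mirrors the 2022 Volta facility composition: CHPS-dominated primary care.
    return {"CHPS": 0.71, "HealthCentre": 0.21, "Hospital": 0.06, "MaternityHome": 0.02}


def _default_ownership_mix() -> dict[str, float]:
    return {"Government": 0.85, "FaithBased": 0.015, "Private": 0.135}


def _default_archetype_mix() -> dict[str, float]:
    # ~61% unchanged-or-increased, ~21% newly operational, small closed /
    # oscillating / no-service fractions.
    return {
        "closed": 0.02,
        "newly_operational": 0.21,
        "no_service": 0.03,
        "oscillating": 0.016,
        "existing_unchanged": 0.35,
        "existing_increased": 0.26,
        "existing_decreased": 0.05,
        "existing_varying": 0.064,
    }


def _default_subgroup_props() -> dict[str, float]:
    # Census-marginal style proportions: women of childbearing age and
    # children under five as fractions of the total population.
    return {"total": 1.0, "wocba": 0.24, "under5": 0.13}


@dataclass
class RegionConfig:
    """Scenario knobs for the synthetic study region and HMIS archive."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 100.0
    seed: int = 0
    n_facilities: int = 150
    type_mix: dict[str, float] = field(default_factory=_default_type_mix)
    ownership_mix: dict[str, float] = field(default_factory=_default_ownership_mix)
    archetype_mix: dict[str, float] = field(default_factory=_default_archetype_mix)
    coord_error_rate: float = 0.05
    total_population: float = 70_000.0
    growth_rate_pct: float = 2.1
    subgroup_props: dict[str, float] = field(default_factory=_default_subgroup_props)
    water: bool = True
    n_districts: tuple[int, int] = (2, 3)
    n_population_centres: int = 6

    def __post_init__(self) -> None:
        if self.n_rows < 10 or self.n_cols < 10:
            raise ConfigError(f"grid must be at least 10x10, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be > 0")
        if not 0.0 <= self.coord_error_rate <= 1.0:
            raise ConfigError("coord_error_rate must be in [0, 1]")
        if self.n_facilities < 0:
            raise ConfigError("n_facilities must be >= 0")
        if self.total_population <= 0:
            raise ConfigError("total_population must be > 0")
        _check_prob_vector("type_mix", self.type_mix, FACILITY_TYPES)
        _check_prob_vector("ownership_mix", self.ownership_mix, OWNERSHIPS)
        _check_prob_vector("archetype_mix", self.archetype_mix, ARCHETYPES)
        self.n_districts = tuple(self.n_districts)  # type: ignore[assignment]
        if len(self.n_districts) != 2 or min(self.n_districts) < 1:
            raise ConfigError("n_districts must be a (rows, cols) pair of positive ints")

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size


# ---------------------------------------------------------------------------
# Travel model
# ---------------------------------------------------------------------------

def _default_walk_speeds() -> dict[int, float]:
    return {
        LANDCOVER_OPEN: 5.0,
        LANDCOVER_DENSE_VEGETATION: 2.0,
        LANDCOVER_BUILTUP: 5.0,
    }


def _default_road_speeds() -> dict[str, float]:
    return {"primary": 80.0, "secondary": 50.0, "tertiary": 20.0}


@dataclass
class SpeedConfig:
    """Travel speeds for the multimodal friction surface.

    ``walk_speed_kmh`` maps land-cover classes to walking speeds (slope
    adjusted by the hiking function); ``road_speed_kmh`` maps road classes to
    mechanised speeds (not slope adjusted). These are documented defaults:
    empirical tracked-vehicle speeds for a real study area are supplied via
    configuration.
    """

    walk_speed_kmh: dict[int, float] = field(default_factory=_default_walk_speeds)
    road_speed_kmh: dict[str, float] = field(default_factory=_default_road_speeds)
    water_impassable: bool = True

    def __post_init__(self) -> None:
        for name, table in (("walk_speed_kmh", self.walk_speed_kmh),
                            ("road_speed_kmh", self.road_speed_kmh)):
            if any(v <= 0 for v in table.values()):
                raise ConfigError(f"{name}: all speeds must be > 0")


# ---------------------------------------------------------------------------
# Population projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectionConfig:
    """Annual geometric population projection from a gridded baseline.

    ``growth_rate_pct`` is either a single annual percentage rate or a
    mapping year -> rate, where the rate for year *y* governs the transition
    from year *y−1* to *y*. ``subgroup_props`` maps sub-group name to its
    fraction of the total population (optionally per year).
    """

    baseline_year: int = 2021
    growth_rate_pct: float | dict[int, float] = 2.1
    subgroup_props: dict[str, float] | dict[int, dict[str, float]] = field(
        default_factory=_default_subgroup_props
    )

    def rate_for(self, year: int) -> float:
        if isinstance(self.growth_rate_pct, Mapping):
            try:
                r = float(self.growth_rate_pct[year])
            except KeyError:
                raise ConfigError(f"no growth rate configured for year {year}") from None
        else:
            r = float(self.growth_rate_pct)
        if 1.0 + r / 100.0 <= 0:
            raise ConfigError(f"growth rate {r}% for {year} implies non-positive factor")
        return r

    def proportion_for(self, year: int, subgroup: str) -> float:
        props: Any = self.subgroup_props
        if props and all(isinstance(k, int) for k in props):
            props = props.get(year)
            if props is None:
                raise ConfigError(f"no sub-group proportions configured for year {year}")
        if subgroup not in props:
            raise ConfigError(f"no proportion configured for sub-group {subgroup!r}")
        p = float(props[subgroup])
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"proportion for {subgroup!r} must be in [0, 1], got {p}")
        return p


# ---------------------------------------------------------------------------
# Pipeline run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    Exactly one of ``synthetic`` (a scenario) or ``input_dir`` (a directory
    of prepared real-data layers) must be active.
    """

    synthetic: RegionConfig | None = None
    input_dir: str | None = None
    speeds: SpeedConfig = field(default_factory=SpeedConfig)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    band_breaks: tuple[float, ...] = DEFAULT_BAND_BREAKS
    coverage_years: tuple[int, ...] = (2016, 2022)
    qa_tolerance_m: float = 2000.0
    seed: int = 0
    out_dir: str = "hmisaccess_run"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ConfigError("exactly one of synthetic scenario or input_dir must be set")
        if list(self.band_breaks) != sorted(set(self.band_breaks)):
            raise ConfigError("band_breaks must be strictly increasing")
        bad = [y for y in self.coverage_years if y not in YEARS]
        if bad:
            raise ConfigError(f"coverage_years outside the study span: {bad}")


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _as_plain(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _as_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def run_config_to_yaml(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_as_plain(cfg), sort_keys=True))
    return path


def run_config_from_yaml(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return run_config_from_dict(raw)


def _intify_keys(d: Mapping[Any, Any]) -> dict:
    out = {}
    for k, v in d.items():
        try:
            k = int(k)
        except (TypeError, ValueError):
            pass
        out[k] = v
    return out


def run_config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    kwargs: dict[str, Any] = dict(raw)
    if kwargs.get("synthetic") is not None:
        syn = dict(kwargs["synthetic"])
        if "n_districts" in syn:
            syn["n_districts"] = tuple(syn["n_districts"])
        kwargs["synthetic"] = RegionConfig(**syn)
    if kwargs.get("speeds") is not None:
        sp = dict(kwargs["speeds"])
        if "walk_speed_kmh" in sp:
            sp["walk_speed_kmh"] = _intify_keys(sp["walk_speed_kmh"])
        kwargs["speeds"] = SpeedConfig(**sp)
    if kwargs.get("projection") is not None:
        pj = dict(kwargs["projection"])
        if isinstance(pj.get("growth_rate_pct"), Mapping):
            pj["growth_rate_pct"] = _intify_keys(pj["growth_rate_pct"])
        if isinstance(pj.get("subgroup_props"), Mapping):
            pj["subgroup_props"] = _intify_keys(pj["subgroup_props"])
        kwargs["projection"] = ProjectionConfig(**pj)
    for key in ("band_breaks", "coverage_years"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)
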