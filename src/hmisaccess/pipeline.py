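"""End-to-end pipeline: inputs → QA → classification → travel time → coverage.

Runs the stages in dependency order from a single :class:`RunConfig`,
writes every tabular and raster product into the output directory, and
records a manifest (stage statuses, per-stage sizes, output checksums,
config hash, seed). Outputs carry no timestamps, so a re-run with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import classify as _classify
from .config import ConfigError, RunConfig, _as_plain
from .coverage import coverage_change, coverage_trend
from .grid import write_raster
from .hmis_io import RegionData, load_region, qa_locations
from .synthetic import generate_region, write_scenario
from .traveltime import band_classify

logger = logging.getLogger(__name__)

PIPELINE_VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; downstream stages were skipped."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    canonical = yaml.safe_dump(_as_plain(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run all stages; return (and write) the run manifest.

    In synthetic mode the scenario seed is replaced by ``cfg.seed`` so one
    knob controls all randomness in a run.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "pipeline_version": PIPELINE_VERSION,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
        "outputs": {},
    }
    stage_order = ["inputs", "qa", "classify", "coverage"]

    def finish_with_error(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "error", "detail": str(exc)}
        idx = stage_order.index(stage)
        for later in stage_order[idx + 1 :]:
            manifest["stages"][later] = {"status": "skipped"}
        _write_manifest(out, manifest)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # -- stage: inputs ------------------------------------------------------
    try:
        if cfg.synthetic is not None:
            scenario = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            region = generate_region(scenario)
            write_scenario(region, out / "inputs")
        else:
            region = load_region(cfg.input_dir)
        manifest["stages"]["inputs"] = {
            "status": "ok",
            "n_facilities": int(len(region.registry)),
            "n_record_rows": int(len(region.records)),
            "grid": list(region.dem.shape),
        }
    except Exception as exc:  # noqa: BLE001 - reported via manifest
        finish_with_error("inputs", exc)

    # -- stage: qa ----------------------------------------------------------
    try:
        qa, corrected = qa_locations(region.registry, region.districts, cfg.qa_tolerance_m)
        qa.to_csv(out / "qa_report.csv", index=False)
        corrected.to_csv(out / "facility_registry_corrected.csv", index=False)
        manifest["stages"]["qa"] = {
            "status": "ok",
            "statuses": {k: int(v) for k, v in qa["status"].value_counts().items()},
        }
    except Exception as exc:  # noqa: BLE001
        finish_with_error("qa", exc)

    # -- stage: classify ----------------------------------------------------
    try:
        cube = _classify.provision_cube(region.records, corrected)
        classes = _classify.classify_all(cube)
        classes.rename_axis("facility_id").reset_index().to_csv(
            out / "functional_classes.csv", index=False
        )
        _classify.class_distribution(classes, corrected).to_csv(
            out / "class_distribution.csv", index=False
        )
        _classify.percent_providing_table(cube, corrected).to_csv(
            out / "percent_providing.csv", index=False
        )
        ott = _classify.ownership_type_table(corrected)
        ott.counts.to_csv(out / "ownership_type_counts.csv")

        ctab = pd.crosstab(
            corrected.set_index("facility_id")["ownership"].reindex(classes.index),
            classes,
        )
        ctab = ctab.loc[ctab.sum(axis=1) > 0, ctab.sum(axis=0) > 0]
        fisher = _classify.fisher_exact(ctab.to_numpy(), seed=cfg.seed)
        (out / "fisher_ownership_functionality.json").write_text(
            json.dumps(dataclasses.asdict(fisher), indent=2)
        )
        manifest["stages"]["classify"] = {
            "status": "ok",
            "n_classified": int(len(classes)),
            "fisher_p": fisher.p_value,
            "fisher_method": fisher.method,
        }
    except Exception as exc:  # noqa: BLE001
        finish_with_error("classify", exc)

    # -- stage: coverage (travel time + projection + bands) -----------------
    try:
        table, surfaces = coverage_trend(
            cube,
            corrected,
            region,
            cfg.speeds,
            cfg.projection,
            years=cfg.coverage_years,
            breaks=cfg.band_breaks,
            qa=qa,
            return_surfaces=True,
        )
        table.to_csv(out / "coverage.csv", index=False)
        if {cfg.coverage_years[0], cfg.coverage_years[-1]} <= set(table["year"]):
            coverage_change(table, cfg.coverage_years[0], cfg.coverage_years[-1]).to_csv(
                out / "coverage_change.csv", index=False
            )
        rasters = out / "rasters"
        rasters.mkdir(exist_ok=True)
        for (indicator, year), tt in surfaces.items():
            write_raster(tt, rasters / f"traveltime_{indicator}_{year}.tif")
            write_raster(band_classify(tt, cfg.band_breaks), rasters / f"bands_{indicator}_{year}.tif")
        manifest["stages"]["coverage"] = {
            "status": "ok",
            "n_rows": int(len(table)),
            "n_surfaces": len(surfaces),
        }
    except Exception as exc:  # noqa: BLE001
        finish_with_error("coverage", exc)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict[str, Any]) -> None:
    checksums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(out))] = _sha256(p)
    manifest["outputs"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
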