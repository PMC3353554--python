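"""End-to-end orchestration: survey -> screening -> variography -> kriging ->
maps -> pollen comparison, with a checksummed run manifest.

A run takes delimited-text inputs (sampling points, per-date observations,
daily pollen) or simulates them, then per survey date computes the
descriptive/outlier screen, fits the Gaussian variogram, runs leave-one-out
cross-validation, kriges the phase surface onto a regular grid, writes the
raster and classifies the full-flowering band; finally the pollen series is
aggregated weekly and joined with the per-date band fractions.  All artefacts
are plain text (CSV and ESRI ASCII) and the manifest records a SHA-256 per
artefact, so identical (inputs, config, seed) runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .data import (
    PhenoDataset,
    PollenSeries,
    build_datasets,
    read_observations,
    read_points,
    read_pollen,
    write_ascii_grid,
    write_observations,
    write_points,
    write_pollen,
)
from .kriging import krige_grid
from .mapping import classify_full_flowering, elevation_gradient_summary
from .pollen import flowering_pollen_table, peak_week, weekly_pollen_index
from .screening import descriptive_stats, flag_outliers
from .simulate import SimulationConfig, generate_network, simulate_phenology, simulate_pollen
from .validation import loo_cross_validation
from .variogram import empirical_semivariogram, fit_variogram

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("phenokrig")


@dataclass
class PipelineConfig:
    """Every knob of the workflow, with the package defaults."""

    # inputs; any left None is simulated (points may also be "cordoba")
    points_path: str | None = None
    observations_path: str | None = None
    pollen_path: str | None = None
    # variography
    n_lags: int = 6
    max_lag: float | None = None
    weighting: str = "none"
    model_kind: str = "gaussian"
    # kriging
    mean_policy: str = "mean"
    bbox: tuple[float, float, float, float] | None = None
    cellsize: float = 100.0
    nugget_as_error: bool = False
    # mapping / pollen
    band: tuple[float, float] = (1.5, 2.5)
    week_anchor: _dt.date | None = None
    # simulation + reproducibility
    seed: int = 0
    simulation: SimulationConfig | None = None
    outdir: str = "phenokrig_run"

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(seed=self.seed)


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    sim = raw.pop("simulation", None)
    cfg = PipelineConfig(**raw)
    if isinstance(cfg.band, list):
        cfg.band = tuple(cfg.band)
    if cfg.bbox is not None and isinstance(cfg.bbox, list):
        cfg.bbox = tuple(cfg.bbox)
    if isinstance(cfg.week_anchor, str):
        cfg.week_anchor = _dt.date.fromisoformat(cfg.week_anchor)
    if sim is not None:
        if "dates" in sim:
            sim["dates"] = tuple(_dt.date.fromisoformat(d) for d in sim["dates"])
        for key in ("bbox", "altitude_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        sim.setdefault("seed", cfg.seed)
        cfg.simulation = SimulationConfig(**sim)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_record(config: PipelineConfig) -> dict:
    rec = dataclasses.asdict(config)
    rec.pop("outdir", None)  # manifests compare equal across output locations
    if rec.get("week_anchor"):
        rec["week_anchor"] = config.week_anchor.isoformat()
    if rec.get("simulation"):
        rec["simulation"]["dates"] = [d.isoformat() for d in config.simulation.dates]
    return rec


def _acquire_inputs(config: PipelineConfig, outdir: Path):
    sim = config.resolved_simulation()
    if config.points_path == "cordoba":
        points = reference.cordoba_network()
    elif config.points_path:
        points = read_points(config.points_path)
    else:
        points = generate_network(sim)
        log.info("simulated network of %d points (seed %d)", len(points), sim.seed)
    write_points(points, outdir / "points.csv")

    if config.observations_path:
        datasets = build_datasets(read_observations(config.observations_path), points)
    else:
        datasets = simulate_phenology(points, sim)
        log.info("simulated %d survey dates", len(datasets))
    write_observations(datasets, outdir / "observations.csv")

    if config.pollen_path:
        pollen = read_pollen(config.pollen_path)
    else:
        pollen = simulate_pollen(datasets, sim)
        log.info("simulated pollen series of %d days", len(pollen))
    write_pollen(pollen, outdir / "pollen.csv")
    return points, datasets, pollen


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        points, datasets, pollen = _acquire_inputs(config, outdir)

        stats_rows, vario_rows, cv_rows, area_rows = [], [], [], []
        masks = {}
        for ds in datasets:
            st = descriptive_stats(ds.values)
            n_out = int(flag_outliers(ds.values, st).sum())
            stats_rows.append(
                {
                    "date": ds.date.isoformat(), "n": st.n,
                    "mean": st.mean, "variance": st.variance,
                    "minimum": st.minimum, "maximum": st.maximum, "cv": st.cv,
                    "lower_threshold": st.lower_threshold,
                    "upper_threshold": st.upper_threshold,
                    "n_outliers": n_out,
                }
            )
            if n_out:
                log.warning("%s: %d outlier(s) flagged", ds.date, n_out)

            emp = empirical_semivariogram(ds, n_lags=config.n_lags, max_lag=config.max_lag)
            model = fit_variogram(emp, kind=config.model_kind, weighting=config.weighting)
            vario_rows.append(
                {
                    "date": ds.date.isoformat(), "kind": model.kind,
                    "nugget": model.nugget, "structural_sill": model.structural_sill,
                    "range_param": model.range_param, "sill": model.sill,
                    "effective_range": model.effective_range,
                    "r2": model.r2, "rss": model.rss,
                    "pure_nugget": model.pure_nugget,
                }
            )
            log.info(
                "%s variogram: C0=%.4g C=%.4g A0=%.4g r2=%.3f rss=%.3g%s",
                ds.date, model.nugget, model.structural_sill, model.range_param,
                model.r2, model.rss, " [pure nugget]" if model.pure_nugget else "",
            )

            cv = loo_cross_validation(
                ds, model, mean_policy=config.mean_policy,
                nugget_as_error=config.nugget_as_error,
            )
            cv_rows.append(
                {
                    "date": ds.date.isoformat(), "slope": cv.slope,
                    "intercept": cv.intercept, "r2": cv.r2, "rmse": cv.rmse,
                    "bias": cv.bias, "degenerate": cv.degenerate,
                }
            )
            log.info("%s cross-validation: slope=%.3f rmse=%.3f%s",
                     ds.date, cv.slope, cv.rmse, " [degenerate]" if cv.degenerate else "")

            grid = krige_grid(
                ds, model, mean=None, bbox=config.bbox, cellsize=config.cellsize,
                nugget_as_error=config.nugget_as_error,
            )
            if grid.clamp_flags is not None and grid.clamp_flags.any():
                log.info("%s: %d kriged cells clamped to [0, 4]",
                         ds.date, int(grid.clamp_flags.sum()))
            write_ascii_grid(grid, outdir / f"pheno_{ds.date.isoformat()}.asc")
            mask = classify_full_flowering(grid, *config.band)
            masks[ds.date] = mask
            rho, ok = elevation_gradient_summary(grid, ds.points)
            area_rows.append(
                {
                    "date": ds.date.isoformat(),
                    "area_fraction": mask.area_fraction,
                    "altitude_phase_rho": rho,
                    "rho_defined": ok,
                }
            )

        pd.DataFrame(stats_rows).to_csv(outdir / "describe.csv", index=False)
        pd.DataFrame(vario_rows).to_csv(outdir / "variograms.csv", index=False)
        pd.DataFrame(cv_rows).to_csv(outdir / "cv.csv", index=False)
        pd.DataFrame(area_rows).to_csv(outdir / "area_fractions.csv", index=False)

        weekly = weekly_pollen_index(pollen, config.week_anchor)
        pd.DataFrame(
            {
                "week_start": [d.isoformat() for d in weekly.week_starts],
                "pollen_index": weekly.indices,
                "complete": weekly.complete,
            }
        ).to_csv(outdir / "weekly_pollen.csv", index=False)
        pk_date, pk_index, pk_tied = peak_week(weekly)
        log.info("peak pollen week starts %s (index %.1f%s)",
                 pk_date, pk_index, ", tied" if pk_tied else "")
        flowering_pollen_table(masks, weekly).to_csv(
            outdir / "flowering_pollen.csv", index=False
        )

        artefacts = sorted(
            p.name for p in outdir.iterdir()
            if p.suffix in (".csv", ".asc") and p.is_file()
        )
        manifest = {
            "config": _config_record(config),
            "peak_week": {"week_start": pk_date.isoformat(), "index": pk_index,
                          "tied": pk_tied},
            "artifacts": {name: _sha256(outdir / name) for name in artefacts},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
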