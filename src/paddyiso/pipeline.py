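"""End-to-end orchestration: generate -> calibrate -> keeling ->
partition -> associate, from one run configuration.

Every stage writes its tabular output as CSV with a JSON sidecar of the
parameters that produced it, and the run closes with a machine-readable
manifest.  Deterministic stages are bit-identical across reruns of the
same configuration.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .association import correlate, flux_weighted_delta
from .calibration import assignments_from_config, calibrate_stream
from .config import ConfigurationError, ScenarioConfig
from .io import (
    read_ecosystem,
    read_kp_table,
    read_raw_stream,
    read_regions,
    write_csv,
)
from .keeling import filter_fits, fit_keeling, summarize_daily
from .partition import combine_heights_and_models, partition_season
from .synthetic import season_dates, simulate_campaign

STAGES = ["generate", "calibrate", "keeling", "partition", "associate"]


class RunConfig(BaseModel):
    """Flat configuration of one pipeline run."""

    mode: Literal["synthetic", "observed"] = "synthetic"
    out_dir: Path = Path("paddyiso_run")
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)

    # observed-mode inputs
    raw_path: Optional[Path] = None
    kp_path: Optional[Path] = None
    ecosystem_path: Optional[Path] = None
    transplant_date: Optional[str] = None
    regions_path: Optional[Path] = None

    # analysis parameters (defaults follow the campaign's choices:
    # 5-min slots, R^2 > 0.5 filter, 15-day windows offset 3 days)
    r2_threshold: float = 0.5
    keeling_min_points: int = 20
    window_width_d: int = 15
    window_start_offset_d: int = 3
    bootstrap_B: int = 200
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode == "observed":
            for name in ("raw_path", "kp_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigurationError(f"{name} is required in observed mode")
                if not Path(p).exists():
                    raise ConfigurationError(f"{name} does not exist: {p}")
            if self.transplant_date is None:
                raise ConfigurationError("transplant_date is required in observed mode")
        return self


def _sidecar(path: Path, params: dict) -> None:
    path.with_suffix(path.suffix + ".params.json").write_text(
        json.dumps(params, indent=2, default=str) + "\n"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    A stage failure raises with the failing stage named; outputs of the
    completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "mode": config.mode,
        "seed": config.seed,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "stages": [],
    }

    stage = "generate"
    try:
        if config.mode == "synthetic":
            campaign = simulate_campaign(config.scenario)
            raw = campaign["raw"]
            kp_table = campaign["kp"]
            eco = campaign["ecosystem"]
            transplant = season_dates(config.scenario)[0]
            for name in ("truth", "raw", "ecosystem", "kp"):
                p = write_csv(campaign[name], out / f"{name}.csv")
                _sidecar(p, {"stage": stage, "scenario_seed": config.scenario.rng_seed})
            counts = {k: len(v) for k, v in campaign.items()}
        else:
            raw = read_raw_stream(config.raw_path)
            kp_table = read_kp_table(config.kp_path)
            eco = read_ecosystem(config.ecosystem_path) if config.ecosystem_path else None
            transplant = pd.Timestamp(config.transplant_date)
            counts = {"raw": len(raw), "kp": len(kp_table)}
        manifest["stages"].append({"name": stage, "counts": counts})

        stage = "calibrate"
        assignments = assignments_from_config(config.scenario.refgas_values)
        samples, ledger = calibrate_stream(raw, assignments)
        p = write_csv(samples, out / "calibrated.csv")
        _sidecar(p, {"stage": stage, "rejections": ledger.counts})
        manifest["stages"].append(
            {"name": stage, "counts": {"samples": len(samples), **ledger.counts}}
        )

        stage = "keeling"
        fits = fit_keeling(samples, min_points=config.keeling_min_points)
        fits, retention = filter_fits(fits, r2_threshold=config.r2_threshold)
        daily = summarize_daily(fits)
        p = write_csv(fits, out / "keeling_fits.csv")
        _sidecar(
            p,
            {
                "stage": stage,
                "r2_threshold": config.r2_threshold,
                "min_points": config.keeling_min_points,
                "retention_percent": retention,
            },
        )
        write_csv(daily, out / "keeling_daily.csv")
        manifest["stages"].append(
            {
                "name": stage,
                "counts": {"fits": len(fits), "retained": int(fits["retained"].sum())},
                "retention_percent": retention,
            }
        )

        stage = "partition"
        windows = partition_season(
            daily,
            kp_table,
            transplant,
            width_d=config.window_width_d,
            start_offset_d=config.window_start_offset_d,
            bootstrap_B=config.bootstrap_B,
            seed=config.seed,
        )
        combined = combine_heights_and_models(windows)
        p = write_csv(windows, out / "windows.csv")
        _sidecar(
            p,
            {
                "stage": stage,
                "window_width_d": config.window_width_d,
                "start_offset_d": config.window_start_offset_d,
                "bootstrap_B": config.bootstrap_B,
                "seed": config.seed,
            },
        )
        write_csv(combined, out / "windows_mean.csv")
        manifest["stages"].append(
            {"name": stage, "counts": {"windows": len(windows), "combined": len(combined)}}
        )

        stage = "associate"
        assoc_counts = {}
        if eco is not None and len(combined):
            rows = []
            eco = eco.copy()
            eco["date"] = pd.to_datetime(eco["date"]).dt.normalize()
            for model, sub in combined.groupby("model_label"):
                merged = sub.copy()
                for var in ("gpp", "respiration"):
                    means = [
                        eco[(eco["date"] >= s) & (eco["date"] <= e)][var].mean()
                        for s, e in zip(sub["window_start"], sub["window_end"])
                    ]
                    tab = correlate(pd.Series(means), sub["delta_source_permil"])
                    tab.insert(0, "pair", f"delta_source~{var}")
                    tab.insert(0, "model_label", model)
                    rows.append(tab)
            corr = pd.concat(rows, ignore_index=True)
            p = write_csv(corr, out / "correlations.csv")
            _sidecar(p, {"stage": stage})
            assoc_counts["correlations"] = len(corr)
        if config.regions_path:
            regions = read_regions(config.regions_path)
            weighted = flux_weighted_delta(regions)
            (out / "regional.json").write_text(
                json.dumps(
                    {"flux_weighted_delta_source_permil": weighted, "n_regions": len(regions)},
                    indent=2,
                )
                + "\n"
            )
            assoc_counts["regions"] = len(regions)
        manifest["stages"].append({"name": stage, "counts": assoc_counts})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
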