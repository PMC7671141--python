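"""End-to-end orchestration: simulate -> odba -> timing -> weather -> model.

A single structured config (YAML or dict, sections named after the
modules) drives a reproducible run.  Stages execute in dependency order,
log record counts (so the filter bookkeeping — how many detections the
plausibility windows and the snow rule removed — is visible), and any
stage failure aborts with the failing stage named.  A run manifest records
the config hash, seed, per-stage output row counts and package version;
identical (config, seed) reproduces identical manifests and byte-identical
output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ValidationError, activity_days_frame
from .io import read_trace, read_twilight, read_weather, write_trace, write_twilight, write_weather
from .models import ModelSpec, fit_lmm
from .odba import OdbaConfig, aggregate, compute_odba
from .synthetic import DEFAULT_ANIMALS, SimConfig, simulate_study
from .timing import DetectorConfig, activity_days, build_actogram, partition_snow_days, plot_actogram
from .weather import daily_covariate_table, daily_snow_series, twilight_window_table

log = logging.getLogger("noctograph.pipeline")

_SECTIONS = ("simulate", "odba", "timing", "weather", "model")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping of module sections")
    for key in config:
        if key not in _SECTIONS:
            raise ConfigError(f"unknown config section {key!r}")
    return config


def _sim_config(section: dict, seed: int) -> SimConfig:
    section = dict(section or {})
    n_animals = section.pop("n_animals", None)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    for key in section:
        if key not in known:
            raise ConfigError(f"unknown simulate config key {key!r}")
    if n_animals is not None:
        section["animals"] = DEFAULT_ANIMALS[:n_animals]
    if "animals" in section:
        section["animals"] = tuple(tuple(a) for a in section["animals"])
    return SimConfig(seed=seed, **section)


def _detector_config(section: dict) -> DetectorConfig:
    section = dict(section or {})
    known = {f.name for f in dataclasses.fields(DetectorConfig)}
    for key in section:
        if key not in known:
            raise ConfigError(f"unknown timing config key {key!r}")
    return DetectorConfig(**section)


def _write(frame: pd.DataFrame, path: Path, outputs: dict, float_format="%.6f") -> None:
    frame.to_csv(path, index=False, float_format=float_format)
    outputs[path.name] = len(frame)


def run_pipeline(config, outdir, seed: int = 0, actograms: bool = True) -> RunManifest:
    """Execute the full pipeline; returns the run manifest.

    ``config`` is a dict or a YAML path with sections ``simulate``,
    ``odba``, ``timing``, ``weather`` and ``model``.  All randomness is
    derived from ``seed``.
    """
    config = _load_config(config)
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    # Config errors (unknown sections/keys, bad values) surface before any
    # stage runs, so a typo never produces a partial output directory.
    sim = _sim_config(config.get("simulate", {}), seed)
    det_cfg = _detector_config(config.get("timing", {}))
    try:
        odba_cfg = OdbaConfig(**(config.get("odba") or {}))
    except TypeError as exc:
        raise ConfigError(f"bad odba config: {exc}") from exc

    outdir = Path(outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    stages_report = []

    # ---------------- simulate ----------------
    try:
        bundle = simulate_study(sim)
        outputs: dict = {}
        trace_files = []
        for trace, (_, dep) in zip(bundle.traces, bundle.deployments.iterrows()):
            path = outdir / "inputs" / f"trace_{dep.animal_id}_{dep.stage}.csv"
            write_trace(trace, path)
            trace_files.append((path, dep))
            outputs[path.name] = trace.n_samples
        write_weather(bundle.weather, outdir / "inputs" / "weather.csv")
        outputs["weather.csv"] = len(bundle.weather)
        write_twilight(bundle.twilight, outdir / "inputs" / "twilight.csv")
        outputs["twilight.csv"] = len(bundle.twilight.frame)
        truth = bundle.truth.copy()
        _write(truth, outdir / "inputs" / "truth.csv", outputs)
        stages_report.append({"name": "simulate", "outputs": outputs})
        log.info("simulate: %d deployments", len(trace_files))
    except (ValidationError, ConfigError) as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # ---------------- odba ----------------
    try:
        outputs = {}
        series_by_dep = []
        daily_rows = []
        hourly_frames = []
        for path, dep in trace_files:
            trace = read_trace(path, sim.rate_hz, dep.animal_id, dep.sex)
            series = compute_odba(trace, odba_cfg)
            hourly = aggregate(series, "hourly")
            daily = aggregate(series, "daily")
            series_by_dep.append((series, dep))
            for date, val in daily.items():
                daily_rows.append(
                    {
                        "animal_id": dep.animal_id,
                        "sex": dep.sex,
                        "stage": dep.stage,
                        "date": date,
                        "mean_daily_odba": val,
                    }
                )
            h = hourly.reset_index()
            h.insert(0, "animal_id", dep.animal_id)
            hourly_frames.append(h)
        daily_odba = pd.DataFrame(daily_rows)
        _write(daily_odba, outdir / "odba_daily.csv", outputs)
        _write(pd.concat(hourly_frames, ignore_index=True), outdir / "odba_hourly.csv", outputs)
        stages_report.append({"name": "odba", "outputs": outputs})
    except (ValidationError, ValueError, FileNotFoundError) as exc:
        raise PipelineError("odba", str(exc)) from exc

    # ---------------- timing ----------------
    try:
        outputs = {}
        twi = read_twilight(outdir / "inputs" / "twilight.csv")
        weather_frame = read_weather(outdir / "inputs" / "weather.csv")
        snow = daily_snow_series(weather_frame)
        all_days = []
        (outdir / "actograms").mkdir(exist_ok=True)
        for series, dep in series_by_dep:
            days = activity_days(series, twi, det_cfg)
            retained, excluded = partition_snow_days(days, snow)
            frame = activity_days_frame(retained + excluded)
            # normalize dtypes so deployments with no detections concat
            # cleanly with ones that have them
            for col in ("onset", "offset"):
                frame[col] = pd.to_datetime(frame[col])
            for col in ("duration_h", "onset_rel_dusk_min", "offset_rel_dawn_min"):
                frame[col] = pd.to_numeric(frame[col])
            frame.insert(1, "sex", dep.sex)
            frame.insert(2, "stage", dep.stage)
            all_days.append(frame)
            if actograms:
                mat = build_actogram(series, bin_min=10, double_plot=True)
                plot_actogram(
                    mat,
                    outdir / "actograms" / f"{dep.animal_id}_{dep.stage}.png",
                    title=f"{dep.animal_id} {dep.stage}",
                )
        activity = pd.concat(all_days, ignore_index=True).sort_values(
            ["animal_id", "night_date"], kind="stable"
        )
        n_window_removed = activity["flags"].str.contains("out_of_window").sum()
        n_snow_removed = activity["flags"].str.contains("snow").sum()
        log.info(
            "timing: %d nights, %d window-filtered, %d snow-excluded",
            len(activity), n_window_removed, n_snow_removed,
        )
        _write(activity, outdir / "activity_days.csv", outputs)
        stages_report.append({"name": "timing", "outputs": outputs})
    except (ValidationError, ValueError) as exc:
        raise PipelineError("timing", str(exc)) from exc

    # ---------------- weather ----------------
    try:
        outputs = {}
        dates = pd.DatetimeIndex(sorted(set(daily_odba["date"])))
        wdaily = daily_covariate_table(weather_frame, dates).reset_index()
        _write(wdaily, outdir / "weather_daily.csv", outputs)
        dusk_times = [twi.dusk(d) for d in dates if d in twi.frame.index]
        wdusk = twilight_window_table(weather_frame, dusk_times)
        _write(wdusk, outdir / "weather_dusk_window.csv", outputs)
        stages_report.append({"name": "weather", "outputs": outputs})
    except (ValidationError, ValueError) as exc:
        raise PipelineError("weather", str(exc)) from exc

    # ---------------- model ----------------
    try:
        outputs = {}
        records = daily_odba.merge(
            wdaily.rename(columns={"index": "date"}), on="date", how="left"
        ).dropna(subset=["mean_daily_odba"])
        est_rows = []
        for sex in sorted(records["sex"].unique()):
            sub = records[records["sex"] == sex]
            if sub["animal_id"].nunique() < 2 or sub["stage"].nunique() < 2:
                log.info("model: skipping sex=%s (insufficient design)", sex)
                continue
            spec = ModelSpec(response="mean_daily_odba", fixed=("stage",))
            fit = fit_lmm(sub, spec)
            for term, row in fit.params.iterrows():
                est_rows.append(
                    {
                        "model": f"odba_stage_{sex}",
                        "term": term,
                        "estimate": row["estimate"],
                        "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"],
                        "p_value": row["p_value"],
                        "sigma2": fit.sigma2,
                        "converged": fit.converged,
                        "singular": fit.singular,
                    }
                )
            for name, tau in sorted(fit.tau00.items()):
                est_rows.append(
                    {
                        "model": f"odba_stage_{sex}",
                        "term": f"tau00_{name}",
                        "estimate": tau,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "sigma2": fit.sigma2,
                        "converged": fit.converged,
                        "singular": fit.singular,
                    }
                )
        _write(pd.DataFrame(est_rows), outdir / "model_estimates.csv", outputs)
        stages_report.append({"name": "model", "outputs": outputs})
    except (ValidationError, ValueError) as exc:
        raise PipelineError("model", str(exc)) from exc

    manifest = RunManifest(
        config_hash=config_hash, seed=seed, version=__version__, stages=stages_report
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
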