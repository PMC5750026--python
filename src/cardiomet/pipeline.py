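"""End-to-end reproducible runs: simulate → detect → respiro → calibrate → field.

A run is driven by a :class:`RunConfig` (YAML-serializable, with every
default made explicit in the emitted effective config).  Each stage writes
CSV outputs with JSON sidecars recording the config digest and seed, so
identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration, detection, field as field_analysis, io, respirometry, synthetic
from .trajectory import RateTrajectory, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline", "make_fixtures"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full parameterization of a pipeline run.

    Unknown keys in a loaded file are rejected so silent typos cannot
    change a run.  ``effective()`` returns the config with every default
    filled in, which is also what gets written next to the outputs.
    """

    seed: int = 0
    out_dir: str = "run"
    audio_duration_s: float = 120.0
    audio_rate_bpm: float = 300.0
    aggregation_s: float = 10.0
    sample_rate: float = 48000.0
    carrier_freq: float = 1500.0
    noise_sd: float = 0.02
    respiro_duration_s: float = 7200.0
    respiro_mr_kj_h: tuple = (0.45, 0.131, 0.160)
    rer: float = 0.8
    mass_g: float = respirometry.DEFAULT_MASS_G
    calib_n_individuals: int = 6
    calib_n_obs: int = 150
    field_duration_h: float = 36.0
    field_torpor_schedule: tuple = ((14.0, 18.0),)
    detection: dict = field(default_factory=dict)
    input_wav: str | None = None  # detect a real recording instead of synthetic

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("respiro_mr_kj_h", "field_torpor_schedule"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in raw[key])
        return cls(**raw)

    def effective(self) -> dict:
        return io._jsonable(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.effective(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sidecar(cfg: RunConfig, path, **extra):
    extra.setdefault("spec", None)
    io.write_sidecar(path, seed=cfg.seed, config_digest=cfg.digest(),
                     version=__version__, **extra)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.yaml").write_text(yaml.safe_dump(config.effective()))
    logger.info("run %s -> %s", config.digest(), out)
    dcfg = detection.DetectionConfig(**config.detection)

    # --- stage: simulate / load audio -------------------------------------
    try:
        if config.input_wav:
            if not Path(config.input_wav).exists():
                raise FileNotFoundError(f"input_wav not found: {config.input_wav}")
            samples, sr = io.read_wav(config.input_wav)
            audio = detection.AudioRecording(samples, sr)
            truth = None
        else:
            spec = synthetic.SignalSpec(
                sample_rate=config.sample_rate,
                carrier_freq=config.carrier_freq,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            traj = RateTrajectory.constant(config.audio_rate_bpm, config.audio_duration_s)
            audio, truth = synthetic.synthesize_transmitter_audio(spec, traj)
            io.write_wav(out / "audio.wav", audio.samples, int(audio.sample_rate))
            pd.DataFrame({"beat_time_s": truth}).to_csv(out / "beat_truth.csv", index=False)
            _sidecar(config, out / "audio.wav", spec=io._jsonable(spec))
            _sidecar(config, out / "beat_truth.csv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # --- stage: detect -----------------------------------------------------
    try:
        carrier = detection.estimate_carrier_frequency(audio, dcfg)
        filtered = detection.bandpass_filter(audio, carrier, dcfg)
        events = detection.detect_beats(filtered, dcfg)
        rate = detection.counts_to_rate(events, aggregation=config.aggregation_s)
        rate = detection.kde_quantile_filter(rate, dcfg)
        rate.to_frame().to_csv(out / "heart_rate.csv", index=False)
        _sidecar(config, out / "heart_rate.csv", carrier_hz=carrier)
    except Exception as exc:
        raise StageError("detect", exc) from exc

    # --- stage: respiro ----------------------------------------------------
    try:
        n_states = len(config.respiro_mr_kj_h)
        seg = config.respiro_duration_s / n_states
        bps = tuple(np.arange(n_states + 1) * seg)
        mr_traj = Trajectory(bps, tuple(config.respiro_mr_kj_h), "step")
        baselines = ((0.0, 120.0), (config.respiro_duration_s - 120.0, config.respiro_duration_s))
        chamber = synthetic.ChamberSpec(baseline_schedule=baselines)
        trace = synthetic.simulate_respirometry_trace(chamber, mr_traj, config.rer, seed=config.seed)
        trace.to_frame().to_csv(out / "respirometry_trace.csv", index=False)
        corrected = respirometry.baseline_correct(trace)
        met = respirometry.metabolic_series(corrected, config.rer, config.mass_g)
        met.to_csv(out / "metabolic_series.csv", index=False)
        _sidecar(config, out / "metabolic_series.csv")
    except Exception as exc:
        raise StageError("respiro", exc) from exc

    # --- stage: calibrate --------------------------------------------------
    try:
        mspec = synthetic.MixedModelSpec(
            n_individuals=config.calib_n_individuals,
            n_obs_per_individual=config.calib_n_obs,
            seed=config.seed,
        )
        calib_data = synthetic.simulate_calibration_dataset(mspec)
        calib_data.to_csv(out / "calibration_data.csv", index=False)
        table, fits = calibration.model_selection(calib_data, unit=mspec.unit)
        table.to_csv(out / "model_selection.csv", index=False)
        best = fits[("f_h",)]
        (out / "calibration_fit.json").write_text(
            json.dumps(
                {
                    "intercept": best.beta["intercept"],
                    "slope": best.beta["f_h"],
                    "unit": best.unit,
                    "r2m": best.r2m,
                    "r2c": best.r2c,
                    "n": best.n_obs,
                },
                indent=2,
            )
        )
        _sidecar(config, out / "model_selection.csv")
    except Exception as exc:
        raise StageError("calibrate", exc) from exc

    # --- stage: field ------------------------------------------------------
    try:
        fd = synthetic.simulate_field_dataset(
            duration_h=config.field_duration_h,
            torpor_schedule=config.field_torpor_schedule,
            seed=config.seed,
        )
        records = field_analysis.sync_streams(fd.hr, fd.tb, fd.ta)
        records, threshold, hours = field_analysis.classify_low_state(records)
        records.to_csv(out / "field_records.csv", index=False)
        field_analysis.hourly_summary(records).to_csv(out / "hourly_summary.csv")
        _, totals = field_analysis.predict_field_expenditure(records, fit=None)
        totals.to_csv(out / "daily_expenditure.csv", index=False)
        _sidecar(config, out / "field_records.csv", low_state_threshold=threshold,
                 low_state_hours=hours)
    except Exception as exc:
        raise StageError("field", exc) from exc

    return out


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the small canonical fixture set; returns paths by name.

    Contents: 10-s audio clips at five constant rates, a 2-h respirometry
    trace, a 6x150 calibration table, and a 36-h field dataset (one diurnal
    torpor bout, foraging gaps — the structure of a typical in-roost
    recording).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for bpm in (60, 150, 300, 600, 1000):
        spec = synthetic.SignalSpec(seed=seed + bpm)
        audio, truth = synthetic.synthesize_transmitter_audio(
            spec, RateTrajectory.constant(bpm, 10.0)
        )
        p = out / f"audio_{bpm}bpm.wav"
        io.write_wav(p, audio.samples, int(audio.sample_rate))
        pd.DataFrame({"beat_time_s": truth}).to_csv(out / f"audio_{bpm}bpm_truth.csv", index=False)
        io.write_sidecar(p, spec=spec, seed=seed + bpm)
        paths[f"audio_{bpm}"] = p

    mr_traj = Trajectory((0.0, 2400.0, 4800.0, 7200.0), (0.45, 0.131, 0.160), "step")
    chamber = synthetic.ChamberSpec(baseline_schedule=((0.0, 120.0), (7080.0, 7200.0)))
    trace = synthetic.simulate_respirometry_trace(chamber, mr_traj, 0.8, seed=seed)
    p = out / "respirometry_trace.csv"
    trace.to_frame().to_csv(p, index=False)
    io.write_sidecar(p, spec=chamber, seed=seed)
    paths["respirometry"] = p

    calib = synthetic.simulate_calibration_dataset(synthetic.MixedModelSpec(seed=seed))
    p = out / "calibration.csv"
    calib.to_csv(p, index=False)
    io.write_sidecar(p, spec=synthetic.MixedModelSpec(seed=seed), seed=seed)
    paths["calibration"] = p

    fd = synthetic.simulate_field_dataset(
        duration_h=36.0, torpor_schedule=((14.0, 18.0),), seed=seed
    )
    for name, df in (("field_hr", fd.hr), ("field_tb", fd.tb), ("field_ta", fd.ta)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        io.write_sidecar(p, seed=seed)
        paths[name] = p
    return paths
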