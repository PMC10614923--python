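"""Readers/writers, run configuration, manifests and the end-to-end pipeline.

Conventions: all timestamps are seconds from recording start; intervals are
half-open [onset, offset); tables are UTF-8 CSV with a header row; nested
outputs are JSON.  CSV traces are either one column (uniform sampling at a
supplied rate) or two columns (time_s, value) whose time stamps must be
uniform to 1 microsecond.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import __version__
from .breath import (AirflowTrace, preprocess_airflow, segment_breaths,
                     compute_breath_features, label_vocal_breaths,
                     timing_metrics_frame)
from .emg import EmgTrace, remove_ecg, rectify_integrate, detect_bursts, \
    burst_phase_metrics
from .intonation import intonation_analysis, results_frame
from .pitch import PitchContour, UsvEvent, SYLLABLE_TYPES, detect_usv_events, \
    group_syllables, classify_contour
from .sim import SimConfig, generate_breath_train, synthesize_emg

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def read_trace(path, kind: str = "airflow", rate_override: float | None = None):
    """Read a WAV or CSV trace as the matching domain type.

    CSV: one column implies uniform sampling at ``rate_override`` (required);
    two columns are (time_s, value) and the time stamps must be uniform to
    1e-6 s.  WAV takes its rate from the header unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        samples = np.asarray(data, dtype=float)
        if samples.ndim > 1:
            samples = samples[:, 0]
        rate = rate_override or float(rate)
        start = 0.0
    else:
        df = pd.read_csv(path)
        if df.shape[1] == 1:
            if rate_override is None:
                raise ValueError(f"{path}: single-column CSV needs an explicit "
                                 "sampling rate (rate_override)")
            samples = df.iloc[:, 0].to_numpy(float)
            rate, start = float(rate_override), 0.0
        elif df.shape[1] >= 2:
            t = df.iloc[:, 0].to_numpy(float)
            samples = df.iloc[:, 1].to_numpy(float)
            dt = np.diff(t)
            if dt.size == 0:
                raise ValueError(f"{path}: trace needs at least two samples")
            off = np.abs(dt - np.median(dt))
            if off.max() > 1e-6:
                k = int(np.argmax(off))
                raise ValueError(
                    f"{path}: non-uniform timestamps (worst offset "
                    f"{off.max():.3g} s at row {k + 1}, t={t[k + 1]:.6f})")
            rate = rate_override or 1.0 / float(np.median(dt))
            start = float(t[0])
        else:
            raise ValueError(f"{path}: empty CSV")
    if kind == "airflow":
        return AirflowTrace(samples=samples, rate=rate, start_time=start)
    if kind == "emg":
        return EmgTrace(samples=samples, rate=rate, start_time=start)
    if kind == "audio":
        return samples, rate
    raise ValueError(f"unknown trace kind {kind!r}")


def write_trace_csv(path, samples: np.ndarray, rate: float,
                    value_name: str = "flow_au", start_time: float = 0.0):
    t = start_time + np.arange(len(samples)) / rate
    pd.DataFrame({"time_s": t, value_name: samples}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def write_wav(path, samples: np.ndarray, rate: float):
    wavfile.write(path, int(round(rate)), samples.astype(np.float32))


def read_usv_table(path) -> list[UsvEvent]:
    """VocalMat-style interchange CSV: start_s, end_s[, type]."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "start_s" not in cols or "end_s" not in cols:
        raise ValueError(f"{path}: USV table needs columns start_s,end_s")
    df = df.rename(columns={cols["start_s"]: "start_s", cols["end_s"]: "end_s"})
    for i, row in df.iterrows():
        if row.end_s <= row.start_s:
            raise ValueError(f"{path}: row {i + 1} has end_s <= start_s")
    df = df.sort_values("start_s").reset_index(drop=True)
    ends = df["end_s"].to_numpy()
    starts = df["start_s"].to_numpy()
    if np.any(starts[1:] < ends[:-1]):
        k = int(np.argmax(starts[1:] < ends[:-1]))
        raise ValueError(f"{path}: overlapping events around row {k + 2}")
    events = []
    for i, row in df.iterrows():
        ty = str(row.get("type", "unknown")).strip().lower() \
            if "type" in df.columns else "unknown"
        if ty not in SYLLABLE_TYPES and ty != "unknown":
            log.warning("unknown USV type %r mapped to 'unknown'", ty)
            ty = "unknown"
        events.append(UsvEvent(id=int(i), onset=float(row.start_s),
                               offset=float(row.end_s),
                               syllables=[(float(row.start_s),
                                           float(row.end_s))],
                               type_label=ty))
    return events


def write_usv_table(path, events: list[UsvEvent]):
    pd.DataFrame([dict(start_s=e.onset, end_s=e.offset, type=e.type_label)
                  for e in events]).to_csv(path, index=False,
                                           float_format=_FLOAT_FMT)


def write_contour_csv(path, contour: PitchContour):
    pd.DataFrame({"time_s": contour.times, "f_peak_hz": contour.f_peak,
                  "power": contour.peak_power,
                  "valid": contour.valid.astype(int)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration and pipeline

_STAGE_DEFAULTS = {
    "breaths": dict(highpass_hz=2.0, smooth_ms=5.0, hysteresis_frac=0.05,
                    min_breath_ms=50.0),
    "pitch": dict(band_low_hz=40_000.0, band_high_hz=120_000.0,
                  floor_db=15.0, min_dur_ms=5.0, max_gap_ms=5.0,
                  gap_threshold_ms=20.0, jump_threshold_khz=10.0),
    "intonation": dict(n_perm=200, alpha=0.05, min_bins=5, per_type_min=20),
    "emg": dict(cutoff_hz=40.0, threshold_frac=0.3, min_dur_ms=10.0,
                min_gap_ms=10.0, pdf_bins=20, max_lag_ms=50.0),
}


@dataclass
class RunConfig:
    """Namespaced parameters for every pipeline stage.

    Unknown keys are rejected on construction so typos never silently fall
    back to defaults; the config round-trips losslessly through YAML.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    breaths: dict = field(default_factory=lambda: dict(_STAGE_DEFAULTS["breaths"]))
    pitch: dict = field(default_factory=lambda: dict(_STAGE_DEFAULTS["pitch"]))
    intonation: dict = field(default_factory=lambda: dict(
        _STAGE_DEFAULTS["intonation"]))
    emg: dict = field(default_factory=lambda: dict(_STAGE_DEFAULTS["emg"]))
    stages: tuple = ("simulate", "breaths", "pitch", "intonation", "emg")
    out_dir: str = "intonate_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {"sim", "breaths", "pitch", "intonation", "emg", "stages",
                 "out_dir", "seed", "log_level"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_d = d.pop("sim", {})
        sim_known = set(SimConfig().to_dict())
        bad = set(sim_d) - sim_known
        if bad:
            raise ValueError(f"unknown sim config keys: {sorted(bad)}")
        cfg = cls(sim=SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in sim_d.items()}))
        for stage in ("breaths", "pitch", "intonation", "emg"):
            params = d.pop(stage, {})
            bad = set(params) - set(_STAGE_DEFAULTS[stage])
            if bad:
                raise ValueError(f"unknown {stage} config keys: {sorted(bad)}")
            getattr(cfg, stage).update(params)
        for k, v in d.items():
            setattr(cfg, k, tuple(v) if k == "stages" else v)
        cfg.sim.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".toml",):
            import tomllib
            with open(path, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    input_digests: dict
    stage_timings_s: dict
    warnings: list
    outputs: list


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir=None) -> RunManifest:
    """Execute the configured stages and write all result tables.

    simulate -> breaths -> pitch -> intonation -> emg, each skippable via
    ``config.stages``.  Identical config and seed reproduce byte-identical
    result tables.  A stage failure raises with the stage name; outputs
    written so far are left in place.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings, warnings_, outputs = {}, [], []
    config.sim.seed = int(config.seed)

    def _write(name, fn):
        p = out / name
        fn(p)
        outputs.append(name)
        return p

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        trace = truth = None
        if "simulate" in config.stages:
            trace, truth = generate_breath_train(config.sim)
            dia, lar = synthesize_emg(truth, config.sim)
            _write("airflow.csv", lambda p: write_trace_csv(
                p, trace.samples, trace.rate))
            _write("truth_breaths.csv", lambda p: truth.breaths.to_csv(
                p, index=False, float_format=_FLOAT_FMT))
            _write("truth_syllables.csv", lambda p: truth.syllables.to_csv(
                p, index=False, float_format=_FLOAT_FMT))
            _write("truth_mini_breaths.csv",
                   lambda p: truth.mini_breaths.to_csv(
                       p, index=False, float_format=_FLOAT_FMT))
            _write("truth_jumps.csv", lambda p: truth.jumps.to_csv(
                p, index=False, float_format=_FLOAT_FMT))
            _write("config.yaml", lambda p: p.write_text(
                yaml.safe_dump(config.to_dict(), sort_keys=True)))
        timings[stage] = time.perf_counter() - t0

        stage = "breaths"
        breaths = None
        if "breaths" in config.stages and trace is not None:
            t0 = time.perf_counter()
            bp = config.breaths
            pre = preprocess_airflow(trace, bp["highpass_hz"], bp["smooth_ms"])
            breaths = segment_breaths(pre, bp["hysteresis_frac"],
                                      bp["min_breath_ms"])
            _write("breaths.csv", lambda p: compute_breath_features(
                breaths, pre).to_csv(p, index=False, float_format=_FLOAT_FMT))
            timings[stage] = time.perf_counter() - t0

        stage = "pitch"
        events, contours = [], []
        if "pitch" in config.stages and truth is not None and breaths:
            t0 = time.perf_counter()
            pp = config.pitch
            intervals = []
            for c in truth.contours:
                intervals.extend(detect_usv_events(c, pp["min_dur_ms"],
                                                   pp["max_gap_ms"]))
            events = group_syllables(intervals, breaths,
                                     pp["gap_threshold_ms"])
            for ev in events:
                for c in truth.contours:
                    if c.times[0] - 1e-9 <= ev.onset <= c.times[-1] + 1e-9:
                        ev.contour = c
                        break
                if ev.contour is not None:
                    ev.type_label = classify_contour(
                        ev, jump_threshold_khz=pp["jump_threshold_khz"])
            events = [e for e in events if e.contour is not None]
            _, metrics = label_vocal_breaths(breaths, events)
            _write("usv_events.csv", lambda p: write_usv_table(p, events))
            _write("usv_timing.csv", lambda p: timing_metrics_frame(
                metrics).to_csv(p, index=False, float_format=_FLOAT_FMT))
            timings[stage] = time.perf_counter() - t0

        stage = "intonation"
        if "intonation" in config.stages and len(events) >= 2:
            t0 = time.perf_counter()
            ip = config.intonation
            results, summary, _ = intonation_analysis(
                events, trace, n_perm=ip["n_perm"], seed=config.seed,
                alpha=ip["alpha"], min_bins=ip["min_bins"],
                per_type_min=ip["per_type_min"])
            _write("intonation_results.csv", lambda p: results_frame(
                results).to_csv(p, index=False, float_format=_FLOAT_FMT))
            _write("intonation_summary.csv", lambda p: summary.to_csv(
                p, index=False, float_format=_FLOAT_FMT))
            timings[stage] = time.perf_counter() - t0

        stage = "emg"
        if "emg" in config.stages and truth is not None and breaths:
            t0 = time.perf_counter()
            ep = config.emg
            dia_clean, _ = remove_ecg(dia)
            env_d = rectify_integrate(dia_clean, ep["cutoff_hz"])
            env_l = rectify_integrate(lar, ep["cutoff_hz"])
            bursts_d = detect_bursts(env_d, ep["threshold_frac"],
                                     ep["min_dur_ms"], ep["min_gap_ms"],
                                     channel="diaphragm")
            bursts_l = detect_bursts(env_l, ep["threshold_frac"],
                                     ep["min_dur_ms"], ep["min_gap_ms"],
                                     channel="laryngeal")
            pm = burst_phase_metrics(bursts_d, bursts_l, breaths,
                                     airflow=trace, dia_envelope=env_d,
                                     n_bins=ep["pdf_bins"],
                                     max_lag_ms=ep["max_lag_ms"])
            _write("emg_bursts.csv", lambda p: pd.DataFrame(
                [vars(b) for b in bursts_d + bursts_l]).to_csv(
                p, index=False, float_format=_FLOAT_FMT))
            _write("emg_phase_metrics.json", lambda p: p.write_text(
                json.dumps(dict(
                    cycles_per_expiration=pm.cycles_per_expiration,
                    cycles_per_expiration_plus1=pm.cycles_per_expiration_plus1,
                    inter_diaphragm_interval_ms=list(
                        pm.inter_diaphragm_interval_ms),
                    laryngeal_phase=list(pm.laryngeal_phase),
                    emg_lag_ms=pm.emg_lag_ms,
                    n_breaths_used=pm.n_breaths_used,
                    peak_time_pdf={k: list(v) for k, v
                                   in pm.peak_time_pdf.items()}),
                    indent=2)))
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(),
        seed=int(config.seed),
        input_digests={n: _digest(out / n) for n in outputs},
        stage_timings_s={k: round(v, 3) for k, v in timings.items()},
        warnings=warnings_, outputs=outputs)
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(asdict(manifest), indent=2))
    tmp.replace(out / "manifest.json")   # atomic finalization
    return manifest
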