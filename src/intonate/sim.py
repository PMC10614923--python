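"""Generative simulator of breath-coupled vocalization.

The simulator produces synthetic chamber airflow, pitch contours (optionally
rendered to audio), EMG and full ground truth for the two intonation
mechanisms:

* **Model 1 (breath modulation)** — the larynx holds a fixed narrow aperture
  ``a_c`` while the driving expiratory pressure fluctuates, notably through
  "mini-breaths": ectopic raised-cosine diaphragm bursts that transiently brake
  expiratory flow.  Pitch follows local airflow speed, so pitch and measured
  flow are *positively* correlated.
* **Model 2 (laryngeal constriction)** — the driving pressure is held constant
  while the laryngeal aperture ``a(t)`` narrows.  A narrower aperture speeds
  the local airflow (raising pitch) while impeding the overall measured flow,
  so pitch and measured flow are *negatively* correlated.

The quantitative convention is the minimal power-law family with these
properties: measured flow ``Q = P * a**beta`` with ``beta`` in (0, 1), local
velocity ``v = Q / a = P * a**(beta - 1)``, and pitch ``f`` affine in ``v``
(mapped into the syllable's target frequency band).  Under Model 1 (``a``
constant) ``f`` is exactly affine in ``Q``; under Model 2 (``P`` constant,
``a`` monotone) ``f`` rises while ``Q`` falls.  This is a simulator
phenomenology, not a claim about laryngeal fluid dynamics.

Register jumps (step/multi syllable types) are multiplicative steps applied to
``f`` only; measured flow is untouched, mirroring the observation that pitch
jumps have no airflow correlate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import substreams, smooth_noise, raised_cosine, runs_of_true
from .breath import AirflowTrace
from .pitch import PitchContour, SYLLABLE_TYPES

# aperture convention (arbitrary units): open airway vs phonatory constriction
A_OPEN = 1.0
A_CONSTRICT = 0.3
APERTURE_GATE = 0.6     # phonation requires a(t) < APERTURE_GATE * A_OPEN


def _default_mix() -> dict[str, float]:
    # endogenous relative abundances (most common first): up fm dominates,
    # down fm / step up / two step are rare
    return {"up fm": 0.32, "flat": 0.18, "step down": 0.16, "short": 0.09,
            "complex": 0.09, "chevron": 0.05, "multi": 0.04, "two step": 0.03,
            "down fm": 0.02, "step up": 0.02}


@dataclass
class SimConfig:
    """All tunable parameters of the simulator; defaults are the study
    conditions (vocal breaths at 7.5 Hz, sniffing at 8.5-10 Hz, 88/8/4%
    one/two/three syllables per breath, laryngeal phase 0.69, 1.5 mini-breath
    cycles per expiration, 10 ms EMG lead)."""

    duration_s: float = 60.0
    airflow_rate_hz: float = 1000.0
    audio_rate_hz: float = 250_000.0
    emg_rate_hz: float = 10_000.0
    breath_rate_hz: float = 7.5
    sniff_rate_hz: float = 9.0
    sniff_bout_prob: float = 0.25
    vocal_fraction: float = 0.35
    syllable_mix: dict = field(default_factory=_default_mix)
    syllable_count_probs: tuple = (0.88, 0.08, 0.04)
    beta: float = 0.5
    burst_depth_d: float = 0.9
    burst_width_ms: float = 25.0
    laryngeal_phase_phi: float = 0.69
    cycles_per_expiration: float = 1.5
    emg_lag_ms: float = 10.0
    ecg_rate_hz: float = 10.0
    airflow_noise: float = 0.01     # additive white sensor noise, airflow a.u.
    pitch_jitter_khz: float = 0.5   # white jitter on observed contours
    emg_noise: float = 0.05         # additive white noise on EMG channels
    flow_wiggle: float = 0.2        # breath-shape irregularity (rel. std of P0)
    aperture_wiggle: float = 0.3    # laryngeal motor noise (rel. std of a)
    wiggle_bandwidth_hz: float = 70.0  # bandwidth of both wiggle processes
    pitch_band_khz: tuple = (40.0, 120.0)
    ti_fraction: float = 0.4        # Ti as fraction of the breath period
    breath_jitter: float = 0.1      # rel. std of instantaneous breath frequency
    amp_jitter: float = 0.1         # rel. std of per-breath Pif/Pef
    pif: float = 1.0                # peak inspiratory flow, a.u.
    pef: float = 1.0                # peak expiratory flow, a.u.
    ti_s: float | None = None       # fixed Ti override (periodic test traces)
    te_s: float | None = None       # fixed Te override
    seed: int = 0

    def validate(self) -> None:
        for name in ("airflow_rate_hz", "audio_rate_hz", "emg_rate_hz",
                     "breath_rate_hz", "sniff_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")
        if not (0.0 < self.laryngeal_phase_phi < 1.0):
            raise ValueError("laryngeal_phase_phi must lie in (0, 1)")
        if not (0.0 <= self.burst_depth_d <= 1.5):
            raise ValueError("burst_depth_d must lie in [0, 1.5]")
        if not (0.0 <= self.vocal_fraction <= 1.0):
            raise ValueError("vocal_fraction must lie in [0, 1]")
        if abs(sum(self.syllable_mix.values()) - 1.0) > 1e-9:
            raise ValueError("syllable_mix probabilities must sum to 1")
        if abs(sum(self.syllable_count_probs) - 1.0) > 1e-9:
            raise ValueError("syllable_count_probs must sum to 1")
        unknown = set(self.syllable_mix) - set(SYLLABLE_TYPES)
        if unknown:
            raise ValueError(f"unknown syllable types in mix: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)


#: mechanisms a syllable type may be generated with ("none" — pitch drawn
#: independently of airflow — is available everywhere as a control condition)
ALLOWED_MECHANISMS: dict[str, set] = {
    "down fm": {"model1"}, "complex": {"model1"}, "chevron": {"model1"},
    "step down": {"model1"}, "multi": {"model1"},
    "two step": {"model1", "mixed"},
    "step up": {"model1", "model2", "mixed"},
    "up fm": {"model2"},
    "flat": {"model1", "model2"}, "short": {"model1", "model2"},
}
for _t in ALLOWED_MECHANISMS:
    ALLOWED_MECHANISMS[_t] = ALLOWED_MECHANISMS[_t] | {"none"}

DEFAULT_MECHANISM: dict[str, str] = {
    t: "model1" for t in SYLLABLE_TYPES} | {
    "up fm": "model2", "two step": "mixed", "step up": "mixed"}

# syllable contour templates: duration, target pitch band (kHz), window start
# as a fraction of Te, register jumps (fraction of window, multiplicative
# factor), and mini-breath policy
_TEMPLATES: dict[str, dict] = {
    "down fm":  dict(dur=0.050, band=(55, 85), start=(0.28, 0.45), bursts="pre"),
    "up fm":    dict(dur=0.055, band=(55, 95), start=(0.15, 0.30)),
    "chevron":  dict(dur=0.060, band=(60, 90), start=(0.02, 0.05)),
    "complex":  dict(dur=0.090, band=(55, 90), start=(0.20, 0.30), bursts="cycles"),
    "step down": dict(dur=0.045, band=(65, 82), start=(0.15, 0.30),
                      jumps=[(0.5, 0.78)]),
    "step up":  dict(dur=0.045, band=(60, 75), start=(0.15, 0.30),
                     jumps=[(0.5, 1.3)],
                     mixed=[(0.0, 0.5, "model2", (56, 68)),
                            (0.5, 1.0, "model1", (84, 95))]),
    "two step": dict(dur=0.070, band=(60, 75), start=(0.15, 0.30),
                     jumps=[(1 / 3, 1.3), (2 / 3, 0.75)],
                     mixed=[(0.0, 1 / 3, "model1", (62, 74)),
                            (1 / 3, 2 / 3, "model2", (84, 96)),
                            (2 / 3, 1.0, "model1", (60, 72))]),
    "multi":    dict(dur=0.080, band=(60, 75), start=(0.15, 0.30),
                     jumps=[(0.25, 1.3), (0.5, 0.75), (0.75, 1.3)]),
    "flat":     dict(dur=0.035, band=(70, 72), start=(0.10, 0.25)),
    "short":    dict(dur=0.008, band=(68, 74), start=(0.10, 0.25)),
}


@dataclass
class GroundTruth:
    """Everything the analysis stages are later asked to recover.

    Times in ``breaths``, ``syllables``, ``jumps`` and the contours are on the
    airflow/sound clock; ``mini_breaths`` and ``emg_bursts`` are on the EMG
    clock, which leads airflow and sound by ``config.emg_lag_ms``.
    """

    breaths: pd.DataFrame
    syllables: pd.DataFrame
    mini_breaths: pd.DataFrame
    jumps: pd.DataFrame
    signals: dict            # P, a, v, Q, f arrays at the airflow rate
    contours: list           # observed (jittered) PitchContour per vocal breath
    config: SimConfig
    emg_bursts: pd.DataFrame | None = None
    ecg_times: np.ndarray | None = None


def _pick(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = sorted(table)
    p = np.array([table[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


TAIL_FLOOR = 0.05   # late-expiratory flow plateau, fraction of Pef


def _expiration_baseline(n_e: int, fs: float, te: float, pef: float) -> np.ndarray:
    """Positive expiratory pressure: rise to ``pef`` at 0.12*Te, a slow
    quasi-exponential decline through mid-expiration (~30% drop over a
    syllable-length window), then a late return toward a small positive
    plateau.

    The plateau (``TAIL_FLOOR * pef``) keeps the inspiration onset a sharp,
    well-defined zero crossing instead of a noise-dominated graze; the gentle
    mid-expiratory decline matches the observation that airflow during a
    syllable varies moderately rather than collapsing.
    """
    s = (np.arange(n_e) + 1.0) / fs
    sp = 0.12 * te
    tau = 0.55 * te
    p = np.where(s < sp, pef * np.sin(0.5 * np.pi * s / sp),
                 pef * np.exp(-(s - sp) / tau))
    knee = 0.85 * te
    pk = pef * np.exp(-(knee - sp) / tau)
    ramp = np.clip((s - knee) / (0.97 * te - knee), 0.0, 1.0)
    p = np.where(s < knee, p, pk + (TAIL_FLOOR * pef - pk) * ramp)
    return np.maximum(p, TAIL_FLOOR * pef)


def _plan_syllables(types: list[str], mechanisms: list[str], te_base: float,
                    cfg: SimConfig, rng: np.random.Generator):
    """Place syllable windows in the expiration; extend Te when a window would
    run past 90% of it (vocalizing late in expiration prolongs the breath)."""
    tpl0 = _TEMPLATES[types[0]]
    lo, hi = tpl0["start"]
    t0 = (lo + (hi - lo) * rng.random()) * te_base
    windows = []
    cursor = t0
    for ty in types:
        dur = _TEMPLATES[ty]["dur"]
        windows.append((cursor, cursor + dur))
        cursor = cursor + dur + rng.uniform(0.025, 0.040)
    te = max(te_base, windows[-1][1] / 0.9)
    return windows, te


def _render_vocal_expiration(types, mechanisms, windows, te, pef, cfg, rng):
    """Build P, a, Q, v, f over one expiration carrying the given syllables.

    Returns arrays at the airflow rate plus syllable/jump/mini-breath records
    with times relative to expiration onset.
    """
    fs = cfg.airflow_rate_hz
    n_e = int(round(te * fs))
    # sample-aligned times: contour bins land exactly on airflow samples
    t = np.arange(n_e) / fs
    band_lo, band_hi = cfg.pitch_band_khz

    P = _expiration_baseline(n_e, fs, te, pef)
    P *= np.clip(1.0 + smooth_noise(rng, n_e, fs, cfg.wiggle_bandwidth_hz,
                                    cfg.flow_wiggle), 0.2, 1.8)
    P = np.maximum(P, TAIL_FLOOR * pef)

    # mini-breath bursts (model-1 machinery)
    mini_times: list[float] = []
    w = cfg.burst_width_ms / 1000.0
    for ty, mech, (t0, t1) in zip(types, mechanisms, windows):
        policy = _TEMPLATES[ty].get("bursts")
        if mech not in ("model1",) or policy is None:
            continue
        if policy == "pre":          # single burst ending at phonation onset
            mini_times.append(t0 - w / 2 - 0.001)
        elif policy == "cycles":     # 1 + Bernoulli(cycles - 1) bursts inside
            n_b = 1 + int(rng.random() < (cfg.cycles_per_expiration - 1.0))
            c = t0 + rng.uniform(0.008, 0.015)
            for _ in range(n_b):
                if c + w / 2 < t1:
                    mini_times.append(c)
                c += 0.043 + rng.normal(0.0, 0.004)
    if mini_times:
        burst_sum = np.zeros(n_e)
        for tk in mini_times:
            burst_sum += raised_cosine(t, tk, w)
        P *= np.maximum(1.0 - cfg.burst_depth_d * burst_sum, -0.5)

    # aperture trajectory: abrupt laryngeal adduction at the window edges
    a = np.full(n_e, A_OPEN)
    seg_records = []   # (i0, i1, mechanism, band) spans in samples
    for ty, mech, (t0, t1) in zip(types, mechanisms, windows):
        tpl = _TEMPLATES[ty]
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n_e)
        if i1 - i0 < 2:
            continue
        segs = (tpl["mixed"] if mech == "mixed"
                else [(0.0, 1.0, mech, tpl["band"])])
        win = np.full(i1 - i0, A_CONSTRICT)
        u_win = (np.arange(i1 - i0) + 0.5) / (i1 - i0)
        for (u0, u1, smech, sband) in segs:
            sm = np.flatnonzero((u_win >= u0) & (u_win < u1))
            j0, j1 = i0 + int(sm[0]), i0 + int(sm[-1]) + 1
            if smech == "model2":
                depth = rng.uniform(0.4, 0.8)
                useg = (np.arange(j1 - j0) + 0.5) / (j1 - j0)
                prof = (1.0 - depth * useg) * np.clip(
                    1.0 + smooth_noise(rng, j1 - j0, fs,
                                       cfg.wiggle_bandwidth_hz,
                                       cfg.aperture_wiggle), 0.3, 1.7)
                win[j0 - i0:j1 - i0] = A_CONSTRICT * np.clip(prof, 0.05, None)
                # constant driving pressure inside a model-2 segment
                P[j0:j1] = float(np.mean(P[j0:j1]))
            seg_records.append((j0, j1, smech, sband))
        a[i0:i1] = win

    Q = P * a ** cfg.beta
    v = Q / a
    gate = (a < APERTURE_GATE * A_OPEN) & (Q > 0)

    # pitch: per-segment affine map of the mechanism's source signal
    f = np.full(n_e, np.nan)
    jump_rows = []
    syl_rows = []
    for (ty, mech, (t0, t1)), segs in zip(
            zip(types, mechanisms, windows),
            _group_segments(seg_records, windows, fs)):
        tpl = _TEMPLATES[ty]
        for (j0, j1, smech, sband) in segs:
            m = np.zeros(n_e, dtype=bool)
            m[j0:j1] = gate[j0:j1]
            if m.sum() < 2:
                continue
            if smech == "model1":
                src = Q[m]
            elif smech == "model2":
                src = v[m]
            else:  # independent pitch: smooth noise, unrelated to airflow
                src = smooth_noise(rng, int(m.sum()), fs, 60.0, 1.0) \
                    + np.linspace(0, rng.normal(0, 1), int(m.sum()))
            lo, hi = sband
            rngv = src.max() - src.min()
            if rngv <= 0:
                f[m] = 0.5 * (lo + hi)
            else:
                f[m] = lo + (hi - lo) * (src - src.min()) / rngv
        # register jumps: multiplicative steps on f, airflow untouched
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n_e)
        if mech in ("model1", "none"):
            for (frac, factor) in tpl.get("jumps", []):
                jidx = i0 + int(round(frac * (i1 - i0)))
                before = f[jidx - 1] if np.isfinite(f[jidx - 1]) else np.nan
                f[jidx:i1] = np.where(np.isfinite(f[jidx:i1]),
                                      f[jidx:i1] * factor, np.nan)
                after = f[jidx] if np.isfinite(f[jidx]) else np.nan
                jump_rows.append(dict(time=t[jidx], size_khz=after - before,
                                      kind="register"))
        elif mech == "mixed":
            for (u0, _u1, _m, _b) in tpl["mixed"][1:]:
                jidx = i0 + int(round(u0 * (i1 - i0)))
                if np.isfinite(f[jidx]) and np.isfinite(f[jidx - 1]):
                    jump_rows.append(dict(time=t[jidx],
                                          size_khz=f[jidx] - f[jidx - 1],
                                          kind="switch"))
        # syllable records from the phonation gate within the window
        wmask = np.zeros(n_e, dtype=bool)
        wmask[i0:i1] = gate[i0:i1] & np.isfinite(f[i0:i1])
        for (r0, r1) in runs_of_true(wmask):
            syl_rows.append(dict(onset=r0 / fs, offset=r1 / fs, type=ty,
                                 mechanism=mech))
    f = np.clip(f, band_lo, band_hi)
    phon = np.isfinite(f)
    return dict(P=P, a=a, Q=Q, v=v, f=f, phonation=phon, t=t,
                syllables=syl_rows, jumps=jump_rows, mini_times=mini_times)


def _balance_tidal_volume(insp: np.ndarray, exp: dict) -> float:
    """Scale the expiration so expired volume equals inspired volume.

    Breathing conserves tidal volume, so the per-breath flow integral is ~0;
    this keeps slow high-pass filtering from shifting the zero-flow baseline
    around vocal breaths.  P, Q and v scale together (a is untouched), which
    preserves Q = P*a**beta, v = Q/a and every correlation exactly.
    """
    vol_in = -float(insp.sum())
    vol_out = float(exp["Q"].sum())
    if vol_out <= 0:
        return 1.0
    s = float(np.clip(vol_in / vol_out, 0.3, 3.0))
    for k in ("P", "Q", "v"):
        exp[k] = exp[k] * s
    return s


def _group_segments(seg_records, windows, fs):
    """Regroup flat segment records by owning window, in order."""
    out = []
    for (t0, t1) in windows:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        out.append([s for s in seg_records if i0 <= s[0] < i1])
    return out


def generate_vocal_breath(syllable_type: str, mechanism: str, config: SimConfig,
                          rng: np.random.Generator | None = None):
    """One standalone vocal breath: (AirflowTrace, observed PitchContour, record).

    The record carries the noise-free ground truth (P, a, v, Q, f arrays,
    syllable intervals, jump and mini-breath times).  Times are relative to
    the breath's inspiration onset; no EMG lag is applied at this level.
    """
    config.validate()
    if syllable_type not in _TEMPLATES:
        raise ValueError(f"unknown syllable type {syllable_type!r}")
    if mechanism not in ALLOWED_MECHANISMS[syllable_type]:
        raise ValueError(f"mechanism {mechanism!r} is not valid for "
                         f"{syllable_type!r} (allowed: "
                         f"{sorted(ALLOWED_MECHANISMS[syllable_type])})")
    if rng is None:
        rng = substreams(config.seed, 1)[0]
    fs = config.airflow_rate_hz
    period = 1.0 / config.breath_rate_hz
    ti = config.ti_s if config.ti_s is not None else config.ti_fraction * period
    te_base = (config.te_s if config.te_s is not None
               else (1 - config.ti_fraction) * period)
    pif = config.pif * float(np.exp(rng.normal(0, config.amp_jitter)))
    pef = config.pef * float(np.exp(rng.normal(0, config.amp_jitter)))
    windows, te = _plan_syllables([syllable_type], [mechanism], te_base,
                                  config, rng)
    n_i = int(round(ti * fs))
    insp = -pif * np.sin(np.pi * (np.arange(n_i) + 0.5) / n_i)
    exp = _render_vocal_expiration([syllable_type], [mechanism], windows, te,
                                   pef, config, rng)
    pef *= _balance_tidal_volume(insp, exp)
    x = np.concatenate([insp, exp["Q"]])
    if config.airflow_noise > 0:
        x = x + rng.normal(0.0, config.airflow_noise, x.size)
    trace = AirflowTrace(samples=x, rate=fs, start_time=0.0)
    t_exp0 = n_i / fs
    times = t_exp0 + exp["t"]
    f_hz = exp["f"] * 1000.0
    valid = exp["phonation"].copy()
    f_obs = f_hz + np.where(valid,
                            rng.normal(0.0, config.pitch_jitter_khz * 1000.0,
                                       f_hz.size), 0.0)
    contour = PitchContour(times=times, f_peak=np.where(valid, f_obs, np.nan),
                           peak_power=valid.astype(float), valid=valid)
    record = dict(
        insp_onset=0.0, exp_onset=t_exp0, end=t_exp0 + exp["Q"].size / fs,
        Ti=n_i / fs, Te=exp["Q"].size / fs, Pif=pif, Pef=pef,
        syllables=[{**s, "onset": s["onset"] + t_exp0,
                    "offset": s["offset"] + t_exp0} for s in exp["syllables"]],
        jumps=[{**j, "time": j["time"] + t_exp0} for j in exp["jumps"]],
        mini_times=[mt + t_exp0 for mt in exp["mini_times"]],
        P=np.concatenate([insp, exp["P"]]),
        a=np.concatenate([np.full(n_i, A_OPEN), exp["a"]]),
        Q=np.concatenate([insp, exp["Q"]]),
        v=np.concatenate([insp, exp["v"]]),
        f_khz=np.concatenate([np.full(n_i, np.nan), exp["f"]]),
        type=syllable_type, mechanism=mechanism,
    )
    return trace, contour, record


def generate_breath_train(config: SimConfig):
    """Full session: (AirflowTrace, GroundTruth), deterministic given the seed.

    Breaths are concatenated cycles (negative half-sine inspiration, positive
    decaying expiration); a configured fraction carry syllables, and episodes
    of rapid sniffing are interleaved.  Airflow (and hence every sound-clock
    time stamp) is delayed by ``emg_lag_ms`` relative to the EMG clock on
    which mini-breath and EMG burst times are reported.
    """
    config.validate()
    fs = config.airflow_rate_hz
    period_min = (config.ti_s or 0.0) + (config.te_s or 0.0) \
        or 1.0 / config.breath_rate_hz
    if config.duration_s < period_min:
        raise ValueError("duration_s too short to hold one breath")
    r_struct, r_shape, r_noise, r_pitch = substreams(config.seed, 4)
    n_total = int(round(config.duration_s * fs))
    lag_n = int(round(config.emg_lag_ms / 1000.0 * fs))
    pieces = [np.zeros(lag_n)]
    sig = {k: [np.full(lag_n, np.nan) if k == "f" else np.zeros(lag_n)]
           for k in ("P", "a", "v", "Q", "f")}
    sig["a"][0][:] = A_OPEN
    breath_rows, syl_rows, mini_rows, jump_rows, contours = [], [], [], [], []
    cursor = lag_n          # sample index on the airflow clock
    sniff_left = 0
    usv_id = 0
    while True:
        in_sniff = sniff_left > 0
        if not in_sniff and r_struct.random() < config.sniff_bout_prob:
            sniff_left = int(r_struct.integers(5, 13))
            in_sniff = True
        vocal = r_struct.random() < config.vocal_fraction
        rate = config.sniff_rate_hz if (in_sniff and not vocal) \
            else config.breath_rate_hz
        f_b = float(np.clip(r_struct.normal(rate, config.breath_jitter * rate),
                            0.5 * rate, 1.5 * rate))
        period = 1.0 / f_b
        ti = config.ti_s if config.ti_s is not None else config.ti_fraction * period
        te = config.te_s if config.te_s is not None \
            else (1 - config.ti_fraction) * period
        pif = config.pif * float(np.exp(r_shape.normal(0, config.amp_jitter))) \
            if config.amp_jitter else config.pif
        pef = config.pef * float(np.exp(r_shape.normal(0, config.amp_jitter))) \
            if config.amp_jitter else config.pef
        types, mechanisms, windows = [], [], []
        if vocal:
            n_syl = 1 + int(r_struct.choice(3, p=np.asarray(
                config.syllable_count_probs, dtype=float)))
            types = [_pick(r_struct, config.syllable_mix) for _ in range(n_syl)]
            mechanisms = [DEFAULT_MECHANISM[t] for t in types]
            windows, te = _plan_syllables(types, mechanisms, te, config,
                                          r_shape)
        n_i = int(round(ti * fs))
        n_e = int(round(te * fs))
        if n_i < 2 or n_e < 2 or cursor + n_i + n_e > n_total:
            break
        insp = -pif * np.sin(np.pi * (np.arange(n_i) + 0.5) / n_i)
        if vocal:
            exp = _render_vocal_expiration(types, mechanisms, windows, te, pef,
                                           config, r_shape)
        else:
            p_e = _expiration_baseline(n_e, fs, te, pef)
            p_e = p_e * np.clip(1.0 + smooth_noise(
                r_shape, n_e, fs, config.wiggle_bandwidth_hz,
                config.flow_wiggle), 0.2, 1.8)
            p_e = np.maximum(p_e, TAIL_FLOOR * pef)
            a_e = np.full(n_e, A_OPEN)
            exp = dict(P=p_e, a=a_e, Q=p_e * a_e ** config.beta,
                       v=p_e * a_e ** (config.beta - 1.0),
                       f=np.full(n_e, np.nan))
        pef *= _balance_tidal_volume(insp, exp)
        q_e, p_e, a_e, v_e, f_e = (exp["Q"], exp["P"], exp["a"], exp["v"],
                                   exp["f"])
        t_insp = cursor / fs
        t_exp = (cursor + n_i) / fs
        breath_rows.append(dict(
            breath_index=len(breath_rows), insp_onset=t_insp, exp_onset=t_exp,
            end=t_exp + n_e / fs, Ti=n_i / fs, Te=n_e / fs, Pif=pif, Pef=pef,
            f_inst=1.0 / (n_i / fs + n_e / fs), is_vocal=vocal,
            in_sniff_bout=in_sniff))
        if vocal:
            bi = len(breath_rows) - 1
            for s in exp["syllables"]:
                syl_rows.append(dict(usv_id=usv_id, breath_index=bi,
                                     onset=t_exp + s["onset"],
                                     offset=t_exp + s["offset"],
                                     type=s["type"], mechanism=s["mechanism"]))
            for j in exp["jumps"]:
                jump_rows.append(dict(usv_id=usv_id, time=t_exp + j["time"],
                                      size_khz=j["size_khz"], kind=j["kind"]))
            for mt in exp["mini_times"]:
                # mini-breath times on the EMG clock (leads airflow by the lag)
                mini_rows.append(dict(breath_index=bi,
                                      time=t_exp + mt - lag_n / fs))
            valid = exp["phonation"]
            if valid.any():
                f_hz = exp["f"] * 1000.0
                jit = r_pitch.normal(0.0, config.pitch_jitter_khz * 1000.0,
                                     f_hz.size)
                contours.append(PitchContour(
                    times=t_exp + exp["t"],
                    f_peak=np.where(valid, f_hz + jit, np.nan),
                    peak_power=valid.astype(float), valid=valid.copy()))
                usv_id += 1
        pieces.append(np.concatenate([insp, q_e]))
        sig["P"].append(np.concatenate([insp, p_e]))
        sig["a"].append(np.concatenate([np.full(n_i, A_OPEN), a_e]))
        sig["Q"].append(np.concatenate([insp, q_e]))
        sig["v"].append(np.concatenate([insp, v_e]))
        sig["f"].append(np.concatenate([np.full(n_i, np.nan), f_e]))
        cursor += n_i + n_e
        if in_sniff:
            sniff_left = max(sniff_left - 1, 0)
    if not breath_rows:
        raise ValueError("duration too short to hold one breath")
    pad = n_total - cursor
    x = np.concatenate(pieces + [np.zeros(pad)])
    if config.airflow_noise > 0:
        x = x + r_noise.normal(0.0, config.airflow_noise, x.size)
    signals = {k: np.concatenate(sig[k] + [np.full(pad, np.nan) if k == "f"
                                           else np.zeros(pad)])
               for k in sig}
    if pad:
        signals["a"][-pad:] = A_OPEN
    truth = GroundTruth(
        breaths=pd.DataFrame(breath_rows),
        syllables=pd.DataFrame(syl_rows, columns=[
            "usv_id", "breath_index", "onset", "offset", "type", "mechanism"]),
        mini_breaths=pd.DataFrame(mini_rows, columns=["breath_index", "time"]),
        jumps=pd.DataFrame(jump_rows, columns=["usv_id", "time", "size_khz",
                                               "kind"]),
        signals=signals, contours=contours, config=config)
    return AirflowTrace(samples=x, rate=fs, start_time=0.0), truth


def simulate_usv_dataset(n: int, types, mechanism: str, config: SimConfig,
                         seed: int = 0):
    """``n`` standalone vocal breaths cycling through ``types`` under one
    mechanism; returns a list of (AirflowTrace, PitchContour, record)."""
    types = list(types)
    rngs = substreams(seed, n)
    out = []
    for k in range(n):
        out.append(generate_vocal_breath(types[k % len(types)], mechanism,
                                         config, rng=rngs[k]))
    return out


def synthesize_audio(contour: PitchContour, config: SimConfig,
                     duration_s: float | None = None, start_time: float = 0.0,
                     noise_floor: float = 0.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Phase-continuous FM tone following a pitch contour.

    Amplitude is gated to the contour's valid (phonation) bins; the waveform is
    zero elsewhere.  An empty contour yields silence of the requested length.
    """
    fs = config.audio_rate_hz
    if duration_s is None:
        duration_s = (float(contour.times[-1]) - start_time
                      + 0.002) if contour.times.size else 0.0
    n = int(round(duration_s * fs))
    t = start_time + np.arange(n) / fs
    if not np.any(contour.valid):
        wave = np.zeros(n)
    else:
        tv = contour.times[contour.valid]
        fv = contour.f_peak[contour.valid]
        if np.nanmax(fv) >= fs / 2:
            raise ValueError("contour frequency at or above Nyquist")
        f_inst = np.interp(t, tv, fv, left=fv[0], right=fv[-1])
        dt = float(np.median(np.diff(contour.times))) if contour.times.size > 1 \
            else 1e-3
        gate = np.zeros(n)
        for (a, b) in runs_of_true(contour.valid):
            gate += ((t >= contour.times[a] - dt / 2)
                     & (t < contour.times[b - 1] + dt / 2))
        gate = np.clip(gate, 0, 1)
        phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
        wave = gate * np.sin(phase)
    if noise_floor > 0:
        if rng is None:
            rng = substreams(config.seed, 1)[0]
        wave = wave + rng.normal(0.0, noise_floor, n)
    return wave


def _ecg_template(rate: float) -> np.ndarray:
    """Stereotyped biphasic spike, ~4 ms total."""
    n = max(int(round(0.004 * rate)), 4)
    u = np.linspace(0, 1, n)
    return 5.0 * np.sin(2 * np.pi * u) * np.exp(-((u - 0.35) / 0.25) ** 2)


def synthesize_emg(truth: GroundTruth, config: SimConfig,
                   rng: np.random.Generator | None = None):
    """Diaphragm and laryngeal EMG traces consistent with the ground truth.

    Band-limited noise carriers are multiplied by burst envelopes: the
    diaphragm bursts at every inspiration and every mini-breath; the larynx
    bursts at fraction ``laryngeal_phase_phi`` of each local
    diaphragm-to-diaphragm interval.  ECG contamination (regular biphasic
    spikes at ``ecg_rate_hz``) is added to the diaphragm channel.  All burst
    times are on the EMG clock, which leads airflow/sound by ``emg_lag_ms``;
    the burst annotations are appended to ``truth.emg_bursts``.
    """
    from .emg import EmgTrace   # local import to avoid a cycle
    cfg = config
    fs = cfg.emg_rate_hz
    if rng is None:
        rng = substreams(cfg.seed + 1, 1)[0]
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    lag = cfg.emg_lag_ms / 1000.0

    dia_bursts, lar_bursts = [], []
    for _, b in truth.breaths.iterrows():
        c = 0.5 * (b.insp_onset + b.exp_onset) - lag
        dia_bursts.append((c, 0.8 * b.Ti, 1.0))
    for _, m in truth.mini_breaths.iterrows():
        dia_bursts.append((m.time, cfg.burst_width_ms / 1000.0, 0.8))
    dia_bursts.sort()
    peaks = np.array([c for c, _, _ in dia_bursts])
    for k in range(len(peaks) - 1):
        gap = peaks[k + 1] - peaks[k]
        if gap < 0.4:
            lar_bursts.append((peaks[k] + cfg.laryngeal_phase_phi * gap,
                               0.020, 1.0))

    def envelope(bursts):
        env = np.zeros(n)
        for c, w, amp in bursts:
            i0 = max(int((c - w / 2) * fs) - 1, 0)
            i1 = min(int((c + w / 2) * fs) + 2, n)
            if i1 > i0:
                env[i0:i1] += amp * raised_cosine(t[i0:i1], c, w)
        return np.clip(env, 0, None)

    def carrier():
        from scipy import signal as sps
        x = rng.standard_normal(n)
        sos = sps.butter(4, [300 / (fs / 2), 3000 / (fs / 2)], "bandpass",
                         output="sos")
        y = sps.sosfiltfilt(sos, x)
        return y / y.std()

    dia = envelope(dia_bursts) * carrier() + cfg.emg_noise * rng.standard_normal(n)
    lar = envelope(lar_bursts) * carrier() + cfg.emg_noise * rng.standard_normal(n)

    ecg_times = np.array([])
    if cfg.ecg_rate_hz > 0:
        ecg_times = np.arange(0.0, cfg.duration_s, 1.0 / cfg.ecg_rate_hz)
        tmpl = _ecg_template(fs)
        for tk in ecg_times:
            i = int(round(tk * fs))
            j = min(i + tmpl.size, n)
            dia[i:j] += tmpl[:j - i]
    rows = ([dict(channel="diaphragm", onset=c - w / 2, peak_time=c,
                  offset=c + w / 2, amp=a) for c, w, a in dia_bursts]
            + [dict(channel="laryngeal", onset=c - w / 2, peak_time=c,
                    offset=c + w / 2, amp=a) for c, w, a in lar_bursts])
    truth.emg_bursts = pd.DataFrame(rows, columns=["channel", "onset",
                                                   "peak_time", "offset",
                                                   "amp"])
    truth.ecg_times = ecg_times
    return (EmgTrace(samples=dia, rate=fs, channel="diaphragm"),
            EmgTrace(samples=lar, rate=fs, channel="laryngeal"))
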