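"""EMG envelopes, ECG artifact removal, burst detection and breath-phase stats.

The diaphragm drives inspiration; laryngeal muscles (thyroarytenoid and
cricothyroid) are active in post-inspiration and during phonation.  Raw EMG is
full-wave rectified and integrated with a Paynter-style critically damped
low-pass to form an envelope; bursts are threshold excursions of that
envelope.  Phase statistics locate bursts within the normalized expiration and
between channels: mini-breath cycles per expiration, the inter-diaphragm-burst
interval, the laryngeal burst phase within the diaphragm-to-diaphragm
interval, and the lag of airflow behind EMG.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)


@dataclass
class EmgTrace:
    samples: np.ndarray
    rate: float = 10_000.0
    channel: str = "diaphragm"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate


@dataclass
class EmgEnvelope:
    samples: np.ndarray
    rate: float
    filter_params: tuple    # (order, cutoff_hz)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < -1e-9):
            raise ValueError("envelope must be nonnegative")
        self.samples = np.clip(self.samples, 0.0, None)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate


@dataclass
class BurstEvent:
    channel: str
    onset: float
    peak_time: float
    offset: float
    peak_amplitude: float

    def __post_init__(self) -> None:
        if not (self.onset <= self.peak_time <= self.offset):
            raise ValueError("burst peak must lie within [onset, offset]")


@dataclass
class PhaseMetrics:
    cycles_per_expiration: float          # mean ectopic diaphragm bursts
    cycles_per_expiration_plus1: float    # same counting the breath's own cycle
    inter_diaphragm_interval_ms: tuple    # (mean, sd)
    laryngeal_phase: tuple                # (mean, sd), fraction of dia-dia gap
    peak_time_pdf: dict                   # channel -> normalized histogram
    pdf_bin_edges: np.ndarray
    emg_lag_ms: float | None
    n_breaths_used: int
    n_breaths_skipped: int


def remove_ecg(trace: EmgTrace, annotations=None,
               isi_cv_max: float = 0.2) -> tuple[EmgTrace, np.ndarray]:
    """Remove ECG contamination from a diaphragm EMG trace.

    With ``annotations`` (list of (start_s, end_s) spans) the annotated spans
    are replaced by linear interpolation — the authoritative path when manual
    annotations exist.  Without annotations the heartbeat is detected
    automatically: large-amplitude candidate spikes are screened for rate
    regularity (coefficient of variation of the inter-spike interval below
    ``isi_cv_max``), a spike template is averaged from them, and a matched
    filter recovers the full train, which is then interpolated out.  Returns
    the cleaned trace and the detected/annotated spike times.  Laryngeal
    traces pass through unchanged.
    """
    if trace.channel != "diaphragm":
        return trace, np.array([])
    x = trace.samples.copy()
    fs = trace.rate
    if annotations is not None:
        spans = [(float(a), float(b)) for a, b in annotations]
        covered = sum(b - a for a, b in spans)
        if covered >= x.size / fs - 1e-9:
            log.warning("ECG annotations cover the entire trace; the result "
                        "is fully interpolated")
        for a, b in spans:
            i, j = int(round((a - trace.start_time) * fs)), \
                int(round((b - trace.start_time) * fs))
            i, j = max(i, 0), min(j, x.size)
            if j <= i:
                continue
            x0 = x[i - 1] if i > 0 else x[j] if j < x.size else 0.0
            x1 = x[j] if j < x.size else x0
            x[i:j] = np.linspace(x0, x1, j - i + 2)[1:-1]
        return replace(trace, samples=x), np.array(
            [0.5 * (a + b) for a, b in spans])
    # automatic detection.  The heartbeat spike is slower than the 300 Hz -
    # 20 kHz EMG band, so a low-pass strongly favors ECG over muscle bursts.
    if x.size == 0 or np.all(x == 0):
        return replace(trace, samples=x), np.array([])
    sos = sps.butter(4, min(250.0 / (fs / 2), 0.9), "lowpass", output="sos")
    y = np.abs(sps.sosfiltfilt(sos, x))
    h = 0.5 * np.percentile(y, 99.9)
    cand, _ = sps.find_peaks(y, height=h, distance=int(0.030 * fs))
    if cand.size < 4:
        return replace(trace, samples=x), np.array([])
    isi = np.diff(cand) / fs
    med = np.median(isi)
    reg = isi[np.abs(isi - med) < 0.3 * med]
    if reg.size < 3 or reg.std() / reg.mean() > isi_cv_max:
        log.info("no regular large-amplitude spike train found; trace "
                 "returned unchanged")
        return replace(trace, samples=x), np.array([])
    # a heartbeat spike is itself a low-frequency event, so at a true ECG peak
    # the low-passed amplitude approaches the broadband amplitude; a residual
    # of a (band-limited) muscle burst keeps only a small fraction.  Gate on
    # that concentration ratio so regular breathing bursts are not mistaken
    # for a heartbeat.
    half3 = int(0.003 * fs)
    ratios = [y[c] / (np.abs(x[max(c - half3, 0):c + half3]).max() + 1e-12)
              for c in cand]
    if np.median(ratios) < 0.15:
        log.info("periodic events are broadband muscle bursts, not ECG; "
                 "trace returned unchanged")
        return replace(trace, samples=x), np.array([])
    # template from candidate windows, then matched filter over the raw trace
    half = int(0.003 * fs)
    wins = [x[c - half:c + half] for c in cand
            if c - half >= 0 and c + half <= x.size]
    tmpl = np.mean(wins, axis=0)
    tmpl = tmpl - tmpl.mean()
    corr = np.correlate(x, tmpl, mode="same")
    corr /= np.abs(corr).max()
    spikes, _ = sps.find_peaks(corr, height=0.4,
                               distance=int(0.6 * med * fs))
    times = trace.start_time + spikes / fs
    pad = int(0.0035 * fs)
    for c in spikes:
        i, j = max(c - pad, 0), min(c + pad, x.size)
        x0 = x[i - 1] if i > 0 else x[j - 1]
        x1 = x[j] if j < x.size else x[i]
        x[i:j] = np.linspace(x0, x1, j - i + 2)[1:-1]
    return replace(trace, samples=x), times


def _paynter_sos(cutoff_hz: float, fs: float):
    """Third-order critically damped low-pass (triple real pole), DC gain 1.

    The pole is placed so the single-pass -3 dB point sits at ``cutoff_hz``
    (for a triple pole that is at ``w_c / sqrt(2**(1/3) - 1)``).
    """
    a = 2.0 * np.pi * cutoff_hz / np.sqrt(2.0 ** (1.0 / 3.0) - 1.0)
    z, p, k = [], [-a, -a, -a], a ** 3
    return sps.zpk2sos(*sps.bilinear_zpk(z, p, k, fs))


def rectify_integrate(trace: EmgTrace, cutoff_hz: float = 40.0) -> EmgEnvelope:
    """Full-wave rectification then zero-phase Paynter-style integration.

    The smoothing filter is a third-order critically damped low-pass applied
    forward-backward (zero phase, unit DC gain); 40 Hz retains burst timing at
    breathing timescales while removing the carrier.
    """
    if cutoff_hz >= trace.rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    rect = np.abs(trace.samples)
    if rect.size == 0:
        return EmgEnvelope(samples=rect, rate=trace.rate,
                           filter_params=(3, cutoff_hz),
                           start_time=trace.start_time)
    sos = _paynter_sos(cutoff_hz, trace.rate)
    env = sps.sosfiltfilt(sos, rect)
    return EmgEnvelope(samples=np.clip(env, 0.0, None), rate=trace.rate,
                       filter_params=(3, cutoff_hz),
                       start_time=trace.start_time)


def detect_bursts(env: EmgEnvelope, threshold_frac: float = 0.3,
                  min_dur_ms: float = 10.0, min_gap_ms: float = 10.0,
                  channel: str = "") -> list[BurstEvent]:
    """Threshold excursions of the envelope as bursts.

    The threshold is ``threshold_frac`` of the robust envelope maximum (95th
    percentile), so detection is invariant to positive rescaling.  Excursions
    closer than ``min_gap_ms`` are merged; those shorter than ``min_dur_ms``
    discarded.  The burst peak is the envelope argmax within the excursion.
    """
    x = env.samples
    if x.size == 0:
        return []
    robust_max = np.percentile(x, 95)
    if robust_max <= 0:
        # sparse envelope (rare bursts on a silent floor): fall back to the max
        robust_max = float(x.max())
    if robust_max <= 0:
        return []
    thr = threshold_frac * robust_max
    above = x > thr
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(x.size)
    runs = list(zip(starts, stops))
    gap = min_gap_ms / 1000.0 * env.rate
    merged = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        if (b - a) / env.rate * 1000.0 < min_dur_ms:
            continue
        k = a + int(np.argmax(x[a:b]))
        out.append(BurstEvent(
            channel=channel, onset=env.start_time + a / env.rate,
            peak_time=env.start_time + k / env.rate,
            offset=env.start_time + b / env.rate,
            peak_amplitude=float(x[k])))
    return out


def burst_phase_metrics(dia: list[BurstEvent], lar: list[BurstEvent],
                        breaths, airflow=None, dia_envelope=None,
                        n_bins: int = 20, vocal_only: bool = True,
                        max_lag_ms: float = 50.0) -> PhaseMetrics:
    """Burst timing relative to the breath and between channels.

    For each (vocal) breath, ectopic diaphragm bursts are diaphragm peaks
    falling within the expiration; ``cycles_per_expiration`` is their mean
    count (the ``_plus1`` variant counts the breath's own inspiratory cycle as
    well — both countings are reported, the plain count being the default
    reading).  The laryngeal phase is (lar_peak - dia_peak_k) /
    (dia_peak_{k+1} - dia_peak_k) for laryngeal peaks inside a
    diaphragm-to-diaphragm interval.  Peak-time PDFs are histograms over the
    normalized expiration (t - exp_onset)/Te.  When ``airflow`` and
    ``dia_envelope`` are given, the EMG lead over airflow is estimated as the
    argmax of the cross-correlation between the diaphragm envelope and the
    inspiratory airflow magnitude within ±``max_lag_ms``.
    """
    dia_peaks = np.array(sorted(b.peak_time for b in dia))
    lar_peaks = np.array(sorted(b.peak_time for b in lar))
    sel = [b for b in breaths if (b.is_vocal or not vocal_only)]
    ect_counts, intervals, phases = [], [], []
    pdf_counts = {"diaphragm": np.zeros(n_bins), "laryngeal": np.zeros(n_bins)}
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    skipped = 0
    for b in sel:
        in_exp_d = dia_peaks[(dia_peaks >= b.exp_onset) & (dia_peaks < b.end)]
        in_exp_l = lar_peaks[(lar_peaks >= b.exp_onset) & (lar_peaks < b.end)]
        if in_exp_d.size == 0 and in_exp_l.size == 0:
            skipped += 1
            continue
        ect_counts.append(in_exp_d.size)
        # diaphragm peaks framing this breath (own inspiratory burst included)
        frame = dia_peaks[(dia_peaks >= b.insp_onset - 0.5 * b.Ti)
                          & (dia_peaks < b.end)]
        intervals.extend(np.diff(frame))
        for lp in in_exp_l:
            k = np.searchsorted(frame, lp) - 1
            if 0 <= k < frame.size - 1:
                phases.append((lp - frame[k]) / (frame[k + 1] - frame[k]))
        for ch, pk in (("diaphragm", in_exp_d), ("laryngeal", in_exp_l)):
            u = (pk - b.exp_onset) / b.Te
            pdf_counts[ch] += np.histogram(u, bins=edges)[0]
    pdf = {}
    for ch, c in pdf_counts.items():
        pdf[ch] = c / c.sum() if c.sum() > 0 else c
    lag_ms = None
    if airflow is not None and dia_envelope is not None:
        lag_ms = estimate_emg_lag(dia_envelope, airflow, max_lag_ms=max_lag_ms)
    phases = np.array(phases)
    intervals = np.array(intervals) * 1000.0
    return PhaseMetrics(
        cycles_per_expiration=float(np.mean(ect_counts)) if ect_counts else 0.0,
        cycles_per_expiration_plus1=(float(np.mean(ect_counts)) + 1.0
                                     if ect_counts else 1.0),
        inter_diaphragm_interval_ms=(float(intervals.mean()),
                                     float(intervals.std()))
        if intervals.size else (np.nan, np.nan),
        laryngeal_phase=(float(phases.mean()), float(phases.std()))
        if phases.size else (np.nan, np.nan),
        peak_time_pdf=pdf, pdf_bin_edges=edges, emg_lag_ms=lag_ms,
        n_breaths_used=len(ect_counts), n_breaths_skipped=skipped)


def estimate_emg_lag(dia_envelope: EmgEnvelope, airflow,
                     max_lag_ms: float = 50.0) -> float:
    """Lead of diaphragm EMG over inspiratory airflow, in milliseconds.

    The envelope is block-averaged onto the airflow rate and cross-correlated
    with the inspiratory airflow magnitude max(-flow, 0); the argmax of the
    correlation within ±``max_lag_ms`` is the lag of airflow behind EMG
    (positive = EMG leads).
    """
    fs = airflow.rate
    dec = int(round(dia_envelope.rate / fs))
    n = (dia_envelope.samples.size // dec) * dec
    env = dia_envelope.samples[:n].reshape(-1, dec).mean(axis=1)
    insp = np.clip(-airflow.samples, 0.0, None)
    m = min(env.size, insp.size)
    env, insp = env[:m] - env[:m].mean(), insp[:m] - insp[:m].mean()
    max_lag = int(round(max_lag_ms / 1000.0 * fs))
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.array([np.dot(env[:m - k], insp[k:]) if k >= 0
                   else np.dot(env[-k:], insp[:m + k]) for k in lags])
    return float(lags[int(np.argmax(cc))] / fs * 1000.0)
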