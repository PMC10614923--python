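"""Multitaper spectrograms, peak-frequency ("pitch") contours, USV detection,
syllable grouping and rule-based contour classification.

Mouse ultrasonic vocalizations (USVs) are narrow-band tones in the 40-120 kHz
band.  The pitch of a USV is taken as the frequency bin with greatest power in
each spectrogram time bin (the peak-frequency vector).  Sound elements on one
breath separated by more than 20 ms are distinct syllables of a single
multi-syllable event; shorter gaps are treated as one continuous syllable.

The contour classifier is a transparent, rule-based stand-in for CNN-based
type classifiers: it counts register jumps and monotone segments to assign one
of the ten conventional syllable-type labels.  Its rules and precedence are
ordinary configuration, not a learned model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.signal import windows

from ._util import runs_of_true

#: The ten conventional syllable-type labels plus the fallback.
SYLLABLE_TYPES = ("complex", "chevron", "two step", "multi", "step up",
                  "step down", "down fm", "up fm", "flat", "short")


@dataclass
class Spectrogram:
    times: np.ndarray   # bin centers, s
    freqs: np.ndarray   # Hz
    power: np.ndarray   # (time, freq), nonnegative
    window_ms: float
    step_ms: float
    n_tapers: int

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be nonnegative")
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("times and freqs must be strictly increasing")


@dataclass
class PitchContour:
    """Per-time-bin peak frequency with power and a validity mask."""

    times: np.ndarray       # s
    f_peak: np.ndarray      # Hz (NaN where invalid)
    peak_power: np.ndarray
    valid: np.ndarray       # bool

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.f_peak) == len(self.peak_power) == len(self.valid) == n):
            raise ValueError("contour fields must have equal length")

    def slice(self, onset: float, offset: float) -> "PitchContour":
        m = (self.times >= onset) & (self.times < offset)
        return PitchContour(self.times[m], self.f_peak[m],
                            self.peak_power[m], self.valid[m])


@dataclass
class UsvEvent:
    """A detected vocalization: one or more syllables within a single breath."""

    id: int
    onset: float
    offset: float
    syllables: list = field(default_factory=list)  # (onset, offset) pairs
    type_label: str = "unknown"
    contour: PitchContour | None = None
    breath_index: int | None = None


def multitaper_spectrogram(audio: np.ndarray, rate: float,
                           window_ms: float | None = None,
                           step_ms: float | None = None,
                           n_tapers: int = 3, nw: float = 2.0) -> Spectrogram:
    """DPSS multitaper spectrogram (USVseg-style defaults).

    With no explicit window the frame is 512 samples (~2 ms at 250 kHz) with a
    50% step and 3 Slepian tapers at time-bandwidth NW=2; averaging the tapered
    periodograms reduces the variance of the noise floor so a narrow-band tone
    stands out against it.
    """
    audio = np.asarray(audio, dtype=float)
    nwin = (512 if window_ms is None
            else max(int(round(window_ms * rate / 1000.0)), 8))
    step = (nwin // 2 if step_ms is None
            else max(int(round(step_ms * rate / 1000.0)), 1))
    if audio.size < nwin:
        raise ValueError(f"audio shorter than one window ({nwin} samples)")
    tapers = windows.dpss(nwin, NW=nw, Kmax=n_tapers)  # (K, nwin), unit norm
    frames = np.lib.stride_tricks.sliding_window_view(audio, nwin)[::step]
    power = np.zeros((frames.shape[0], nwin // 2 + 1))
    for tap in tapers:
        power += np.abs(np.fft.rfft(frames * tap, axis=1)) ** 2
    power /= n_tapers
    times = (np.arange(frames.shape[0]) * step + nwin / 2) / rate
    freqs = np.fft.rfftfreq(nwin, 1.0 / rate)
    return Spectrogram(times=times, freqs=freqs, power=power,
                       window_ms=nwin / rate * 1000.0,
                       step_ms=step / rate * 1000.0, n_tapers=n_tapers)


def extract_pitch_contour(spec: Spectrogram,
                          band: tuple[float, float] = (40_000.0, 120_000.0),
                          floor_db: float = 15.0) -> PitchContour:
    """Peak frequency per time bin within ``band``.

    A bin is valid when its peak power exceeds the median in-band power by
    ``floor_db`` decibels; energy outside the band never contributes (a tone
    below the band leaves every bin invalid).
    """
    lo, hi = band
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(m):
        raise ValueError(f"band {band} contains no frequency bins")
    sub = spec.power[:, m]
    fsub = spec.freqs[m]
    k = np.argmax(sub, axis=1)
    peak_power = sub[np.arange(sub.shape[0]), k]
    floor = np.median(sub) * 10.0 ** (floor_db / 10.0)
    valid = peak_power > floor
    f_peak = np.where(valid, fsub[k], np.nan)
    return PitchContour(times=spec.times.copy(), f_peak=f_peak,
                        peak_power=peak_power, valid=valid)


def detect_usv_events(contour: PitchContour, min_dur_ms: float = 5.0,
                      max_gap_ms: float = 5.0) -> list[tuple[float, float]]:
    """Maximal runs of valid pitch bins as (onset, offset) intervals.

    Gaps of at most ``max_gap_ms`` are bridged, runs shorter than
    ``min_dur_ms`` discarded.  Intervals are half-open in seconds, extended by
    half a bin on each side so a single-bin tone has nonzero duration.
    """
    if contour.times.size == 0:
        return []
    dt = float(np.median(np.diff(contour.times))) if contour.times.size > 1 else 1e-3
    runs = runs_of_true(contour.valid)
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if (a - merged[-1][1]) * dt * 1000.0 <= max_gap_ms:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        onset = contour.times[a] - dt / 2
        offset = contour.times[b - 1] + dt / 2
        if (offset - onset) * 1000.0 >= min_dur_ms:
            out.append((float(onset), float(offset)))
    return out


def group_syllables(intervals: list[tuple[float, float]], breaths,
                    gap_threshold_ms: float = 20.0) -> list[UsvEvent]:
    """Group detected intervals into per-breath USV events.

    Intervals are assigned to the breath containing their onset.  Within a
    breath, consecutive intervals separated by strictly more than
    ``gap_threshold_ms`` become distinct syllables of one multi-syllable event;
    a gap of exactly the threshold (or less) merges into a single syllable.
    Intervals outside every breath are dropped.
    """
    if not intervals:
        return []
    starts = np.array([b.insp_onset for b in breaths]) if breaths else np.array([])
    per_breath: dict[int, list[tuple[float, float]]] = {}
    for onset, offset in sorted(intervals):
        if starts.size == 0:
            per_breath.setdefault(0, []).append((onset, offset))
            continue
        k = int(np.searchsorted(starts, onset, side="right")) - 1
        if k < 0 or onset >= breaths[k].end:
            continue
        per_breath.setdefault(k, []).append((onset, offset))
    events: list[UsvEvent] = []
    # strict "> threshold" rule; the 1 ns tolerance absorbs floating-point
    # representation error so an exactly-threshold gap always merges
    thr = gap_threshold_ms / 1000.0 + 1e-9
    for k in sorted(per_breath):
        ivs = per_breath[k]
        syllables = [list(ivs[0])]
        for onset, offset in ivs[1:]:
            if onset - syllables[-1][1] > thr:
                syllables.append([onset, offset])
            else:
                syllables[-1][1] = max(syllables[-1][1], offset)
        events.append(UsvEvent(
            id=len(events), onset=syllables[0][0], offset=syllables[-1][1],
            syllables=[tuple(s) for s in syllables],
            breath_index=k if breaths else None))
    return events


def classify_contour(event: UsvEvent, jump_threshold_khz: float = 10.0,
                     flat_range_khz: float = 5.0, short_ms: float = 10.0,
                     smooth_bins: int = 5,
                     prominence_frac: float = 0.15) -> str:
    """Deterministic rule-based syllable-type label for an event's contour.

    Precedence (documented order):

    1. total duration < ``short_ms``            -> "short"
    2. valid-pitch range < ``flat_range_khz``   -> "flat"
    3. register jumps (inter-bin steps > ``jump_threshold_khz`` within a
       syllable): 1 up -> "step up", 1 down -> "step down", 2 -> "two step",
       >=3 -> "multi"
    4. shape of the (median-smoothed) contour, using interior extrema with
       prominence above ``prominence_frac`` of the contour range: none and
       falling -> "down fm", none and rising -> "up fm", a single maximum
       (rise-fall) -> "chevron", anything with a trough or >=2 reversals ->
       "complex"

    Unclassifiable contours return "unknown"; the function never raises for a
    degenerate contour.
    """
    c = event.contour
    if c is None:
        return "unknown"
    f = c.f_peak[c.valid] / 1000.0  # kHz
    t = c.times[c.valid]
    if f.size < 2:
        return "unknown"
    duration_ms = (event.offset - event.onset) * 1000.0
    if duration_ms < short_ms:
        return "short"
    if np.ptp(f) < flat_range_khz:
        return "flat"
    # jumps: steps between consecutive valid bins inside one syllable
    jumps = []
    syllables = event.syllables or [(event.onset, event.offset)]
    for s0, s1 in syllables:
        m = (t >= s0) & (t < s1)
        d = np.diff(f[m])
        for step in d[np.abs(d) > jump_threshold_khz]:
            jumps.append(step)
    if len(jumps) >= 3:
        return "multi"
    if len(jumps) == 2:
        return "two step"
    if len(jumps) == 1:
        return "step up" if jumps[0] > 0 else "step down"
    # shape analysis on a lightly smoothed contour
    if f.size >= smooth_bins:
        fs = sps.medfilt(f, smooth_bins if smooth_bins % 2 else smooth_bins + 1)
    else:
        fs = f
    rng = np.ptp(fs)
    if rng == 0:
        return "flat"
    prom = prominence_frac * rng
    n_max = len(sps.find_peaks(fs, prominence=prom)[0])
    n_min = len(sps.find_peaks(-fs, prominence=prom)[0])
    if n_max == 0 and n_min == 0:
        return "down fm" if fs[-1] < fs[0] else "up fm"
    if n_max == 1 and n_min == 0:
        return "chevron"
    if n_min >= 1 or (n_max + n_min) >= 2:
        return "complex"
    return "unknown"
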