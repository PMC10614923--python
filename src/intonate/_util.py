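"""Shared numeric helpers: seeded substreams, smooth noise, burst envelopes."""
from __future__ import annotations

import numpy as np
from scipy import signal


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent random generators from one integer seed.

    All randomness in the package flows through these named substreams so a
    single seed reproduces every signal byte-for-byte.
    """
    ss = np.random.SeedSequence(int(seed))
    return [np.random.default_rng(child) for child in ss.spawn(int(n))]


def smooth_noise(rng: np.random.Generator, n: int, rate_hz: float,
                 bandwidth_hz: float, std: float) -> np.ndarray:
    """Zero-mean Gaussian noise low-passed to ``bandwidth_hz``, rescaled to ``std``.

    Used for breath-shape irregularity and laryngeal motor noise; the low-pass
    makes fluctuations smooth on the timescale of a syllable.
    """
    if n == 0 or std == 0.0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    wn = min(bandwidth_hz / (rate_hz / 2.0), 0.99)
    sos = signal.butter(2, wn, output="sos")
    y = signal.sosfiltfilt(sos, x) if n > 24 else x
    s = y.std()
    if s > 0:
        y = y * (std / s)
    return y


def raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump of total support ``width`` centered at ``center``; peak 1."""
    u = (t - center) / width
    b = np.zeros_like(t, dtype=float)
    m = np.abs(u) < 0.5
    b[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[m]))
    return b


def moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Length-preserving moving average (boxcar, edge-padded)."""
    if w <= 1:
        return np.asarray(x, dtype=float)
    xp = np.pad(np.asarray(x, dtype=float), (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(xp, np.ones(w) / w, mode="valid")


def runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(m.size)
    return list(zip(starts, stops))
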