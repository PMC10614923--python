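"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

import intonate as it
from intonate.breath import Breath


def oracle_crossings(x, h):
    """Per-sample Schmitt-trigger oracle for hysteresis zero crossings.

    Deliberately written as a dumb state machine, independent of the
    vectorized implementation it checks.
    """
    out = []
    state = 0
    pending = None
    for i, xi in enumerate(x):
        s = 1 if xi > 0 else -1
        if pending is not None and s != pending[1]:
            pending = None
        if pending is None and s != state:
            pending = (i, s)
        if pending is not None and abs(xi) >= h and s == pending[1]:
            if state != 0:
                out.append((pending[0], pending[1]))
            state = pending[1]
            pending = None
    return out


def oracle_pearson(x, y):
    """From-scratch Pearson r via explicit covariance and standard deviations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    sx = (sum((a - mx) ** 2 for a in x) / len(x)) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / len(y)) ** 0.5
    return cov / (sx * sy)


def events_from_dataset(ds, base=0):
    """Standalone vocal-breath records -> (UsvEvents, per-event airflow traces)."""
    events, airs = [], []
    for k, (trace, contour, rec) in enumerate(ds):
        if not rec["syllables"]:
            continue
        events.append(it.UsvEvent(
            id=base + k, onset=rec["syllables"][0]["onset"],
            offset=rec["syllables"][-1]["offset"],
            syllables=[(s["onset"], s["offset"]) for s in rec["syllables"]],
            type_label=rec["type"], contour=contour))
        airs.append(trace)
    return events, airs


def breaths_from_truth(truth):
    return [Breath(index=i, insp_onset=r.insp_onset, exp_onset=r.exp_onset,
                   end=r.end, Ti=r.Ti, Te=r.Te, Pif=r.Pif, Pef=r.Pef,
                   f_inst=r.f_inst, is_vocal=r.is_vocal)
            for i, r in truth.breaths.iterrows()]


@pytest.fixture(scope="session")
def quiet_config():
    """Low-noise generator conditions for template-shape tests."""
    return it.SimConfig(airflow_noise=0.0, pitch_jitter_khz=0.1,
                        flow_wiggle=0.05, aperture_wiggle=0.05)


@pytest.fixture(scope="session")
def default_session():
    """One mid-sized default-noise session shared across read-only tests."""
    cfg = it.SimConfig(duration_s=60.0, seed=17)
    trace, truth = it.generate_breath_train(cfg)
    return cfg, trace, truth
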