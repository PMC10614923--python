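"""Airflow-pitch correlation per USV, shuffle nulls, and intonation calls.

The central statistic is the Pearson correlation ``r`` between instantaneous
expiratory airflow (interpolated at the pitch-contour time bins of one USV)
and the USV's peak frequency.  Positive intonation (breath-modulation
mechanism) predicts ``r > 0``; negative intonation (laryngeal constriction)
predicts ``r < 0``.  Significance is judged against shuffle nulls in which
each USV's pitch is paired with a *different* USV's expiratory airflow
(``shuffled_airflow``) or vice versa (``shuffled_pitch``), the partner signal
linearly time-rescaled onto the recipient's bins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import substreams
from .breath import AirflowTrace
from .pitch import PitchContour, UsvEvent

log = logging.getLogger(__name__)

MIN_BINS = 5


@dataclass
class IntonationResult:
    usv_id: int
    r: float | None            # None when indeterminate (too few bins / no variance)
    n_bins: int
    type_label: str = "unknown"
    call: str = "indeterminate"
    null_percentile: float | None = None


@dataclass
class NullDistribution:
    mode: str                  # "shuffled_airflow" | "shuffled_pitch"
    r_values: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if self.mode not in ("shuffled_airflow", "shuffled_pitch"):
            raise ValueError(f"invalid null mode {self.mode!r}")
        self.r_values = np.asarray(self.r_values, dtype=float)
        if np.any(np.abs(self.r_values) > 1 + 1e-12):
            raise ValueError("null r values must lie in [-1, 1]")


def align_airflow_to_pitch(breath_airflow: AirflowTrace, contour: PitchContour,
                           usv: UsvEvent, min_bins: int = MIN_BINS):
    """Paired vectors (Q_i, f_i) at the contour's valid bins within the USV.

    Airflow is linearly interpolated at the bin times; signed flow is kept
    (expiration positive, so transient mini-breath dips enter as negative
    values).  Fewer than ``min_bins`` valid pairs yields two empty arrays.
    """
    m = (contour.valid & (contour.times >= usv.onset)
         & (contour.times < usv.offset))
    tb = contour.times[m]
    f = contour.f_peak[m]
    if tb.size < min_bins:
        return np.array([]), np.array([])
    q = np.interp(tb, breath_airflow.times, breath_airflow.samples)
    return q, f


def intonation_correlation(pairs) -> float | None:
    """Pearson r of a (Q, f) pairing; ``None`` for degenerate input.

    Zero variance in either vector or fewer than MIN_BINS pairs is reported as
    indeterminate (``None``), never as 0 and never as NaN.
    """
    q, f = pairs
    q = np.asarray(q, dtype=float)
    f = np.asarray(f, dtype=float)
    if q.size < MIN_BINS or f.size != q.size:
        return None
    sq, sf = q.std(), f.std()
    if sq == 0.0 or sf == 0.0:
        return None
    r = float(np.mean((q - q.mean()) * (f - f.mean())) / (sq * sf))
    return float(np.clip(r, -1.0, 1.0))


def _usv_vectors(usvs, airflows, min_bins):
    """Per-USV (u, f, Q) with u the bin times normalized to [0, 1]."""
    out = []
    for k, usv in enumerate(usvs):
        trace = airflows[k] if isinstance(airflows, (list, tuple)) else airflows
        q, f = align_airflow_to_pitch(trace, usv.contour, usv, min_bins)
        if q.size == 0:
            out.append(None)
            continue
        m = (usv.contour.valid & (usv.contour.times >= usv.onset)
             & (usv.contour.times < usv.offset))
        tb = usv.contour.times[m]
        span = tb[-1] - tb[0]
        u = (tb - tb[0]) / span if span > 0 else np.zeros_like(tb)
        out.append((u, f, q))
    return out


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    if n < 2:
        raise ValueError("need at least two USVs to shuffle")
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def build_shuffle_null(usvs, airflows, mode: str = "shuffled_airflow",
                       n_perm: int = 200, seed: int = 0,
                       min_bins: int = MIN_BINS) -> NullDistribution:
    """Null r distribution from derangement pairings of pitch and airflow.

    For each of ``n_perm`` permutations every USV's pitch contour is paired
    with a different USV's expiratory airflow (``shuffled_airflow``) or every
    airflow with a different USV's pitch (``shuffled_pitch``); the partner
    signal is linearly time-rescaled onto the recipient's bins.  Deterministic
    given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("shuffled_airflow", "shuffled_pitch"):
        raise ValueError(f"invalid null mode {mode!r}")
    vecs = [v for v in _usv_vectors(usvs, airflows, min_bins) if v is not None]
    if len(vecs) < 2:
        raise ValueError("need at least two USVs with defined pairings")
    rng = substreams(seed, 1)[0]
    r_values = []
    for _ in range(n_perm):
        perm = _derangement(rng, len(vecs))
        for i, j in enumerate(perm):
            u_i, f_i, q_i = vecs[i]
            u_j, f_j, q_j = vecs[j]
            if mode == "shuffled_airflow":
                r = intonation_correlation((np.interp(u_i, u_j, q_j), f_i))
            else:
                r = intonation_correlation((q_i, np.interp(u_i, u_j, f_j)))
            if r is not None:
                r_values.append(r)
    return NullDistribution(mode=mode, r_values=np.array(r_values),
                            n_perm=n_perm, seed=seed)


def classify_intonation(results: list[IntonationResult],
                        nulls: dict | NullDistribution,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Positive/negative/indeterminate call per USV against its null.

    ``nulls`` is either a single pooled NullDistribution or a mapping
    type_label -> NullDistribution with the pooled null under the key
    ``None``.  A USV is called positive when its r exceeds the upper
    ``1 - alpha/2`` quantile of the null, negative below the ``alpha/2``
    quantile, else indeterminate.  Returns the per-type summary table
    (median r, call counts); the calls are written onto the results.
    """
    pooled = nulls if isinstance(nulls, NullDistribution) else nulls.get(None)
    for res in results:
        null = pooled
        if isinstance(nulls, dict) and res.type_label in nulls:
            null = nulls[res.type_label]
        if res.r is None:
            res.call = "indeterminate"
            continue
        if null is None or null.r_values.size == 0:
            log.warning("no null distribution for USV %s; call indeterminate",
                        res.usv_id)
            res.call = "indeterminate"
            continue
        lo = float(np.quantile(null.r_values, alpha / 2))
        hi = float(np.quantile(null.r_values, 1 - alpha / 2))
        res.null_percentile = float(np.mean(null.r_values < res.r))
        res.call = ("positive" if res.r > hi
                    else "negative" if res.r < lo else "indeterminate")
    rows = []
    frame = pd.DataFrame([vars(r) for r in results])
    for ty, grp in frame.groupby("type_label"):
        rr = grp["r"].dropna()
        rows.append(dict(
            type_label=ty, n=len(grp), n_defined=len(rr),
            median_r=rr.median() if len(rr) else np.nan,
            q1_r=rr.quantile(0.25) if len(rr) else np.nan,
            q3_r=rr.quantile(0.75) if len(rr) else np.nan,
            n_positive=int((grp["call"] == "positive").sum()),
            n_negative=int((grp["call"] == "negative").sum()),
            n_indeterminate=int((grp["call"] == "indeterminate").sum())))
    return pd.DataFrame(rows)


def intonation_analysis(usvs, airflows, n_perm: int = 200, seed: int = 0,
                        alpha: float = 0.05, min_bins: int = MIN_BINS,
                        per_type_min: int = 20):
    """Full per-USV intonation analysis.

    Computes the observed r for every USV (whole event, all syllables
    concatenated), builds both shuffle nulls per syllable type when at least
    ``per_type_min`` USVs of that type exist (pooled otherwise), and calls
    positive/negative intonation.  Returns (results, per-type summary, nulls).
    """
    results = []
    for k, usv in enumerate(usvs):
        trace = airflows[k] if isinstance(airflows, (list, tuple)) else airflows
        pairs = align_airflow_to_pitch(trace, usv.contour, usv, min_bins)
        r = intonation_correlation(pairs)
        results.append(IntonationResult(usv_id=usv.id, r=r,
                                        n_bins=len(pairs[0]),
                                        type_label=usv.type_label))
    sub_seeds = substreams(seed, 1)[0].integers(0, 2 ** 31 - 1,
                                                2 * (len(set(
                                                    u.type_label for u in usvs))
                                                     + 1))
    nulls: dict = {}
    k_seed = 0

    def both_modes(sel_usvs, sel_air):
        nonlocal k_seed
        parts = []
        for mode in ("shuffled_airflow", "shuffled_pitch"):
            nd = build_shuffle_null(sel_usvs, sel_air, mode=mode,
                                    n_perm=n_perm,
                                    seed=int(sub_seeds[k_seed]),
                                    min_bins=min_bins)
            k_seed += 1
            parts.append(nd.r_values)
        return NullDistribution(mode="shuffled_airflow",
                                r_values=np.concatenate(parts),
                                n_perm=2 * n_perm, seed=seed)

    listed = isinstance(airflows, (list, tuple))
    nulls[None] = both_modes(usvs, airflows)
    for ty in sorted(set(u.type_label for u in usvs)):
        idx = [k for k, u in enumerate(usvs) if u.type_label == ty]
        if len(idx) >= per_type_min:
            sel_air = [airflows[k] for k in idx] if listed else airflows
            nulls[ty] = both_modes([usvs[k] for k in idx], sel_air)
    summary = classify_intonation(results, nulls, alpha=alpha)
    return results, summary, nulls


def results_frame(results: list[IntonationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results], columns=[
        "usv_id", "r", "n_bins", "type_label", "call", "null_percentile"])
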