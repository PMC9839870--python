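"""Normalized modulation index (NMI), response classes, clustering, overlap.

For one neuron the NMI compares duration-normalized trace AUC between a
post-treatment window and a baseline window:

    NMI = (A_post - A_base) / (A_post + A_base)

with A = trapezoidal AUC / window duration, so NMI ranges over [-1, 1]:
-1 is total suppression, +1 de-novo activation, 0 unchanged activity.
The same index computed between pooled WAKE and pooled NREM epochs defines
wake-active (NMI > 0) and sleep-active (NMI < 0) neurons. Responses are
classed INHIBITED (NMI < -0.33), EXCITED (NMI > 0.33) or INSENSITIVE, and
response patterns across anesthetics are grouped by agglomerative
clustering (Euclidean distance on the NMI vectors, average linkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

from .datamodel import StateSequence, TraceMatrix

#: Response-class cuts on the NMI (strict inequalities).
INHIBITED_THRESHOLD = -0.33
EXCITED_THRESHOLD = 0.33

#: Minimum pooled time per state for a sleep-wake NMI (s).
MIN_STATE_SECONDS = 300.0

NMI_COLUMNS = ("neuron_id", "condition", "nmi", "auc_base_rate", "auc_post_rate", "response_class", "degenerate")


@dataclass
class OverlapSummary:
    """Joint response-class counts and NMI correlation for two conditions."""

    condition_a: str
    condition_b: str
    n_shared: int
    n_both_inhibited: int
    n_only_one_inhibited: int
    n_both_excited: int
    n_only_one_excited: int
    pct_inhibited_a_also_b: float | None  # among inhibited-by-a
    pct_inhibited_b_also_a: float | None
    pct_inhibited_mean: float | None
    pct_excited_a_also_b: float | None
    pct_excited_b_also_a: float | None
    pct_excited_mean: float | None
    pearson_r: float | None
    r_pvalue: float | None


def _auc_rate(values: np.ndarray, frame_rate_hz: float) -> float:
    """Trapezoidal AUC divided by duration — the mean signal level."""
    if len(values) < 2:
        raise ValueError("need at least 2 frames for a trapezoidal AUC")
    dt = 1.0 / frame_rate_hz
    return float(np.trapezoid(values, dx=dt) / (dt * (len(values) - 1)))


def compute_nmi(
    trace: np.ndarray,
    frame_rate_hz: float,
    baseline: tuple[float, float],
    post: tuple[float, float],
    start_time_s: float = 0.0,
    duration_normalized: bool = True,
) -> tuple[float, float, float, bool]:
    """NMI of one neuron between a baseline and a post-treatment window.

    Returns ``(nmi, auc_base_rate, auc_post_rate, degenerate)``. Both AUCs
    are duration-normalized by default so unequal windows (5-min baseline vs
    10-min post) compare rates, not totals; ``duration_normalized=False``
    gives the raw-AUC variant for sensitivity analysis. A neuron silent in
    both windows gets NMI = 0 with the degenerate flag set.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if np.any(trace < 0):
        raise ValueError("trace values must be nonnegative")
    t = start_time_s + np.arange(len(trace)) / frame_rate_hz
    vals = []
    for t0, t1 in (baseline, post):
        m = (t >= t0) & (t < t1)
        if m.sum() < 2:
            raise ValueError(f"window ({t0}, {t1}) covers fewer than 2 frames")
        a = _auc_rate(trace[m], frame_rate_hz)
        if not duration_normalized:
            a *= (t1 - t0)
        vals.append(a)
    a_base, a_post = vals
    if a_base + a_post == 0:
        return 0.0, a_base, a_post, True
    return (a_post - a_base) / (a_post + a_base), a_base, a_post, False


def sleepwake_nmi(
    trace: np.ndarray,
    frame_rate_hz: float,
    states: StateSequence,
    start_time_s: float = 0.0,
    min_state_seconds: float = MIN_STATE_SECONDS,
) -> float | None:
    """NMI between pooled WAKE and pooled NREM activity (REM excluded).

    Positive values mark wake-active neurons, negative sleep-active.
    Returns None when either state covers less than ``min_state_seconds``.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if np.any(trace < 0):
        raise ValueError("trace values must be nonnegative")
    if states.state_seconds("WAKE") < min_state_seconds or states.state_seconds("NREM") < min_state_seconds:
        return None
    t = start_time_s + np.arange(len(trace)) / frame_rate_hz
    rates = {}
    for state in ("WAKE", "NREM"):
        chunks = []
        for t0, t1 in states.intervals(state):
            m = (t >= t0) & (t < t1)
            if m.sum() >= 2:
                chunks.append(trace[m])
        if not chunks:
            return None
        pooled = np.concatenate(chunks)
        rates[state] = float(np.mean(pooled))
    a_wake, a_nrem = rates["WAKE"], rates["NREM"]
    if a_wake + a_nrem == 0:
        return 0.0
    return (a_wake - a_nrem) / (a_wake + a_nrem)


def classify(nmi: float) -> str:
    """Response class from the NMI thresholds (strict at +/-0.33)."""
    if not -1.0 - 1e-9 <= nmi <= 1.0 + 1e-9:
        raise ValueError(f"nmi must lie in [-1, 1], got {nmi}")
    if nmi < INHIBITED_THRESHOLD:
        return "INHIBITED"
    if nmi > EXCITED_THRESHOLD:
        return "EXCITED"
    return "INSENSITIVE"


def nmi_table(
    traces: TraceMatrix,
    condition: str,
    baseline: tuple[float, float],
    post: tuple[float, float],
    duration_normalized: bool = True,
) -> pd.DataFrame:
    """Per-neuron NMI rows for one treatment condition."""
    rows = []
    for i, nid in enumerate(traces.neuron_ids):
        nmi, a_base, a_post, degen = compute_nmi(
            traces.values[i],
            traces.frame_rate_hz,
            baseline,
            post,
            start_time_s=traces.start_time_s,
            duration_normalized=duration_normalized,
        )
        rows.append(
            {
                "neuron_id": nid,
                "condition": condition,
                "nmi": nmi,
                "auc_base_rate": a_base,
                "auc_post_rate": a_post,
                "response_class": classify(nmi),
                "degenerate": degen,
            }
        )
    return pd.DataFrame(rows, columns=list(NMI_COLUMNS))


def sleepwake_table(traces: TraceMatrix, states: StateSequence) -> pd.DataFrame:
    """Per-neuron sleep-wake NMI rows (condition label SLEEPWAKE)."""
    rows = []
    for i, nid in enumerate(traces.neuron_ids):
        nmi = sleepwake_nmi(
            traces.values[i], traces.frame_rate_hz, states, start_time_s=traces.start_time_s
        )
        if nmi is None:
            continue
        rows.append(
            {
                "neuron_id": nid,
                "condition": "SLEEPWAKE",
                "nmi": nmi,
                "auc_base_rate": np.nan,
                "auc_post_rate": np.nan,
                "response_class": classify(nmi),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows, columns=list(NMI_COLUMNS))


def cluster_responses(nmi_matrix: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Group neurons by their NMI response pattern across conditions.

    Agglomerative clustering with Euclidean distance and average linkage,
    cut at ``k`` clusters. Returns ``(labels in 0..k-1, linkage matrix)``.
    Deterministic; identical rows merge at distance 0 and scipy's
    cluster-count cut resolves the degenerate tree (fewer distinct clusters
    than k may result).
    """
    X = np.asarray(nmi_matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("nmi_matrix must be 2-D (neurons x conditions)")
    if not np.all(np.isfinite(X)):
        raise ValueError("nmi_matrix must have no undefined entries")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of neurons {X.shape[0]}")
    Z = linkage(X, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return labels, Z


def overlap_and_correlation(table: pd.DataFrame, cond_a: str, cond_b: str) -> OverlapSummary:
    """Joint classification counts and Pearson correlation of NMI vectors.

    Operates on neurons shared between both conditions. Directional
    percentages are reported both ways plus their mean. Degenerate
    (all-zero) neurons are excluded.
    """
    a = table[(table["condition"] == cond_a) & (~table["degenerate"])].set_index("neuron_id")
    b = table[(table["condition"] == cond_b) & (~table["degenerate"])].set_index("neuron_id")
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared neurons, got {len(shared)}")
    a, b = a.loc[shared], b.loc[shared]
    inh_a = a["response_class"] == "INHIBITED"
    inh_b = b["response_class"] == "INHIBITED"
    exc_a = a["response_class"] == "EXCITED"
    exc_b = b["response_class"] == "EXCITED"

    def _directional(x: pd.Series, y: pd.Series) -> tuple[float | None, float | None, float | None]:
        pa = 100.0 * float((x & y).sum()) / x.sum() if x.sum() else None
        pb = 100.0 * float((x & y).sum()) / y.sum() if y.sum() else None
        mean = (pa + pb) / 2 if pa is not None and pb is not None else None
        return pa, pb, mean

    inh_ab, inh_ba, inh_mean = _directional(inh_a, inh_b)
    exc_ab, exc_ba, exc_mean = _directional(exc_a, exc_b)

    va, vb = a["nmi"].to_numpy(float), b["nmi"].to_numpy(float)
    if va.std() == 0 or vb.std() == 0:
        r, p = None, None
    else:
        r, p = pearsonr(va, vb)
        r, p = float(r), float(p)
    return OverlapSummary(
        condition_a=cond_a,
        condition_b=cond_b,
        n_shared=len(shared),
        n_both_inhibited=int((inh_a & inh_b).sum()),
        n_only_one_inhibited=int((inh_a ^ inh_b).sum()),
        n_both_excited=int((exc_a & exc_b).sum()),
        n_only_one_excited=int((exc_a ^ exc_b).sum()),
        pct_inhibited_a_also_b=inh_ab,
        pct_inhibited_b_also_a=inh_ba,
        pct_inhibited_mean=inh_mean,
        pct_excited_a_also_b=exc_ab,
        pct_excited_b_also_a=exc_ba,
        pct_excited_mean=exc_mean,
        pearson_r=r,
        r_pvalue=p,
    )
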