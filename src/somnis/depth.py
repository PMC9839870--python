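"""Anesthesia depth from EEG/EMG features, and EMG-based induction timing.

Depth is quantified by clustering epochs in the (EMG RMS, delta/theta ratio)
plane. A 5-min active-EMG baseline is pooled with each candidate 10-min
post-treatment window (shifted every 1 min), the pooled features are
standardized, split by 2-means, and the Davies-Bouldin index

    DBI = (1/N) * sum_i max_{j != i} (d'(i) + d'(j)) / d(i, j)

is computed with N = 2 clusters, d'(i) the mean Euclidean distance of
cluster-i points to their centroid and d(i, j) the centroid distance. A
small DBI means the awake and anesthetized epochs form two well-separated
clusters; the window with minimal DBI is taken as the period of adequate
anesthesia depth.

Induction/recovery times are detected from EMG RMS in 20-s windows hopped
every 10 s against a mean + 3*SD threshold from a reference interval, using
run-length rules (15 consecutive sub-threshold windows => fully
anesthetized; 9 consecutive supra-threshold windows => fully awake).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datamodel import Recording, TreatmentEvent

#: Sliding-window search defaults (s).
WINDOW_LEN_S = 600.0
WINDOW_STEP_S = 60.0
BASELINE_LEN_S = 300.0

#: EMG timing defaults: 20-s RMS windows with 10-s overlap, run lengths.
RMS_WINDOW_S = 20.0
RMS_HOP_S = 10.0
N_ANESTHETIZED_WINDOWS = 15
N_AWAKE_WINDOWS = 9


@dataclass
class DepthResult:
    selected_window: tuple[float, float]
    dbi: float
    cluster_assignments: np.ndarray  # {0,1} per pooled epoch
    epoch_times: np.ndarray  # start time of each pooled epoch
    feature_scaling: dict[str, tuple[float, float]]  # feature -> (mean, sd)
    awake_cluster: int
    candidates: pd.DataFrame = field(repr=False, default=None)


@dataclass
class AnesthesiaTiming:
    emg_threshold: float
    fully_anesthetized_start_s: float | None
    fully_awake_s: float | None
    induction_time_s: float | None
    recovery_time_s: float | None


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index for a 2-cluster partition of 2-D points."""
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    clusters = [points[labels == k] for k in (0, 1)]
    if any(len(c) == 0 for c in clusters):
        raise ValueError("both clusters must be nonempty")
    centroids = [c.mean(axis=0) for c in clusters]
    spread = [float(np.mean(np.linalg.norm(c - mu, axis=1))) for c, mu in zip(clusters, centroids)]
    d01 = float(np.linalg.norm(centroids[0] - centroids[1]))
    if d01 == 0:
        raise ValueError("coincident centroids: DBI undefined")
    # With N=2 each cluster's max over j != i is the same single ratio.
    return (spread[0] + spread[1]) / d01


def depth_search(
    features: pd.DataFrame,
    event: TreatmentEvent,
    window_len_s: float = WINDOW_LEN_S,
    step_s: float = WINDOW_STEP_S,
    random_state: int = 0,
) -> DepthResult:
    """Find the post-treatment window of adequate anesthesia depth.

    For every candidate window of ``window_len_s`` starting at the injection
    and shifted by ``step_s``, the baseline epochs and window epochs are
    pooled in (emg_rms, dt_ratio) space, standardized feature-wise, split by
    2-means (10 restarts, fixed seed), and scored by the Davies-Bouldin
    index. The window with minimal DBI wins; ties go to the earliest window.
    """
    epoch_s = float(features["t_start_s"].iloc[1] - features["t_start_s"].iloc[0])
    t = features["t_start_s"].to_numpy(dtype=float)
    feats = features[["emg_rms", "dt_ratio"]].to_numpy(dtype=float)
    finite = np.isfinite(feats).all(axis=1)

    b0, b1 = event.baseline_window
    base_m = (t >= b0) & (t + epoch_s <= b1) & finite
    if base_m.sum() < 2:
        raise ValueError("baseline window covers fewer than 2 usable epochs")

    p0, p1 = event.post_window_candidate
    p0 = max(p0, event.injection_time_s)
    starts = np.arange(p0, p1 - window_len_s + 1e-9, step_s)
    if len(starts) == 0:
        raise ValueError("no candidate window fits in the post-treatment span")

    rows = []
    best = None
    for w0 in starts:
        win_m = (t >= w0) & (t + epoch_s <= w0 + window_len_s) & finite
        if win_m.sum() < 2:
            continue
        pooled = np.concatenate([feats[base_m], feats[win_m]])
        times = np.concatenate([t[base_m], t[win_m]])
        mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (pooled - mu) / sd
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(X)
        lab = km.labels_
        if len(np.unique(lab)) < 2:
            warnings.warn(f"k-means collapsed for window starting {w0:.0f} s; skipped", stacklevel=2)
            continue
        try:
            dbi = davies_bouldin(X, lab)
        except ValueError:
            continue
        rows.append({"window_start_s": w0, "dbi": dbi})
        if best is None or dbi < best["dbi"] - 1e-15:
            n_base = base_m.sum()
            base_labels = lab[:n_base]
            awake_cluster = int(np.bincount(base_labels, minlength=2).argmax())
            best = {
                "w0": w0,
                "dbi": dbi,
                "lab": lab,
                "times": times,
                "mu": mu,
                "sd": sd,
                "awake_cluster": awake_cluster,
                "base_frac": float(np.mean(base_labels == awake_cluster)),
                "win_frac": float(np.mean(lab[n_base:] == awake_cluster)),
            }
    if best is None:
        raise ValueError("every candidate window was degenerate")
    if best["base_frac"] < 0.9 or best["win_frac"] > 0.1:
        warnings.warn(
            "k-means clusters do not align cleanly with the baseline/window "
            "time periods; interpret the DBI with caution",
            stacklevel=2,
        )
    return DepthResult(
        selected_window=(best["w0"], best["w0"] + window_len_s),
        dbi=best["dbi"],
        cluster_assignments=best["lab"],
        epoch_times=best["times"],
        feature_scaling={
            "emg_rms": (float(best["mu"][0]), float(best["sd"][0])),
            "dt_ratio": (float(best["mu"][1]), float(best["sd"][1])),
        },
        awake_cluster=best["awake_cluster"],
        candidates=pd.DataFrame(rows),
    )


def hopped_rms(
    x: np.ndarray,
    rate: float,
    window_s: float = RMS_WINDOW_S,
    hop_s: float = RMS_HOP_S,
    start_time_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """EMG RMS in overlapping windows; returns (window start times, RMS)."""
    x = np.asarray(x, dtype=np.float64)
    w = int(round(window_s * rate))
    h = int(round(hop_s * rate))
    if x.size < w:
        raise ValueError("signal shorter than one RMS window")
    starts = np.arange(0, x.size - w + 1, h)
    rms = np.array([np.sqrt(np.mean(x[s : s + w] ** 2)) for s in starts])
    return start_time_s + starts / rate, rms


def _first_run_start(mask: np.ndarray, run_len: int) -> int | None:
    """Index of the first element of the first run of `run_len` Trues."""
    count = 0
    for i, m in enumerate(mask):
        count = count + 1 if m else 0
        if count == run_len:
            return i - run_len + 1
    return None


def emg_timing(
    emg: np.ndarray,
    rate: float,
    reference_interval: tuple[float, float],
    anesthetic_interval: tuple[float, float],
    start_time_s: float = 0.0,
    n_anesthetized: int = N_ANESTHETIZED_WINDOWS,
    n_awake: int = N_AWAKE_WINDOWS,
) -> AnesthesiaTiming:
    """Detect induction and recovery times from EMG RMS run-length rules.

    The threshold is mean + 3*SD of the hopped RMS over
    ``reference_interval``. "Fully anesthetized" starts at the first run of
    ``n_anesthetized`` consecutive sub-threshold windows after the
    anesthetic starts; "fully awake" at the first run of ``n_awake``
    consecutive supra-threshold windows after the anesthetic stops. Events
    that never occur are reported as None.
    """
    times, rms = hopped_rms(emg, rate, start_time_s=start_time_s)
    r0, r1 = reference_interval
    ref = (times >= r0) & (times + RMS_WINDOW_S <= r1)
    if ref.sum() < 1:
        raise ValueError("reference interval shorter than one RMS window")
    thr = float(rms[ref].mean() + 3.0 * rms[ref].std())

    a_start, a_stop = anesthetic_interval
    post_start = times >= a_start
    idx = _first_run_start(
        (rms < thr) & post_start, n_anesthetized
    )
    fully_anesthetized = float(times[idx]) if idx is not None else None

    post_stop = times >= a_stop
    idx = _first_run_start((rms > thr) & post_stop, n_awake)
    fully_awake = float(times[idx]) if idx is not None else None

    return AnesthesiaTiming(
        emg_threshold=thr,
        fully_anesthetized_start_s=fully_anesthetized,
        fully_awake_s=fully_awake,
        induction_time_s=(fully_anesthetized - a_start) if fully_anesthetized is not None else None,
        recovery_time_s=(fully_awake - a_stop) if fully_awake is not None else None,
    )


def emg_timing_from_recording(
    rec: Recording,
    reference_interval: tuple[float, float],
    anesthetic_interval: tuple[float, float],
) -> AnesthesiaTiming:
    if "emg" not in rec:
        raise ValueError("recording lacks the required channel 'emg'")
    return emg_timing(
        rec.channels["emg"],
        rec.sample_rate_hz,
        reference_interval,
        anesthetic_interval,
        start_time_s=rec.start_time_s,
    )
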