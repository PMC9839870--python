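"""Rule-based sleep scoring of 5-s epochs from EEG/EMG features.

The scorer applies the standard rodent criteria as a transparent decision
rule with total precedence WAKE > REM > NREM:

* WAKE — desynchronized EEG with high EMG (``emg_rms`` above threshold);
* REM  — theta-dominant EEG (theta/delta above a cut) with low EMG;
* NREM — everything else with low EMG (high-amplitude delta).

The EMG threshold is calibrated per session by a two-means split of the
log RMS distribution; the theta-dominance cut is a fixed default. A 3-epoch
majority vote smooths single-epoch flickers, mimicking the bout-consistency
editing a human scorer applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datamodel import StateSequence

#: theta/delta ratio above which a low-EMG epoch is scored REM.
DEFAULT_REM_THETA_DOMINANCE = 1.5

#: Minimum separation of the two log-RMS k-means centers, in units of the
#: mean within-cluster SD, for the bimodal calibration to be trusted.
#: A 2-means split of a single Gaussian yields a ratio of about 2.6, a
#: genuinely bimodal wake/sleep EMG distribution several times more.
_MIN_CENTER_SEPARATION = 3.0


@dataclass
class ScoringThresholds:
    emg_threshold: float
    rem_theta_dominance: float = DEFAULT_REM_THETA_DOMINANCE
    min_delta_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.emg_threshold <= 0 or self.rem_theta_dominance <= 0:
            raise ValueError("thresholds must be > 0")


def fit_thresholds(
    features: pd.DataFrame,
    rem_theta_dominance: float = DEFAULT_REM_THETA_DOMINANCE,
    emg_threshold_override: float | None = None,
    fallback_emg_threshold: float | None = None,
) -> ScoringThresholds:
    """Calibrate the EMG threshold from the session's own RMS distribution.

    The log RMS values are split by 2-means; the threshold is the midpoint
    of the two centers. If the distribution is effectively unimodal (center
    separation below 2 pooled SDs) the configured absolute fallback is used
    with a warning.
    """
    if emg_threshold_override is not None:
        return ScoringThresholds(emg_threshold_override, rem_theta_dominance)
    rms = features["emg_rms"].to_numpy(dtype=float)
    rms = rms[rms > 0]
    if len(rms) < 100:
        raise ValueError(f"need >= 100 epochs with positive EMG RMS, got {len(rms)}")
    log_rms = np.log(rms)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(log_rms[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    c = km.cluster_centers_.ravel()[order]
    within_sd = np.array(
        [log_rms[km.labels_ == k].std() for k in order]
    )
    mean_within = float(within_sd.mean())
    unimodal = mean_within > 0 and (c[1] - c[0]) < _MIN_CENTER_SEPARATION * mean_within
    if unimodal:
        if fallback_emg_threshold is None:
            fallback_emg_threshold = float(np.exp(np.median(log_rms)))
        warnings.warn(
            "EMG log-RMS distribution looks unimodal; falling back to the "
            f"absolute threshold {fallback_emg_threshold:.4g}",
            stacklevel=2,
        )
        return ScoringThresholds(fallback_emg_threshold, rem_theta_dominance)
    return ScoringThresholds(float(np.exp(c.mean())), rem_theta_dominance)


def majority_smooth(labels: np.ndarray, window: int = 3) -> np.ndarray:
    """Majority vote over a centered window; ties keep the original label."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    half = window // 2
    out = labels.copy()
    for i in range(len(labels)):
        lo, hi = max(0, i - half), min(len(labels), i + half + 1)
        vals, counts = np.unique(labels[lo:hi].astype(str), return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        if len(winners) == 1:
            out[i] = winners[0]
    return out


def score_epochs(
    features: pd.DataFrame,
    thresholds: ScoringThresholds,
    epoch_length_s: float = 5.0,
    smooth: bool = True,
) -> StateSequence:
    """Score each epoch WAKE/NREM/REM; undefined-ratio epochs become UNKNOWN."""
    emg = features["emg_rms"].to_numpy(dtype=float)
    ratio = features["dt_ratio"].to_numpy(dtype=float)  # delta/theta
    labels = np.empty(len(features), dtype=object)
    undefined = ~np.isfinite(ratio)
    wake = emg > thresholds.emg_threshold
    # theta dominance is a cut on theta/delta, i.e. 1/dt_ratio
    rem = ~wake & ~undefined & (1.0 / np.where(ratio > 0, ratio, np.inf) > thresholds.rem_theta_dominance)
    labels[:] = "NREM"
    labels[rem] = "REM"
    labels[wake] = "WAKE"
    labels[undefined & ~wake] = "UNKNOWN"
    if smooth:
        labels = majority_smooth(labels, window=3)
    t0 = float(features["t_start_s"].iloc[0]) if len(features) else 0.0
    return StateSequence(labels=labels, epoch_length_s=epoch_length_s, start_time_s=t0)


def scoring_accuracy(predicted: StateSequence, truth: StateSequence) -> float:
    """Fraction of epochs scored identically to the reference sequence."""
    n = min(predicted.n_epochs, truth.n_epochs)
    if n == 0:
        raise ValueError("empty sequences")
    return float(np.mean(predicted.labels[:n] == truth.labels[:n]))
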