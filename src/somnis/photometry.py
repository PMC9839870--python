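"""Fiber-photometry processing: 1-Hz binning, baseline fits, dF/F0, z-scores.

The raw demodulated fluorescence is autofluorescence-subtracted and averaged
into contiguous 1-s bins. The slowly varying baseline F0(t) — dominated by
photobleaching — is estimated either by a second-order exponential fit on
the pre-injection baseline window (extrapolated over the session) or by a
centered 100-s moving average. dF/F0 is z-scored against the baseline
window, and the post-treatment effect is summarized as the fold change of
the z-score SD, which equals SD_post / SD_baseline of dF/F0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Moving-average baseline window (s).
MA_WINDOW_S = 100.0


@dataclass
class PhotometryResult:
    """1-Hz dF/F0 and z-score series with the post-window fold change."""

    t_s: np.ndarray
    dff: np.ndarray
    zscore: np.ndarray
    f0: np.ndarray
    baseline_sd: float
    fold_change: float
    baseline_mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t_s, "f0": self.f0, "dff": self.dff, "zscore": self.zscore}
        )


def preprocess(
    raw: np.ndarray, sample_rate_hz: float, autofluorescence: float, start_time_s: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract autofluorescence and average into contiguous 1-s bins.

    Returns ``(t_s, series)`` where ``t_s`` is the start time of each 1-s bin.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("empty photometry signal")
    if autofluorescence < 0:
        raise ValueError("autofluorescence must be >= 0")
    if autofluorescence > raw.min():
        warnings.warn(
            "autofluorescence exceeds the signal minimum; corrected trace "
            "will contain negative fluorescence",
            stacklevel=2,
        )
    per_bin = int(round(sample_rate_hz))
    n_bins = raw.size // per_bin
    if n_bins == 0:
        raise ValueError("signal shorter than one 1-s bin")
    binned = (raw[: n_bins * per_bin] - autofluorescence).reshape(n_bins, per_bin).mean(axis=1)
    return start_time_s + np.arange(n_bins, dtype=np.float64), binned


def _exp2(t: np.ndarray, a: float, tau1: float, b: float, tau2: float, c: float) -> np.ndarray:
    return a * np.exp(-t / tau1) + b * np.exp(-t / tau2) + c


def fit_baseline(
    t_s: np.ndarray,
    series: np.ndarray,
    baseline_window: tuple[float, float] | None = None,
    mode: str = "exp2",
) -> np.ndarray:
    """Estimate the baseline F0(t) over the whole series.

    ``exp2`` fits a double exponential ``a*exp(-t/tau1) + b*exp(-t/tau2) + c``
    (both time constants constrained positive) on the baseline window and
    extrapolates; non-convergence falls back to the moving average with a
    warning. ``moving_average`` is a centered 100-s running mean of the full
    series (windows truncated at the edges).
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    series = np.asarray(series, dtype=np.float64)
    if mode == "moving_average":
        w = int(round(MA_WINDOW_S / (t_s[1] - t_s[0]))) if len(t_s) > 1 else 1
        w += 1 - w % 2  # odd length so the centered window is symmetric
        return (
            pd.Series(series).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
        )
    if mode != "exp2":
        raise ValueError(f"unknown baseline mode {mode!r}")
    if baseline_window is None:
        baseline_window = (t_s[0], t_s[-1] + 1.0)
    m = (t_s >= baseline_window[0]) & (t_s < baseline_window[1])
    if (baseline_window[1] - baseline_window[0]) < 60 or m.sum() < 10:
        raise ValueError("exp2 mode needs a baseline window of at least 60 s")
    tb, yb = t_s[m] - t_s[m][0], series[m]
    span = max(tb[-1], 1.0)
    amp = max(yb.max() - yb.min(), 1e-12)
    # bleaching decays toward a positive asymptote: amplitudes and offset
    # are constrained nonnegative so the extrapolated F0 stays positive
    p0 = [amp, span / 3.0, amp / 2.0, span * 3.0, max(yb.min(), 1e-12)]
    try:
        popt, _ = curve_fit(
            _exp2,
            tb,
            yb,
            p0=p0,
            bounds=([0.0, 1e-6, 0.0, 1e-6, 0.0], np.inf),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        warnings.warn(
            "double-exponential baseline fit failed to converge; "
            "falling back to the 100-s moving average",
            stacklevel=2,
        )
        return fit_baseline(t_s, series, baseline_window, mode="moving_average")
    return _exp2(t_s - t_s[m][0], *popt)


def dff_zscore(
    t_s: np.ndarray,
    series: np.ndarray,
    f0: np.ndarray,
    baseline_window: tuple[float, float],
    post_window: tuple[float, float],
    baseline_mode: str = "exp2",
) -> PhotometryResult:
    """dF/F0, baseline-referenced z-score, and post-window SD fold change.

    The z-score is centered and scaled by the dF/F0 mean and SD over the
    baseline window; ``fold_change`` is the SD of the z-score over the post
    window, i.e. SD_post / SD_baseline of dF/F0.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    series = np.asarray(series, dtype=np.float64)
    f0 = np.asarray(f0, dtype=np.float64)
    if np.any(f0 <= 0):
        raise ValueError("F0 must be strictly positive over the evaluation span")
    dff = (series - f0) / f0
    base = (t_s >= baseline_window[0]) & (t_s < baseline_window[1])
    post = (t_s >= post_window[0]) & (t_s < post_window[1])
    if base.sum() < 2 or post.sum() < 2:
        raise ValueError("baseline and post windows must each cover >= 2 s")
    mu, sd = float(dff[base].mean()), float(dff[base].std())
    if sd == 0:
        raise ValueError("degenerate baseline: zero dF/F0 standard deviation")
    z = (dff - mu) / sd
    return PhotometryResult(
        t_s=t_s,
        dff=dff,
        zscore=z,
        f0=f0,
        baseline_sd=sd,
        fold_change=float(z[post].std()),
        baseline_mode=baseline_mode,
    )


def analyze_photometry(
    raw: np.ndarray,
    sample_rate_hz: float,
    autofluorescence: float,
    baseline_window: tuple[float, float],
    post_window: tuple[float, float],
    mode: str = "exp2",
    start_time_s: float = 0.0,
    fit_window: tuple[float, float] | None = None,
) -> PhotometryResult:
    """Full photometry chain: binning, baseline fit, dF/F0 and fold change.

    ``fit_window`` is the span the exp2 baseline is fitted on (default: the
    z-score baseline window itself); use the whole pre-injection recording
    when it is longer than the 5-min normalization window.
    """
    t_s, series = preprocess(raw, sample_rate_hz, autofluorescence, start_time_s)
    f0 = fit_baseline(t_s, series, fit_window or baseline_window, mode=mode)
    return dff_zscore(t_s, series, f0, baseline_window, post_window, baseline_mode=mode)
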