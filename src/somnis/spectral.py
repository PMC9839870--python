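"""Per-epoch EEG band powers, delta/theta ratio and EMG RMS.

These four numbers per 5-s epoch are the feature space for both sleep
scoring and the anesthesia-depth analysis. Power is computed from a
Hann-tapered periodogram zero-padded to a frequency grid of at most
``MAX_DF_HZ`` (0.18 Hz) spacing, and integrated over half-open bands so
adjacent bands never double-count a grid point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datamodel import DEFAULT_EPOCH_S, Recording, slice_epochs

#: Canonical EEG bands (Hz): slow-wave delta and hippocampal theta.
DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 10.0)

#: Maximum periodogram grid spacing (Hz).
MAX_DF_HZ = 0.18

#: EpochFeatures CSV column order.
FEATURE_COLUMNS = ("epoch_index", "t_start_s", "delta_power", "theta_power", "dt_ratio", "emg_rms")


def _nfft(n: int, rate: float, max_df: float = MAX_DF_HZ) -> int:
    """Smallest FFT length >= n with grid spacing rate/nfft <= max_df."""
    return max(n, int(np.ceil(rate / max_df)))


def band_power(
    block: np.ndarray, rate: float, band: tuple[float, float], max_df: float = MAX_DF_HZ
) -> float:
    """Periodogram power (signal-units^2) in the half-open band [lo, hi).

    The block is Hann-tapered and zero-padded so the frequency grid spacing
    is at most `max_df`. Summing over all of [0, Nyquist] recovers the
    tapered signal's variance (Parseval).
    """
    block = np.asarray(block, dtype=np.float64)
    if block.size < 2:
        raise ValueError("block must contain at least 2 samples")
    lo, hi = band
    if not (0 <= lo < hi):
        raise ValueError(f"band must satisfy 0 <= lo < hi, got {band}")
    if hi > rate / 2 + 1e-12:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {rate / 2:g} Hz")
    freqs, psd = sps.periodogram(
        block, fs=rate, window="hann", nfft=_nfft(block.size, rate, max_df), scaling="density"
    )
    df = freqs[1] - freqs[0]
    in_band = (freqs >= lo) & (freqs < hi)
    return float(np.sum(psd[in_band]) * df)


def _band_powers_batch(
    blocks: np.ndarray, rate: float, bands: list[tuple[float, float]]
) -> list[np.ndarray]:
    """Vectorized band_power for a stack of equal-length blocks."""
    freqs, psd = sps.periodogram(
        blocks, fs=rate, window="hann", nfft=_nfft(blocks.shape[1], rate), scaling="density", axis=-1
    )
    df = freqs[1] - freqs[0]
    out = []
    for lo, hi in bands:
        in_band = (freqs >= lo) & (freqs < hi)
        out.append(psd[:, in_band].sum(axis=1) * df)
    return out


def emg_rms(block: np.ndarray) -> float:
    """Root-mean-square amplitude of one EMG epoch."""
    block = np.asarray(block, dtype=np.float64)
    return float(np.sqrt(np.mean(block**2)))


def epoch_features(
    rec: Recording, epoch_length_s: float = DEFAULT_EPOCH_S
) -> pd.DataFrame:
    """Per-epoch EEG delta/theta power, delta/theta ratio, and EMG RMS.

    Returns a DataFrame with one row per epoch (columns
    ``FEATURE_COLUMNS``), aligned with :func:`somnis.datamodel.slice_epochs`.
    Epochs with zero theta power get ``dt_ratio = NaN`` (flagged undefined,
    never a silent infinity).
    """
    for name in ("eeg", "emg"):
        if name not in rec:
            raise ValueError(f"recording lacks the required channel {name!r}")
    blocks = slice_epochs(rec, epoch_length_s)
    eeg, emg = blocks["eeg"], blocks["emg"]
    n = eeg.shape[0]
    if n == 0:
        return pd.DataFrame(columns=list(FEATURE_COLUMNS))
    delta, theta = _band_powers_batch(eeg, rec.sample_rate_hz, [DELTA_BAND, THETA_BAND])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(theta > 0, delta / np.where(theta > 0, theta, 1.0), np.nan)
    return pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "t_start_s": rec.start_time_s + np.arange(n) * epoch_length_s,
            "delta_power": delta,
            "theta_power": theta,
            "dt_ratio": ratio,
            "emg_rms": np.sqrt(np.mean(emg**2, axis=1)),
        }
    )
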