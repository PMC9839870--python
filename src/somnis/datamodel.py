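"""Shared data types and time/epoch conventions.

Conventions used throughout the package:

* time is measured in seconds from session start;
* epoch indices are 0-based and epoch/time intervals are half-open
  ``[t0, t1)``;
* absent channels or components are explicit ``None`` / "missing", never
  zero-filled (a zero EMG channel would silently look like anesthesia).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Closed label set for brain-state sequences.
STATES = ("WAKE", "NREM", "REM", "ANESTHESIA", "UNKNOWN")

#: Treatment labels: propofol, isoflurane, ketamine, dexmedetomidine, control.
DRUGS = ("PPF", "ISO", "KET", "DEX", "SALINE")

#: Default polysomnography scoring epoch (s).
DEFAULT_EPOCH_S = 5.0


class FormatError(ValueError):
    """A session file or table does not conform to the documented layout."""


@dataclass
class Recording:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"eeg"``, ``"emg"``,
        ``"photometry"``) to a 1-D float array. All channels must have
        equal length.
    sample_rate_hz
        Sampling rate shared by all channels, > 0.
    start_time_s
        Session time of the first sample.
    """

    channels: dict[str, np.ndarray]
    sample_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not self.channels:
            raise ValueError("Recording needs at least one channel")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channels differ in length: {lengths}")
        self.channels = {
            name: np.asarray(x, dtype=np.float64) for name, x in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels

    def times(self) -> np.ndarray:
        """Sample times in session seconds."""
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class TraceMatrix:
    """Nonnegative single-neuron calcium activity, neurons x frames.

    ``neuron_ids`` are persistent identifiers stable across sessions (the
    cross-session registration that produces them is upstream of this
    package).
    """

    values: np.ndarray
    frame_rate_hz: float = 5.0
    neuron_ids: tuple[str, ...] = ()
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (neurons x frames)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if np.any(self.values < 0):
            raise ValueError("trace values must be nonnegative")
        if not self.neuron_ids:
            self.neuron_ids = tuple(f"n{i:04d}" for i in range(self.values.shape[0]))
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must match number of rows")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class TreatmentEvent:
    """A drug injection with its baseline and candidate post windows.

    ``baseline_window`` is the 5-min active-EMG reference period before the
    injection; ``post_window_candidate`` bounds the sliding-window search
    for the anesthesia-depth analysis. Both are half-open ``(t0, t1)`` in
    session seconds.
    """

    drug: str
    injection_time_s: float
    baseline_window: tuple[float, float]
    post_window_candidate: tuple[float, float]

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")
        if not self.baseline_window[1] <= self.injection_time_s:
            raise ValueError("baseline_window must precede injection_time_s")
        for w in (self.baseline_window, self.post_window_candidate):
            if not w[0] < w[1]:
                raise ValueError(f"window {w} must satisfy t0 < t1")


@dataclass
class StateSequence:
    """Per-epoch brain-state labels on a fixed epoch grid."""

    labels: np.ndarray
    epoch_length_s: float = DEFAULT_EPOCH_S
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be > 0")
        bad = set(self.labels) - set(STATES)
        if bad:
            raise ValueError(f"labels outside the allowed set: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def epoch_times(self) -> np.ndarray:
        """Start time of each epoch in session seconds."""
        return self.start_time_s + np.arange(self.n_epochs) * self.epoch_length_s

    def mask(self, state: str) -> np.ndarray:
        return self.labels == state

    def intervals(self, state: str) -> list[tuple[float, float]]:
        """Half-open time intervals of maximal runs of `state`."""
        out: list[tuple[float, float]] = []
        m = self.mask(state)
        i = 0
        while i < len(m):
            if m[i]:
                j = i
                while j < len(m) and m[j]:
                    j += 1
                t = self.start_time_s
                out.append((t + i * self.epoch_length_s, t + j * self.epoch_length_s))
                i = j
            else:
                i += 1
        return out

    def state_seconds(self, state: str) -> float:
        return float(self.mask(state).sum()) * self.epoch_length_s


@dataclass
class EpochInterval:
    """Half-open run of epochs ``[start_epoch, start_epoch + n_epochs)``."""

    start_epoch: int
    n_epochs: int

    def __post_init__(self) -> None:
        if self.start_epoch < 0 or self.n_epochs <= 0:
            raise ValueError("start_epoch >= 0 and n_epochs > 0 required")

    @property
    def stop_epoch(self) -> int:
        return self.start_epoch + self.n_epochs


@dataclass
class Session:
    """One recording session: raw signals plus optional derived components.

    Components absent from the source file stay ``None``; ``missing``
    records which of the documented pieces were not found.
    """

    ephys: Recording | None = None
    photometry: Recording | None = None
    traces: TraceMatrix | None = None
    states: StateSequence | None = None
    events: list[TreatmentEvent] = field(default_factory=list)
    missing: tuple[str, ...] = ()


def slice_epochs(
    rec: Recording, epoch_length_s: float = DEFAULT_EPOCH_S
) -> dict[str, np.ndarray]:
    """Cut every channel into consecutive fixed-length epochs.

    Returns a mapping from channel name to a ``(n_epochs, samples_per_epoch)``
    array. A trailing partial epoch is discarded; the blocks tile the prefix
    of the recording with no gaps or overlaps.
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be > 0")
    spe = int(round(epoch_length_s * rec.sample_rate_hz))
    n_epochs = int(np.floor(rec.duration_s / epoch_length_s))
    if n_epochs == 0:
        warnings.warn(
            f"recording ({rec.duration_s:.3g} s) shorter than one "
            f"{epoch_length_s:.3g}-s epoch; returning empty blocks",
            stacklevel=2,
        )
    return {
        name: x[: n_epochs * spe].reshape(n_epochs, spe)
        for name, x in rec.channels.items()
    }


def interval_to_epochs(
    interval: tuple[float, float], epoch_length_s: float, start_time_s: float = 0.0
) -> EpochInterval:
    """Epoch-grid cover of a half-open time interval (fully contained epochs)."""
    t0, t1 = interval
    e0 = int(np.ceil((t0 - start_time_s) / epoch_length_s - 1e-9))
    e1 = int(np.floor((t1 - start_time_s) / epoch_length_s + 1e-9))
    if e1 <= e0:
        raise ValueError(f"interval {interval} contains no whole epoch")
    return EpochInterval(start_epoch=max(e0, 0), n_epochs=e1 - max(e0, 0))
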