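"""HDF5 session container and CSV export of derived tables.

One HDF5 file per session with groups ``/eeg``, ``/emg``, ``/photometry``,
``/traces``, ``/states``, ``/events``. Raw signals are stored as float64 so
the round trip is bit-identical; derived statistics are exported to CSV so
they stay diff-able.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datamodel import (
    FormatError,
    Recording,
    Session,
    StateSequence,
    TraceMatrix,
    TreatmentEvent,
)

_EVENT_COLS = ("drug", "injection_time_s", "baseline_t0", "baseline_t1", "post_t0", "post_t1")


def write_session(path: str | Path, session: Session) -> None:
    """Write a Session to the documented HDF5 layout."""
    with h5py.File(path, "w") as f:
        if session.ephys is not None:
            rec = session.ephys
            for name in rec.channels:
                g = f.create_group(name)
                g.create_dataset("data", data=rec.channels[name])
                g.attrs["sample_rate_hz"] = rec.sample_rate_hz
                g.attrs["start_time_s"] = rec.start_time_s
        if session.photometry is not None:
            rec = session.photometry
            g = f.create_group("photometry")
            g.create_dataset("data", data=rec.channels["photometry"])
            g.attrs["sample_rate_hz"] = rec.sample_rate_hz
            g.attrs["start_time_s"] = rec.start_time_s
        if session.traces is not None:
            tm = session.traces
            g = f.create_group("traces")
            g.create_dataset("values", data=tm.values)
            g.create_dataset(
                "neuron_ids", data=np.array(tm.neuron_ids, dtype=h5py.string_dtype())
            )
            g.attrs["frame_rate_hz"] = tm.frame_rate_hz
            g.attrs["start_time_s"] = tm.start_time_s
        if session.states is not None:
            ss = session.states
            g = f.create_group("states")
            g.create_dataset(
                "labels", data=np.array(list(ss.labels), dtype=h5py.string_dtype())
            )
            g.attrs["epoch_length_s"] = ss.epoch_length_s
            g.attrs["start_time_s"] = ss.start_time_s
        if session.events:
            g = f.create_group("events")
            g.create_dataset(
                "drug",
                data=np.array([e.drug for e in session.events], dtype=h5py.string_dtype()),
            )
            g.create_dataset(
                "injection_time_s", data=[e.injection_time_s for e in session.events]
            )
            g.create_dataset("baseline_t0", data=[e.baseline_window[0] for e in session.events])
            g.create_dataset("baseline_t1", data=[e.baseline_window[1] for e in session.events])
            g.create_dataset("post_t0", data=[e.post_window_candidate[0] for e in session.events])
            g.create_dataset("post_t1", data=[e.post_window_candidate[1] for e in session.events])


def _read_signal_group(f: h5py.File, name: str) -> tuple[np.ndarray, float, float]:
    g = f[name]
    if "data" not in g:
        raise FormatError(f"group /{name} lacks the 'data' dataset")
    if "sample_rate_hz" not in g.attrs:
        raise FormatError(f"group /{name} lacks the 'sample_rate_hz' attribute")
    rate = float(g.attrs["sample_rate_hz"])
    if rate <= 0:
        raise FormatError(f"/{name} sample_rate_hz must be > 0, got {rate}")
    return np.asarray(g["data"]), rate, float(g.attrs.get("start_time_s", 0.0))


def read_session(path: str | Path) -> Session:
    """Read a Session; absent components are flagged missing, not defaulted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    missing: list[str] = []
    with h5py.File(path, "r") as f:
        ephys = None
        chans: dict[str, np.ndarray] = {}
        rate = start = None
        for name in ("eeg", "emg"):
            if name in f:
                data, r, s = _read_signal_group(f, name)
                if rate is not None and (r != rate or s != start):
                    raise FormatError("/eeg and /emg must share rate and start time")
                rate, start = r, s
                chans[name] = data
            else:
                missing.append(name)
        if chans:
            ephys = Recording(channels=chans, sample_rate_hz=rate, start_time_s=start)

        photometry = None
        if "photometry" in f:
            data, r, s = _read_signal_group(f, "photometry")
            photometry = Recording(
                channels={"photometry": data}, sample_rate_hz=r, start_time_s=s
            )
        else:
            missing.append("photometry")

        traces = None
        if "traces" in f:
            g = f["traces"]
            if "values" not in g or "frame_rate_hz" not in g.attrs:
                raise FormatError("/traces needs 'values' and attribute 'frame_rate_hz'")
            traces = TraceMatrix(
                values=np.asarray(g["values"]),
                frame_rate_hz=float(g.attrs["frame_rate_hz"]),
                neuron_ids=tuple(x.decode() for x in g["neuron_ids"][:])
                if "neuron_ids" in g
                else (),
                start_time_s=float(g.attrs.get("start_time_s", 0.0)),
            )
        else:
            missing.append("traces")

        states = None
        if "states" in f:
            g = f["states"]
            if "labels" not in g or "epoch_length_s" not in g.attrs:
                raise FormatError("/states needs 'labels' and attribute 'epoch_length_s'")
            states = StateSequence(
                labels=np.array([x.decode() for x in g["labels"][:]], dtype=object),
                epoch_length_s=float(g.attrs["epoch_length_s"]),
                start_time_s=float(g.attrs.get("start_time_s", 0.0)),
            )
        else:
            missing.append("states")

        events: list[TreatmentEvent] = []
        if "events" in f:
            g = f["events"]
            for col in ("drug", "injection_time_s", "baseline_t0", "baseline_t1", "post_t0", "post_t1"):
                if col not in g:
                    raise FormatError(f"/events lacks the '{col}' column")
            for i in range(len(g["drug"])):
                events.append(
                    TreatmentEvent(
                        drug=g["drug"][i].decode(),
                        injection_time_s=float(g["injection_time_s"][i]),
                        baseline_window=(float(g["baseline_t0"][i]), float(g["baseline_t1"][i])),
                        post_window_candidate=(float(g["post_t0"][i]), float(g["post_t1"][i])),
                    )
                )
        else:
            missing.append("events")

    return Session(
        ephys=ephys,
        photometry=photometry,
        traces=traces,
        states=states,
        events=events,
        missing=tuple(missing),
    )


def write_states_csv(path: str | Path, states: StateSequence) -> None:
    pd.DataFrame(
        {
            "epoch_index": np.arange(states.n_epochs),
            "t_start_s": states.epoch_times(),
            "label": list(states.labels),
        }
    ).to_csv(path, index=False)


def read_states_csv(path: str | Path, epoch_length_s: float = 5.0) -> StateSequence:
    df = pd.read_csv(path)
    start = float(df["t_start_s"].iloc[0]) if len(df) else 0.0
    return StateSequence(
        labels=df["label"].to_numpy(dtype=object),
        epoch_length_s=epoch_length_s,
        start_time_s=start,
    )
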