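"""End-to-end orchestration of the synthetic study from one config.

``run_all`` synthesizes one session per condition (anesthetics, saline
control, sleep-wake), then runs the full analysis sequence — epoch
features, sleep scoring, photometry, DBI depth search, NMI tables with
response classes and clustering, PCA state space, and the entropy
bootstrap — writing versioned CSV/JSON outputs plus a run log with every
parameter and seed. The same master seed reproduces every numeric output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import depth as depth_mod
from . import modulation, photometry, population, scoring, session_io, spectral, synth
from .datamodel import Session, TraceMatrix


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def default_demo_config(seed: int = 1, out_dir: str = "somnis_demo_out") -> dict[str, Any]:
    """Bundled desk-scale demo: two anesthetics, a saline control, sleep."""
    return {
        "seed": seed,
        "out_dir": out_dir,
        "n_neurons": 40,
        "conditions": {
            "ISO": {"kind": "anesthesia", "drug": "ISO", "baseline_s": 360.0, "post_s": 1440.0},
            "PPF": {"kind": "anesthesia", "drug": "PPF", "baseline_s": 360.0, "post_s": 1440.0},
            "SALINE": {"kind": "anesthesia", "drug": "SALINE", "baseline_s": 360.0, "post_s": 1440.0},
            "SLEEP": {"kind": "sleep", "total_s": 2400.0},
        },
        "entropy": {"n_resamples": 500},
        "statespace": {"bin_length_s": 15.0},
        "save_sessions": True,
    }


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as f:
        return yaml.safe_load(f)


def _condition_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _dump_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def concatenate_traces(parts: list[TraceMatrix]) -> tuple[TraceMatrix, list[float]]:
    """Splice per-session traces of the same neurons onto one time axis.

    Returns the combined matrix and the session time offsets on the new
    axis (sessions are laid end to end).
    """
    ids = parts[0].neuron_ids
    for p in parts:
        if p.neuron_ids != ids or p.frame_rate_hz != parts[0].frame_rate_hz:
            raise ValueError("all sessions must share neuron ids and frame rate")
    offsets = []
    t = 0.0
    for p in parts:
        offsets.append(t)
        t += p.duration_s
    combined = TraceMatrix(
        values=np.concatenate([p.values for p in parts], axis=1),
        frame_rate_hz=parts[0].frame_rate_hz,
        neuron_ids=ids,
        start_time_s=0.0,
    )
    return combined, offsets


def run_all(config: dict[str, Any], out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the whole synthetic study; returns the report dictionary.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages remain on disk.
    """
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "somnis_out"))
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    n_neurons = int(config.get("n_neurons", 40))
    report: dict[str, Any] = {"seed": master_seed, "conditions": {}}
    log: dict[str, Any] = {"config": config, "stages": []}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                log["stages"].append(
                    {"stage": name, "wall_s": round(time.perf_counter() - self.t0, 3), "ok": exc is None}
                )
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc

        return _Ctx()

    # --- synthesis -------------------------------------------------------
    sessions: dict[str, Session] = {}
    truths: dict[str, synth.GroundTruth] = {}
    configs: dict[str, synth.SimulationConfig] = {}
    with _stage("synth"):
        cond_items = list(config["conditions"].items())
        # one shared neuron population across all sessions (registered ids)
        spec_rng = np.random.default_rng(np.random.SeedSequence([master_seed, 9999]))
        neurons = synth.sample_neuron_specs(n_neurons, spec_rng)
        for idx, (name, c) in enumerate(cond_items):
            seed = _condition_seed(master_seed, idx)
            if c["kind"] == "anesthesia":
                cfg = synth.anesthesia_config(
                    drug=c.get("drug", name),
                    seed=seed,
                    n_neurons=n_neurons,
                    baseline_s=float(c.get("baseline_s", 360.0)),
                    post_s=float(c.get("post_s", 1440.0)),
                )
            elif c["kind"] == "sleep":
                cfg = synth.sleep_config(seed=seed, n_neurons=n_neurons, total_s=float(c.get("total_s", 2400.0)))
            else:
                raise ValueError(f"unknown condition kind {c['kind']!r}")
            session, truth = synth.make_session(cfg, neurons=neurons)
            if not c.get("include_traces", True):
                session = dataclasses.replace(session, traces=None)
            sessions[name], truths[name], configs[name] = session, truth, cfg
            if config.get("save_sessions", True):
                session_io.write_session(out / f"session_{name}.h5", session)

    # --- epoch features --------------------------------------------------
    features: dict[str, pd.DataFrame] = {}
    with _stage("features"):
        for name, session in sessions.items():
            df = spectral.epoch_features(session.ephys, configs[name].epoch_length_s)
            df.to_csv(out / f"features_{name}.csv", index=False)
            features[name] = df

    # --- sleep scoring ---------------------------------------------------
    with _stage("scoring"):
        for name, c in config["conditions"].items():
            if c["kind"] != "sleep":
                continue
            thr = scoring.fit_thresholds(features[name])
            scored = scoring.score_epochs(features[name], thr)
            session_io.write_states_csv(out / f"hypnogram_{name}.csv", scored)
            acc = scoring.scoring_accuracy(scored, truths[name].states)
            report["conditions"].setdefault(name, {})["scoring_accuracy"] = acc
            sessions[name] = dataclasses.replace(sessions[name], states=scored)

    # --- anesthesia depth ------------------------------------------------
    depth_results: dict[str, depth_mod.DepthResult] = {}
    with _stage("depth"):
        for name, session in sessions.items():
            if not session.events:
                continue
            event = session.events[0]
            res = depth_mod.depth_search(features[name], event)
            depth_results[name] = res
            report["conditions"].setdefault(name, {})["depth"] = {
                "selected_window": res.selected_window,
                "dbi": res.dbi,
            }
            _dump_json(
                out / f"depth_{name}.json",
                {"selected_window": res.selected_window, "dbi": res.dbi, "candidates": res.candidates.to_dict("records")},
            )

    # --- photometry ------------------------------------------------------
    with _stage("photometry"):
        for name, session in sessions.items():
            if session.photometry is None or not session.events or session.events[0].drug == "SALINE":
                continue
            event = session.events[0]
            post = depth_results[name].selected_window if name in depth_results else event.post_window_candidate
            res = photometry.analyze_photometry(
                session.photometry.channels["photometry"],
                session.photometry.sample_rate_hz,
                autofluorescence=configs[name].autofluorescence,
                baseline_window=event.baseline_window,
                post_window=post,
                mode="exp2",
                fit_window=(0.0, event.injection_time_s),
            )
            res.to_frame().to_csv(out / f"photometry_{name}.csv", index=False)
            report["conditions"].setdefault(name, {})["photometry"] = {
                "baseline_sd": res.baseline_sd,
                "fold_change": res.fold_change,
            }

    # --- NMI -------------------------------------------------------------
    nmi_tables = []
    with _stage("nmi"):
        for name, session in sessions.items():
            if not session.events or session.events[0].drug == "SALINE" or session.traces is None:
                continue
            event = session.events[0]
            post = depth_results[name].selected_window
            tbl = modulation.nmi_table(session.traces, event.drug, event.baseline_window, post)
            nmi_tables.append(tbl)
        for name, c in config["conditions"].items():
            if c["kind"] == "sleep" and sessions[name].states is not None and sessions[name].traces is not None:
                nmi_tables.append(modulation.sleepwake_table(sessions[name].traces, sessions[name].states))
        table = pd.concat(nmi_tables, ignore_index=True) if nmi_tables else pd.DataFrame(columns=list(modulation.NMI_COLUMNS))
        table.to_csv(out / "nmi.csv", index=False)
        drug_conds = sorted(c for c in table["condition"].unique() if c != "SLEEPWAKE")
        report["nmi_fraction_inhibited"] = {
            c: float((table[table["condition"] == c]["response_class"] == "INHIBITED").mean())
            for c in drug_conds
        }
        if len(drug_conds) >= 2:
            pairs = []
            for i, a in enumerate(drug_conds):
                for b in drug_conds[i + 1 :]:
                    pairs.append(modulation.overlap_and_correlation(table, a, b))
            _dump_json(out / "overlap.json", pairs)
            report["overlap_pairs"] = len(pairs)
            wide = table[table["condition"].isin(drug_conds)].pivot(
                index="neuron_id", columns="condition", values="nmi"
            ).dropna()
            if len(wide) >= 3:
                labels, _ = modulation.cluster_responses(wide.to_numpy(), k=3)
                pd.DataFrame({"neuron_id": wide.index, "cluster": labels}).to_csv(
                    out / "clusters.csv", index=False
                )

    # --- state space + entropy ------------------------------------------
    with _stage("statespace"):
        parts, segments = _combined_segments(config, sessions, truths, depth_results)
        if parts is not None:
            bin_s = float(config.get("statespace", {}).get("bin_length_s", 15.0))
            res = population.build_state_space(parts, segments, bin_length_s=bin_s)
            res.points.to_csv(out / "statespace_points.csv", index=False)
            sep = res.separation_matrix()
            sep.to_csv(out / "statespace_separation.csv")
            report["statespace_min_separation"] = float(np.nanmin(sep.to_numpy()))

    with _stage("entropy"):
        n_res = int(config.get("entropy", {}).get("n_resamples", 500))
        entropy_out = {}
        for name, session in sessions.items():
            if not session.events or session.events[0].drug == "SALINE" or name not in depth_results:
                continue
            traces = session.traces
            if traces is None:
                raise ValueError(f"condition {name!r} lacks traces for the entropy stage")
            event = session.events[0]
            base_pool = [(max(0.0, event.baseline_window[0] - 60.0), event.injection_time_s)]
            res = population.entropy_bootstrap(
                traces,
                base_pool,
                [depth_results[name].selected_window],
                n_resamples=n_res,
                seed=_condition_seed(master_seed, 777),
                condition=event.drug,
            )
            entropy_out[name] = {"delta_entropy_pct": res.delta_entropy_pct, "ci95": res.ci95}
        for name, c in config["conditions"].items():
            if c["kind"] != "sleep":
                continue
            traces = sessions[name].traces
            if traces is None:
                raise ValueError(f"condition {name!r} lacks traces for the entropy stage")
            truth_states = truths[name].states
            wake = [iv for iv in truth_states.intervals("WAKE") if iv[1] - iv[0] >= 120.0]
            nrem = [iv for iv in truth_states.intervals("NREM") if iv[1] - iv[0] >= 120.0]
            if wake and nrem:
                res = population.entropy_bootstrap(
                    traces, wake, nrem, n_resamples=n_res,
                    seed=_condition_seed(master_seed, 778), condition="NREM",
                )
                entropy_out["NREM"] = {"delta_entropy_pct": res.delta_entropy_pct, "ci95": res.ci95}
        _dump_json(out / "entropy.json", entropy_out)
        report["entropy"] = entropy_out

    _dump_json(out / "report.json", report)
    _dump_json(out / "run_log.json", log)
    return report


def _combined_segments(config, sessions, truths, depth_results):
    """Splice all sessions' traces and map conditions to time segments."""
    names = list(sessions)
    parts = [sessions[n].traces for n in names]
    if any(p is None for p in parts):
        return None, None
    combined, offsets = concatenate_traces(parts)
    segments: dict[str, list[tuple[float, float]]] = {}
    for name, off in zip(names, offsets):
        c = config["conditions"][name]
        if c["kind"] == "anesthesia" and name in depth_results:
            w0, w1 = depth_results[name].selected_window
            segments[name] = [(off + w0, off + w1)]
        elif c["kind"] == "sleep":
            st = truths[name].states
            for state in ("WAKE", "NREM"):
                ivals = [(off + a, off + b) for a, b in st.intervals(state) if b - a >= 60.0]
                if ivals:
                    segments[state] = segments.get(state, []) + ivals
    segments = {k: v for k, v in segments.items() if v}
    if len(segments) < 2:
        return None, None
    return combined, segments
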