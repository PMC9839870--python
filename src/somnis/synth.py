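"""Synthetic session generator with ground truth.

Generates EEG/EMG, single-neuron calcium traces and fiber photometry with
the statistical structure the analysis stages assume:

* state-dependent EEG band power (delta-rich NREM/anesthesia, theta-rich
  REM) and state-dependent EMG amplitude;
* wake/NREM/REM bout structure from a stochastic sleep-cycle sampler or an
  explicit bout plan;
* per-neuron state tuning (wake-active / sleep-active gains) and
  per-anesthetic multiplicative modulation (inhibited / excited /
  insensitive gains) driving inhomogeneous-Poisson events convolved with a
  GCaMP6s-like kernel;
* population photometry with double-exponential bleaching and a constant
  autofluorescence offset.

Every parameter the generator sets (state sequence, anesthesia interval,
modulation gains, bleach curve) is recoverable by the corresponding
analysis module; the ground-truth object makes those recovery tests
possible. One seed fixes the whole session byte-for-byte.

Anesthesia onset is not instantaneous: after the injection a sigmoid ramp
(default 60 s) blends EEG power, EMG amplitude and drug gain from the
awake values to the anesthetized values; the ground-truth anesthesia
interval is the post-ramp plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    DEFAULT_EPOCH_S,
    Recording,
    Session,
    StateSequence,
    TraceMatrix,
    TreatmentEvent,
)
from .spectral import DELTA_BAND, THETA_BAND  # band edges shared with the analyzer

# Band-power tables (signal-units^2) per state: delta, theta, broadband.
STATE_POWERS: dict[str, dict[str, float]] = {
    "WAKE": {"delta": 1.0, "theta": 1.0, "broadband": 2.0},
    "NREM": {"delta": 6.0, "theta": 1.0, "broadband": 2.0},
    "REM": {"delta": 0.8, "theta": 4.0, "broadband": 1.5},
    "ANESTHESIA": {"delta": 8.0, "theta": 1.0, "broadband": 2.0},
    "UNKNOWN": {"delta": 1.0, "theta": 1.0, "broadband": 2.0},
}

# EMG white-noise amplitude (signal units) per state.
EMG_AMPLITUDE: dict[str, float] = {
    "WAKE": 1.0,
    "NREM": 0.2,
    "REM": 0.1,
    "ANESTHESIA": 0.05,
    "UNKNOWN": 0.5,
}

BROADBAND = (0.5, 30.0)

_BAND_EDGES = {"delta": DELTA_BAND, "theta": THETA_BAND, "broadband": BROADBAND}


@dataclass
class GcampKernel:
    """Exponential rise/decay calcium-indicator kernel, peak-normalized."""

    rise_s: float = 0.2
    decay_s: float = 1.5

    def sample(self, frame_rate_hz: float) -> np.ndarray:
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("kernel time constants must be > 0")
        t = np.arange(0, 6 * self.decay_s, 1.0 / frame_rate_hz)
        k = (1 - np.exp(-t / self.rise_s)) * np.exp(-t / self.decay_s)
        return k / k.max()


@dataclass
class NeuronSpec:
    """Ground-truth tuning of one simulated neuron.

    ``state_gain`` multiplies the WAKE event rate per brain state (NREM
    gain > 1 makes the neuron sleep-active); ``drug_gain`` multiplies the
    rate inside the anesthesia plateau (< 1 inhibited, > 1 excited).
    """

    neuron_id: str
    base_rate_hz: float = 0.3
    state_gain: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 1.0, "NREM": 1.0, "REM": 1.0, "ANESTHESIA": 1.0, "UNKNOWN": 1.0}
    )
    drug_gain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_rate_hz < 0:
            raise ValueError("base_rate_hz must be >= 0")
        for g in list(self.state_gain.values()) + list(self.drug_gain.values()):
            if g < 0:
                raise ValueError("gains must be >= 0")

    def expected_nmi(self, drug: str) -> float:
        """Closed-form NMI implied by the drug gain f: (f - 1) / (f + 1)."""
        f = self.drug_gain.get(drug, 1.0)
        return (f - 1.0) / (f + 1.0)


@dataclass
class SleepCyclePlan:
    """Stochastic WAKE -> NREM -> (REM) -> WAKE cycling.

    Bout durations are exponential with the given means, floored at
    ``min_bout_s``; after each NREM bout a REM bout follows with
    probability ``rem_probability``.
    """

    total_s: float = 3600.0
    mean_bout_s: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 200.0, "NREM": 120.0, "REM": 60.0}
    )
    rem_probability: float = 0.5
    min_bout_s: float = 20.0


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic session."""

    seed: int = 0
    n_neurons: int = 50
    plan: list[tuple[str, float]] | SleepCyclePlan = field(
        default_factory=lambda: [("WAKE", 600.0)]
    )
    event: TreatmentEvent | None = None
    epoch_length_s: float = DEFAULT_EPOCH_S
    sample_rate_hz: float = 250.0  # EEG/EMG synthesis rate
    frame_rate_hz: float = 5.0  # calcium trace frame rate
    state_powers: dict[str, dict[str, float]] = field(default_factory=lambda: {k: dict(v) for k, v in STATE_POWERS.items()})
    emg_amplitude: dict[str, float] = field(default_factory=lambda: dict(EMG_AMPLITUDE))
    kernel: GcampKernel = field(default_factory=GcampKernel)
    trace_noise_sd: float = 0.01
    ramp_s: float = 60.0  # anesthesia-onset sigmoid duration
    photometry_rate_hz: float = 100.0
    bleach_amplitudes: tuple[float, float] = (0.5, 0.2)
    bleach_taus_s: tuple[float, float] = (900.0, 120.0)
    autofluorescence: float = 0.1
    photometry_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if isinstance(self.plan, list):
            for state, dur in self.plan:
                if dur <= 0:
                    raise ValueError(f"bout duration must be > 0, got {dur} for {state}")
        for tau in self.bleach_taus_s:
            if tau <= 0:
                raise ValueError("bleach taus must be > 0")
        if self.trace_noise_sd < 0 or self.photometry_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class GroundTruth:
    states: StateSequence
    neurons: list[NeuronSpec]
    anesthesia_interval: tuple[float, float] | None
    expected_nmi: dict[str, dict[str, float]]  # drug -> neuron_id -> NMI


# ---------------------------------------------------------------------------
# state sequence


def gen_state_sequence(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> StateSequence:
    """Epoch-grid state labels from the session plan (deterministic per seed)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    eps = cfg.epoch_length_s
    if isinstance(cfg.plan, SleepCyclePlan):
        plan = cfg.plan
        bouts: list[tuple[str, float]] = []
        total = 0.0
        state = "WAKE"
        while total < plan.total_s:
            dur = max(rng.exponential(plan.mean_bout_s[state]), plan.min_bout_s)
            dur = max(round(dur / eps), 1) * eps
            bouts.append((state, dur))
            total += dur
            if state == "WAKE":
                state = "NREM"
            elif state == "NREM":
                state = "REM" if rng.random() < plan.rem_probability else "WAKE"
            else:
                state = "WAKE"
        total_epochs = int(np.floor(plan.total_s / eps))
    else:
        bouts = list(cfg.plan)
        total_epochs = int(np.floor(sum(d for _, d in bouts) / eps))
    labels = []
    for state, dur in bouts:
        labels.extend([state] * int(round(dur / eps)))
    labels = labels[:total_epochs]
    if len(labels) < total_epochs:  # guard against rounding shortfall
        labels.extend([bouts[-1][0]] * (total_epochs - len(labels)))
    return StateSequence(labels=np.array(labels, dtype=object), epoch_length_s=eps)


# ---------------------------------------------------------------------------
# anesthesia-onset blending


def _onset_weight(t: np.ndarray | float, cfg: SimulationConfig) -> np.ndarray | float:
    """0 -> 1 sigmoid over the ramp after the injection (1 at the plateau)."""
    if cfg.event is None:
        return np.zeros_like(np.asarray(t, dtype=float))
    t0 = cfg.event.injection_time_s
    x = (np.asarray(t, dtype=float) - (t0 + cfg.ramp_s / 2)) / (cfg.ramp_s / 10.0)
    w = 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))
    return np.where(np.asarray(t) < t0, 0.0, w)


def anesthesia_interval(cfg: SimulationConfig) -> tuple[float, float] | None:
    """Ground-truth plateau: from ramp end to the end of ANESTHESIA labels."""
    if cfg.event is None or cfg.event.drug == "SALINE":
        return None
    if not isinstance(cfg.plan, list):
        return None
    t = 0.0
    start = stop = None
    for state, dur in cfg.plan:
        if state == "ANESTHESIA":
            start = t if start is None else start
            stop = t + dur
        t += dur
    if start is None:
        return None
    return (max(start, cfg.event.injection_time_s) + cfg.ramp_s, stop)


# ---------------------------------------------------------------------------
# EEG / EMG


def _band_noise(rng: np.random.Generator, n: int, rate: float, band: tuple[float, float], power: float) -> np.ndarray:
    """Band-limited Gaussian noise with the requested variance."""
    if power <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(freqs < band[0]) | (freqs >= band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return x * (np.sqrt(power) / sd)


def gen_eeg_emg(
    states: StateSequence, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> Recording:
    """State-dependent EEG (banded noise) and EMG (scaled white noise).

    Each epoch's EEG is a sum of delta-, theta- and broadband-limited
    Gaussian noise with the state's band-power table; EMG is white noise
    scaled by the state's amplitude. During the anesthesia onset ramp both
    tables are sigmoid-blended from WAKE to ANESTHESIA values.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    spe = int(round(cfg.epoch_length_s * cfg.sample_rate_hz))
    eeg = np.empty(states.n_epochs * spe)
    emg = np.empty_like(eeg)
    t_epochs = states.epoch_times() + cfg.epoch_length_s / 2
    for i, label in enumerate(states.labels):
        if label not in cfg.state_powers:
            raise ValueError(f"unknown state label {label!r}")
        powers = dict(cfg.state_powers[label])
        amp = cfg.emg_amplitude[label]
        if label == "ANESTHESIA" and cfg.event is not None:
            w = float(_onset_weight(t_epochs[i], cfg))
            powers = {
                b: (1 - w) * cfg.state_powers["WAKE"][b] + w * cfg.state_powers["ANESTHESIA"][b]
                for b in powers
            }
            amp = (1 - w) * cfg.emg_amplitude["WAKE"] + w * cfg.emg_amplitude["ANESTHESIA"]
        block = np.zeros(spe)
        for band_name, power in powers.items():
            block += _band_noise(rng, spe, cfg.sample_rate_hz, _BAND_EDGES[band_name], power)
        eeg[i * spe : (i + 1) * spe] = block
        emg[i * spe : (i + 1) * spe] = amp * rng.standard_normal(spe)
    return Recording(
        channels={"eeg": eeg, "emg": emg},
        sample_rate_hz=cfg.sample_rate_hz,
        start_time_s=states.start_time_s,
    )


# ---------------------------------------------------------------------------
# calcium traces


def gen_traces(
    states: StateSequence,
    neurons: list[NeuronSpec],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TraceMatrix, GroundTruth]:
    """Poisson-event calcium traces with state and drug modulation.

    Per neuron the frame-wise event rate is
    ``base_rate * state_gain(state) * drug_factor(t)`` where the drug
    factor blends from 1 to ``drug_gain`` across the onset ramp and stays
    at ``drug_gain`` inside the plateau. Events are convolved with the
    GCaMP kernel; truncated-at-zero Gaussian noise is added.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.frame_rate_hz
    n_frames = int(round(states.duration_s * cfg.frame_rate_hz))
    t = states.start_time_s + np.arange(n_frames) * dt
    epoch_idx = np.minimum(
        ((t - states.start_time_s) / states.epoch_length_s).astype(int), states.n_epochs - 1
    )
    frame_states = states.labels[epoch_idx]
    w = np.asarray(_onset_weight(t, cfg), dtype=float)
    drug = cfg.event.drug if cfg.event is not None else None

    kernel = cfg.kernel.sample(cfg.frame_rate_hz)
    values = np.empty((len(neurons), n_frames))
    for i, spec in enumerate(neurons):
        gains = np.array([spec.state_gain.get(s, 1.0) for s in frame_states])
        rate = spec.base_rate_hz * gains
        if drug is not None:
            f = spec.drug_gain.get(drug, 1.0)
            rate = rate * ((1 - w) + w * f)
        events = rng.poisson(rate * dt).astype(float)
        sig = np.convolve(events, kernel)[:n_frames]
        noise = rng.normal(0.0, cfg.trace_noise_sd, n_frames) if cfg.trace_noise_sd > 0 else 0.0
        values[i] = np.maximum(sig + noise, 0.0)

    tm = TraceMatrix(
        values=values,
        frame_rate_hz=cfg.frame_rate_hz,
        neuron_ids=tuple(s.neuron_id for s in neurons),
        start_time_s=states.start_time_s,
    )
    expected = {}
    if drug is not None:
        expected[drug] = {s.neuron_id: s.expected_nmi(drug) for s in neurons}
    truth = GroundTruth(
        states=states,
        neurons=neurons,
        anesthesia_interval=anesthesia_interval(cfg),
        expected_nmi=expected,
    )
    return tm, truth


# ---------------------------------------------------------------------------
# photometry


def gen_photometry(
    traces: TraceMatrix, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> Recording:
    """Population photometry: mean trace + bleaching + offset + noise."""
    if traces.n_neurons == 0:
        raise ValueError("traces must contain at least one neuron")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pop = traces.values.mean(axis=0)
    t_frames = traces.frame_times()
    n = int(round(traces.duration_s * cfg.photometry_rate_hz))
    t = traces.start_time_s + np.arange(n) / cfg.photometry_rate_hz
    sig = np.interp(t, t_frames, pop)
    a1, a2 = cfg.bleach_amplitudes
    tau1, tau2 = cfg.bleach_taus_s
    bleach = a1 * np.exp(-(t - t[0]) / tau1) + a2 * np.exp(-(t - t[0]) / tau2)
    noise = rng.normal(0.0, cfg.photometry_noise_sd, n) if cfg.photometry_noise_sd > 0 else 0.0
    return Recording(
        channels={"photometry": sig + bleach + cfg.autofluorescence + noise},
        sample_rate_hz=cfg.photometry_rate_hz,
        start_time_s=traces.start_time_s,
    )


# ---------------------------------------------------------------------------
# neuron sampling and stock configurations


def sample_neuron_specs(
    n: int,
    rng: np.random.Generator,
    drugs: tuple[str, ...] = ("PPF", "ISO", "KET", "DEX"),
    p_inhibited: float = 0.6,
    p_excited: float = 0.2,
    p_sleep_active: float = 0.5,
) -> list[NeuronSpec]:
    """Population with the response mix the analyses expect.

    Each neuron is sleep-active (NREM gain > 1) or wake-active (< 1), and
    per drug is inhibited (gain ~ U(0.05, 0.4)), excited (~ U(2, 5)) or
    insensitive (~ U(0.8, 1.25)) with the given probabilities.
    """
    specs = []
    for i in range(n):
        sleep_active = rng.random() < p_sleep_active
        nrem_gain = rng.uniform(1.5, 3.0) if sleep_active else rng.uniform(0.2, 0.7)
        state_gain = {
            "WAKE": 1.0,
            "NREM": float(nrem_gain),
            "REM": float(rng.uniform(0.5, 1.5)),
            "ANESTHESIA": 1.0,
            "UNKNOWN": 1.0,
        }
        drug_gain = {}
        for d in drugs:
            u = rng.random()
            if u < p_inhibited:
                drug_gain[d] = float(rng.uniform(0.05, 0.4))
            elif u < p_inhibited + p_excited:
                drug_gain[d] = float(rng.uniform(2.0, 5.0))
            else:
                drug_gain[d] = float(rng.uniform(0.8, 1.25))
        specs.append(
            NeuronSpec(neuron_id=f"n{i:04d}", state_gain=state_gain, drug_gain=drug_gain)
        )
    return specs


def correlated_specs(
    n: int,
    rng: np.random.Generator,
    drug_a: str,
    drug_b: str,
    rho: float,
    nmi_mean: float = -0.2,
    nmi_sd: float = 0.35,
) -> list[NeuronSpec]:
    """Neurons whose target NMIs under two drugs share correlation rho.

    Latent bivariate-normal NMI targets (clipped to (-0.95, 0.95)) are
    mapped to gains via f = (1 + nmi) / (1 - nmi), the inverse of the
    closed-form NMI of a rate-scaled process.
    """
    cov = nmi_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([nmi_mean, nmi_mean], cov, size=n)
    z = np.clip(z, -0.95, 0.95)
    specs = []
    for i in range(n):
        fa, fb = (1 + z[i]) / (1 - z[i])
        specs.append(NeuronSpec(neuron_id=f"n{i:04d}", drug_gain={drug_a: float(fa), drug_b: float(fb)}))
    return specs


def anesthesia_config(
    drug: str = "ISO",
    seed: int = 0,
    n_neurons: int = 50,
    baseline_s: float = 360.0,
    post_s: float = 1440.0,
    **overrides,
) -> SimulationConfig:
    """Standard anesthesia session: WAKE baseline, injection, plateau.

    The treatment event carries the 5-min active-EMG baseline window just
    before the injection and the full post span as the sliding-window
    search range. A SALINE "drug" produces no state change.
    """
    total = baseline_s + post_s
    event = TreatmentEvent(
        drug=drug,
        injection_time_s=baseline_s,
        baseline_window=(baseline_s - 300.0, baseline_s),
        post_window_candidate=(baseline_s, total),
    )
    if drug == "SALINE":
        plan = [("WAKE", total)]
    else:
        plan = [("WAKE", baseline_s), ("ANESTHESIA", post_s)]
    return SimulationConfig(
        seed=seed, n_neurons=n_neurons, plan=plan, event=event, **overrides
    )


def sleep_config(seed: int = 0, n_neurons: int = 50, total_s: float = 3600.0, **overrides) -> SimulationConfig:
    """Standard sleep-wake session driven by the stochastic cycle sampler."""
    return SimulationConfig(
        seed=seed, n_neurons=n_neurons, plan=SleepCyclePlan(total_s=total_s), **overrides
    )


def make_session(
    cfg: SimulationConfig, neurons: list[NeuronSpec] | None = None
) -> tuple[Session, GroundTruth]:
    """Generate a complete session (EEG/EMG, traces, photometry) + truth.

    Independent child generators are spawned per component so the session
    is byte-for-byte reproducible from ``cfg.seed`` alone.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_states, r_eeg, r_traces, r_phot, r_specs = [np.random.default_rng(c) for c in ss.spawn(5)]
    states = gen_state_sequence(cfg, r_states)
    if neurons is None:
        neurons = sample_neuron_specs(cfg.n_neurons, r_specs)
    rec = gen_eeg_emg(states, cfg, r_eeg)
    traces, truth = gen_traces(states, neurons, cfg, r_traces)
    phot = gen_photometry(traces, cfg, r_phot)
    session = Session(
        ephys=rec,
        photometry=phot,
        traces=traces,
        states=states,
        events=[cfg.event] if cfg.event is not None else [],
    )
    return session, truth
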