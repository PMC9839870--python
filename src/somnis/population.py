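"""Population state space (PCA) and Shannon-entropy bootstrap.

State space: each neuron's trace is z-scored over the concatenation of the
condition segments, averaged in 15-s (or 30-s) bins, and the bins x neurons
matrix is projected onto its top two principal components. One Gaussian is
fitted per condition (sample mean, covariance, and standard error of the
center = SD / sqrt(n_bins)), summarizing where that brain state lives in
the plane.

Entropy: within a 2-min window split into 5-s bins, a neuron's activity
distribution p_i = S_i / sum(S_i) (S_i the mean activity in bin i) has
Shannon entropy H = -sum p_i ln p_i; the population value is the mean over
neurons with nonzero activity. The bootstrap repeatedly samples one 2-min
window from a wakefulness pool and one from a condition pool and reports
the percent change in entropy with a 95% percentile confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import TraceMatrix

ENTROPY_BIN_S = 5.0
ENTROPY_WINDOW_S = 120.0
DEFAULT_N_RESAMPLES = 5000


@dataclass
class ConditionGaussian:
    condition: str
    center: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2)
    center_se: np.ndarray  # (2,) SD/sqrt(n_bins) per component
    n_bins: int

    @property
    def center_se_norm(self) -> float:
        return float(np.linalg.norm(self.center_se))


@dataclass
class StateSpaceResult:
    components: np.ndarray  # (2, n_neurons) loading basis
    points: pd.DataFrame  # columns: condition, pc1, pc2
    gaussians: dict[str, ConditionGaussian]
    explained_variance_ratio: np.ndarray
    bin_length_s: float
    excluded_neurons: tuple[str, ...] = ()

    def separation_matrix(self) -> pd.DataFrame:
        """Pairwise center distance divided by the larger center-SE norm."""
        conds = list(self.gaussians)
        out = pd.DataFrame(np.nan, index=conds, columns=conds)
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                ga, gb = self.gaussians[a], self.gaussians[b]
                d = float(np.linalg.norm(ga.center - gb.center))
                se = max(ga.center_se_norm, gb.center_se_norm)
                out.loc[a, b] = out.loc[b, a] = d / se if se > 0 else np.inf
        return out


@dataclass
class EntropyResult:
    condition: str
    delta_entropy_pct: float
    ci95: tuple[float, float]
    n_resamples: int
    resamples: np.ndarray = field(repr=False)
    bin_length_s: float = ENTROPY_BIN_S
    window_length_s: float = ENTROPY_WINDOW_S


def _bin_segment(values: np.ndarray, frames_per_bin: int) -> np.ndarray:
    """Average a (neurons, frames) block into whole bins along time."""
    n_bins = values.shape[1] // frames_per_bin
    return values[:, : n_bins * frames_per_bin].reshape(
        values.shape[0], n_bins, frames_per_bin
    ).mean(axis=2)


def build_state_space(
    traces: TraceMatrix,
    segments: dict[str, list[tuple[float, float]]],
    bin_length_s: float = 15.0,
) -> StateSpaceResult:
    """PCA state space of binned, z-scored population activity.

    ``segments`` maps each condition label to its time intervals. All
    neurons must be recorded throughout (the cross-condition intersection
    design); neurons constant over the concatenated segments are excluded
    with a warning since their z-score is undefined.
    """
    if bin_length_s <= 0:
        raise ValueError("bin_length_s must be > 0")
    fpb = int(round(bin_length_s * traces.frame_rate_hz))
    t = traces.frame_times()

    cond_blocks: list[tuple[str, np.ndarray]] = []
    for cond, ivals in segments.items():
        blocks = []
        for t0, t1 in ivals:
            m = (t >= t0) & (t < t1)
            if m.sum() >= fpb:
                blocks.append(traces.values[:, m])
        if not blocks:
            raise ValueError(f"condition {cond!r} has no interval covering one bin")
        cond_blocks.append((cond, np.concatenate(blocks, axis=1)))

    concat = np.concatenate([b for _, b in cond_blocks], axis=1)
    mu = concat.mean(axis=1, keepdims=True)
    sd = concat.std(axis=1, keepdims=True)
    keep = sd.ravel() > 0
    excluded = tuple(np.asarray(traces.neuron_ids)[~keep])
    if excluded:
        import warnings

        warnings.warn(
            f"excluded {len(excluded)} constant neuron(s) with undefined z-score",
            stacklevel=2,
        )
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant neurons")

    binned_rows = []
    cond_labels = []
    for cond, block in cond_blocks:
        z = (block[keep] - mu[keep]) / sd[keep]
        bins = _bin_segment(z, fpb)  # (neurons, n_bins)
        if bins.shape[1] < 2:
            raise ValueError(f"condition {cond!r} yields fewer than 2 bins")
        binned_rows.append(bins.T)  # (n_bins, neurons)
        cond_labels.extend([cond] * bins.shape[1])

    X = np.concatenate(binned_rows, axis=0)
    pca = PCA(n_components=2, svd_solver="full")
    proj = pca.fit_transform(X)

    points = pd.DataFrame({"condition": cond_labels, "pc1": proj[:, 0], "pc2": proj[:, 1]})
    gaussians = {}
    for cond in segments:
        pts = proj[np.asarray(cond_labels) == cond]
        gaussians[cond] = ConditionGaussian(
            condition=cond,
            center=pts.mean(axis=0),
            covariance=np.cov(pts.T),
            center_se=pts.std(axis=0, ddof=1) / np.sqrt(len(pts)),
            n_bins=len(pts),
        )
    return StateSpaceResult(
        components=pca.components_,
        points=points,
        gaussians=gaussians,
        explained_variance_ratio=pca.explained_variance_ratio_,
        bin_length_s=bin_length_s,
        excluded_neurons=excluded,
    )


def window_entropy(
    values: np.ndarray, frame_rate_hz: float, bin_length_s: float = ENTROPY_BIN_S
) -> float:
    """Mean Shannon entropy (natural log) of binned activity across neurons.

    ``values`` is a (neurons, frames) block covering one analysis window.
    Per neuron, S_i is the mean activity in 5-s bin i, p_i = S_i / sum S_i,
    H = -sum p_i ln p_i with 0 ln 0 = 0. Neurons with sum S_i = 0 are
    excluded. H lies in [0, ln n_bins].
    """
    values = np.asarray(values, dtype=np.float64)
    fpb = int(round(bin_length_s * frame_rate_hz))
    n_bins = values.shape[1] // fpb
    if n_bins < 2:
        raise ValueError("window must cover at least 2 bins")
    S = _bin_segment(values, fpb)  # (neurons, n_bins)
    totals = S.sum(axis=1)
    active = totals > 0
    if not np.any(active):
        raise ValueError("no neuron with nonzero activity in the window")
    p = S[active] / totals[active, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(np.mean(-terms.sum(axis=1)))


def population_entropy(
    traces: TraceMatrix, window: tuple[float, float], bin_length_s: float = ENTROPY_BIN_S
) -> float:
    """Entropy of a single time window of a TraceMatrix."""
    t = traces.frame_times()
    m = (t >= window[0]) & (t < window[1])
    return window_entropy(traces.values[:, m], traces.frame_rate_hz, bin_length_s)


def _window_starts(
    segments: list[tuple[float, float]],
    window_s: float,
    grid_s: float,
    t0: float,
) -> np.ndarray:
    """All window start times on the bin grid fully inside some segment."""
    starts = []
    for s0, s1 in segments:
        g0 = t0 + np.ceil((s0 - t0) / grid_s - 1e-9) * grid_s
        starts.extend(np.arange(g0, s1 - window_s + 1e-9, grid_s))
    return np.asarray(sorted(starts))


def _entropy_per_start(
    traces: TraceMatrix, starts: np.ndarray, window_s: float, bin_length_s: float
) -> np.ndarray:
    t = traces.frame_times()
    out = np.empty(len(starts))
    for i, w0 in enumerate(starts):
        m = (t >= w0) & (t < w0 + window_s)
        out[i] = window_entropy(traces.values[:, m], traces.frame_rate_hz, bin_length_s)
    return out


def entropy_bootstrap(
    traces: TraceMatrix,
    baseline_segments: list[tuple[float, float]],
    condition_segments: list[tuple[float, float]],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    condition: str = "CONDITION",
    window_length_s: float = ENTROPY_WINDOW_S,
    bin_length_s: float = ENTROPY_BIN_S,
) -> EntropyResult:
    """Bootstrap the percent entropy change of a condition vs wakefulness.

    Each resample draws one window start uniformly (with replacement, on
    the 5-s bin grid) from the baseline pool and one from the condition
    pool and computes 100 * (H_cond - H_base) / H_base. The point estimate
    is the resample mean; the CI the 2.5/97.5 percentiles. Deterministic
    for a fixed seed.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    t0 = traces.start_time_s
    base_starts = _window_starts(baseline_segments, window_length_s, bin_length_s, t0)
    cond_starts = _window_starts(condition_segments, window_length_s, bin_length_s, t0)
    if len(base_starts) == 0 or len(cond_starts) == 0:
        raise ValueError("each segment pool must admit at least one full window")
    h_base = _entropy_per_start(traces, base_starts, window_length_s, bin_length_s)
    h_cond = _entropy_per_start(traces, cond_starts, window_length_s, bin_length_s)
    rng = np.random.default_rng(seed)
    ib = rng.integers(0, len(h_base), size=n_resamples)
    ic = rng.integers(0, len(h_cond), size=n_resamples)
    deltas = 100.0 * (h_cond[ic] - h_base[ib]) / h_base[ib]
    if n_resamples == 1:
        ci = (float(deltas[0]), float(deltas[0]))
    else:
        ci = tuple(np.percentile(deltas, [2.5, 97.5]))
    return EntropyResult(
        condition=condition,
        delta_entropy_pct=float(deltas.mean()),
        ci95=(float(ci[0]), float(ci[1])),
        n_resamples=n_resamples,
        resamples=deltas,
        bin_length_s=bin_length_s,
        window_length_s=window_length_s,
    )


def exhaustive_delta_entropy_pct(
    traces: TraceMatrix,
    baseline_segments: list[tuple[float, float]],
    condition_segments: list[tuple[float, float]],
    window_length_s: float = ENTROPY_WINDOW_S,
    bin_length_s: float = ENTROPY_BIN_S,
) -> float:
    """Exact mean percent change over all (baseline, condition) window pairs.

    Because draws are independent and uniform, the pair mean factorizes to
    100 * (mean(H_cond) * mean(1 / H_base) - 1).
    """
    t0 = traces.start_time_s
    base_starts = _window_starts(baseline_segments, window_length_s, bin_length_s, t0)
    cond_starts = _window_starts(condition_segments, window_length_s, bin_length_s, t0)
    h_base = _entropy_per_start(traces, base_starts, window_length_s, bin_length_s)
    h_cond = _entropy_per_start(traces, cond_starts, window_length_s, bin_length_s)
    return float(100.0 * (h_cond.mean() * np.mean(1.0 / h_base) - 1.0))
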