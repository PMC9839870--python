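# Methods

## Time and epoch conventions

All times are seconds from session start; epoch indices are 0-based and
all intervals half-open `[t0, t1)`. EEG/EMG, photometry and calcium traces
keep their native sampling rates and are aligned only at the epoch level;
no cross-channel resampling is performed. Absent channels are explicit
"missing", never zero-filled — a silently zero EMG would mimic anesthesia.

## Spectral features

Per 5-s epoch the EEG periodogram is computed with a Hann taper,
zero-padded so the frequency grid spacing is at most 0.18 Hz, and
integrated over half-open bands δ = [0.5, 4) Hz and θ = [6, 10) Hz (the
half-open convention prevents double counting a shared grid point; the
Hann taper controls leakage between the adjacent bands). Power is
absolute (signal-units²). EMG is summarized by the epoch RMS. Epochs with
zero θ power get an undefined (NaN) δ/θ ratio and are excluded from
clustering and scoring rather than imputed; they arise only in degenerate
synthetic inputs.

## Sleep scoring

A transparent decision rule with total precedence WAKE > REM > NREM:
WAKE when EMG RMS exceeds the threshold; otherwise REM when θ/δ exceeds
1.5 (default, dimensionless); otherwise NREM. The EMG threshold is
calibrated per session as the midpoint of a 2-means split of the log-RMS
distribution; if the split's center separation is below 3 mean
within-cluster SDs the distribution is treated as unimodal (e.g. an
all-wake session) and a configured absolute threshold is used with a
warning. A 3-epoch majority vote (configurable off) smooths single-epoch
flickers the way a human scorer enforces bout consistency. The scorer is
validated only against the synthetic generator's ground truth (≥ 90%
epoch accuracy at defaults); no claim is made about agreement with any
particular human scorer.

## Photometry

The raw signal is autofluorescence-subtracted and averaged into contiguous
1-s bins. The baseline `F0(t)` is either a double exponential
`a·exp(−t/τ1) + b·exp(−t/τ2) + c` least-squares fitted on the baseline
window (all of `a, b, c ≥ 0` and `τ1, τ2 > 0`, so the extrapolated
baseline stays positive; non-convergence falls back to the moving average
with a warning) or a centered 100-s moving average of the full series
(odd window length, truncated at the edges). The double exponential is the
default for anesthesia sessions, where monotone bleaching dominates and
the baseline must be extrapolated past the injection; the moving average
suits undrugged sleep sessions. ΔF/F₀ = (F − F0)/F0; the z-score is
centered and scaled by the ΔF/F₀ mean and SD over the baseline window
(baseline-window centering, not session-wide — the alternative was open
and this choice keeps the baseline z-score exactly standardized); the
post-treatment effect is the SD of the z-score over the post window,
identical to SD_post/SD_base of ΔF/F₀. The post window is the DBI-selected
depth window; the baseline is the 5 min before injection.

## Anesthesia depth

Features are (EMG RMS, δ/θ) per 5-s epoch. For each candidate 10-min
window starting at the injection and shifted by 1 min, baseline + window
epochs are pooled, each feature standardized to zero mean/unit SD over the
pooled set (the two features live on incommensurate scales; without
standardization one axis dominates the Euclidean metric), split by
2-means (10 restarts, fixed seed, best inertia — deterministic), and
scored by the 2-cluster Davies–Bouldin index computed on the k-means
labels. Ambiguity resolved as package policy: DBI is computed on k-means
labels, not on time-defined labels, with a warning whenever the clusters
do not align with the baseline/window periods (≥ 90% of baseline epochs
in one cluster); equal-DBI ties go to the earliest window (the earliest
adequate depth is the conservative choice). Coincident centroids make the
index undefined and raise.

EMG-based timing uses RMS in 20-s windows hopped every 10 s. The threshold
is mean + 3·SD of the RMS over a reference interval recorded under
anesthesia (the 20 min before anesthetic stop); "fully anesthetized"
begins at the first run of 15 consecutive sub-threshold windows after the
anesthetic starts, "fully awake" at the first run of 9 consecutive
supra-threshold windows after it stops (the 9-window rule is interpreted
as consecutive, symmetric with the 15-window rule). Undetected events are
reported as undefined, never fabricated. Because the threshold sits 3 SDs
above the anesthetized RMS level, a stationary signal is generically
sub-threshold; the impossible event for a stationary signal is the upward
crossing.

## Modulation index

For one neuron, `A_base` and `A_post` are trapezoidal AUCs divided by
window duration — i.e. mean signal rates — over the 5-min pre-injection
baseline and the DBI-selected 10-min window, and
`NMI = (A_post − A_base)/(A_post + A_base) ∈ [−1, 1]`. Duration
normalization is the default because the two windows differ in length and
NMI = 0 must mean unchanged activity; a raw-AUC mode is available for
sensitivity analysis. A neuron silent in both windows gets NMI = 0 with a
degenerate flag and is excluded from correlation and clustering. Classes
are INHIBITED (NMI < −0.33), EXCITED (NMI > 0.33), INSENSITIVE otherwise;
the boundaries ±0.33 fall in INSENSITIVE (strict inequalities). The
sleep–wake NMI uses pooled WAKE vs pooled NREM mean activity (REM
excluded) and requires ≥ 5 min of each state. Response patterns across
anesthetics are clustered agglomeratively (Euclidean on NMI vectors,
average linkage, tree cut at k = 3); identical rows merge at distance 0
and the cut may yield fewer effective clusters. Cross-condition overlap
percentages are directional and reported both ways plus their mean, since
either denominator (inhibited-by-A or inhibited-by-B) is defensible.

## Population state space

Each neuron's trace is z-scored over the concatenation of the condition
segments (concatenated, not per-condition, so conditions stay comparable
in one coordinate system), averaged within 15-s bins (30-s to check
robustness), and the bins × neurons matrix is projected onto its top two
principal components (full SVD — deterministic up to component sign). One
Gaussian per condition: sample mean, sample covariance, SE of the center
= SD/√n_bins per component. Separation between conditions is summarized
as center distance over the larger center-SE norm. Constant neurons have
no z-score and are excluded with a warning.

## Entropy

Within a 2-min window split into 24 five-second bins, a neuron's binned
mean activities `S_i` define `p_i = S_i/ΣS_i` and
`H = −Σ p_i ln p_i` (natural log; 0·ln 0 ≡ 0), so `0 ≤ H ≤ ln 24`.
Neurons with `ΣS_i = 0` in a window are excluded from that window's mean
rather than counted as H = 0 — a silent neuron carries no distributional
information, and zeroing it would conflate silence with determinism. The
population value is the mean over contributing neurons. The entropy change
is reported as percent of the wakefulness value,
`Δ% = 100·(H_cond − H_base)/H_base`, which is invariant to the logarithm
base. The bootstrap draws one window start per pool uniformly with
replacement on the 5-s grid (pools are 10–20 min, so 5000 draws force
overlap), repeats `n_resamples` times (default 5000; the bundled demo and
coverage checks use 500), and reports the resample mean with the
2.5/97.5-percentile CI; a fixed seed reproduces the result exactly. For
anesthesia the condition pool is the DBI-selected window; for NREM, all
NREM bouts of at least 120 s.

## Synthetic generator

The generator emulates the statistical structure the analyses consume,
not the biophysics:

* **States**: either an explicit bout plan or a stochastic
  WAKE → NREM → (REM with p = 0.5) → WAKE cycle with exponential bout
  durations (means 200/120/60 s, floored at 20 s) — typical mouse bout
  statistics.
* **EEG/EMG** (250 Hz default; band features only need resolution to
  10 Hz): per epoch, sums of band-limited Gaussian noise with
  state-dependent power tables (NREM/anesthesia δ-rich, REM θ-rich) and
  white-noise EMG with state-dependent amplitude (WAKE 1.0, NREM 0.2,
  REM 0.1, ANESTHESIA 0.05 signal units).
* **Traces** (5 Hz): per neuron, Poisson events at
  `base_rate · state_gain(state) · drug_factor(t)` convolved with a
  peak-normalized exponential rise/decay kernel (0.2 s / 1.5 s,
  GCaMP6s-like), plus truncated-at-zero Gaussian noise. Poisson events
  rather than a spiking model: downstream statistics consume only AUC and
  variance, and Poisson rates give the closed-form expectation
  NMI = (f − 1)/(f + 1) for a rate factor f, used as the recovery oracle.
  The default WAKE rate 0.3 Hz and noise SD 0.01 keep the rectified-noise
  floor (≈ 0.004 in AUC-rate units) two orders below the baseline signal
  rate (≈ 0.42), so the total-suppression limit lands near −0.98 rather
  than −1 exactly.
* **Onset ramp**: anesthesia does not switch on instantly; a 60-s sigmoid
  after the injection blends EEG power, EMG amplitude and drug gain from
  awake to anesthetized values. The ground-truth anesthesia interval is
  the post-ramp plateau, which is what the depth search should find.
* **Photometry** (100 Hz default): population mean trace resampled, plus
  a double-exponential bleach (amplitudes 0.5/0.2, taus 900/120 s),
  constant autofluorescence 0.1 and white noise.

One seed fixes a session byte-for-byte (independent child generators are
spawned per component). Every generator parameter is recoverable by the
corresponding analysis stage; that closure is the backbone of the test
suite.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: EEG microarchitecture (spindles, K-complexes,
burst suppression), movement artifacts, hemodynamic or motion
contamination of photometry, correlated population dynamics beyond shared
state gains, non-Poisson firing statistics, and imperfect cross-session
neuron registration (synthetic IDs are exact). In the default mixed
population the excited minority compensates the inhibited majority's AUC
at the population-photometry level, and NREM activity concentration can
lower rather than raise mean entropy; real recordings need not behave
this way.

## Problem sizes

The bundled demo and the recovery benchmarks use desk-scale sessions
chosen as the smallest sizes at which every effect is comfortably
resolved: 30-min anesthesia sessions (5-min active-EMG baseline + 6-min
wake + 24-min post), 40-min sleep sessions, 20–100 neurons, 20–40 seeds
per sweep, and 500 bootstrap resamples where the full analysis would use
5000.

## Known limitations

* The depth search assumes the baseline truly has active EMG; it warns
  but does not refuse when clusters and time periods disagree.
* The exp2 baseline extrapolates; for sessions much longer than the
  baseline window the moving-average mode is more robust but tracks (and
  partially absorbs) slow signal changes.
* Percent entropy change uses the percent-change reading of
  `H_cond − H_base`; an absolute-difference reading would not be
  base-invariant.
* The scorer has no artifact rejection beyond the undefined-ratio rule
  and no transition microstates.
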