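# somnis

Quantitative comparison of neural population activity across natural sleep
and drug-induced anesthesia, built for systems neuroscientists who record
EEG/EMG together with calcium signals (fiber photometry and single-cell
imaging) while inducing anesthesia with agents such as propofol (PPF),
isoflurane (ISO), ketamine (KET) or dexmedetomidine (DEX).

The package implements, as a tested reusable pipeline:

* **Sleep scoring** — per-5-s-epoch EEG δ (0.5–4 Hz) and θ (6–10 Hz) band
  power (periodogram on a ≤ 0.18 Hz grid) and EMG RMS, scored
  WAKE/NREM/REM by the standard rodent criteria with a session-calibrated
  EMG threshold.
* **Anesthesia depth** — epochs live in the (EMG RMS, δ/θ) plane; a 5-min
  active-EMG baseline is pooled with each candidate 10-min post-injection
  window (shifted every 1 min), split by 2-means, and scored by the
  Davies–Bouldin index

  $$\mathrm{DBI} = \frac{1}{N}\sum_{i=1}^{N}\max_{j\ne i}\frac{d'(i)+d'(j)}{d(i,j)},$$

  with $d'(i)$ the mean distance of cluster $i$'s points to their centroid
  and $d(i,j)$ the centroid distance. The minimal-DBI window is the period
  of adequate anesthesia depth; a saline control stays near DBI ≈ 1 while
  anesthetics reach ≈ 0.1–0.3.
* **Photometry** — autofluorescence subtraction, 1-Hz binning, baseline
  $F_0(t)$ by a second-order exponential fit or a 100-s moving average,
  ΔF/F₀, baseline-referenced z-scores and the post-window SD fold change.
* **Modulation** — per neuron the normalized modulation index
  $\mathrm{NMI} = (A_\text{post} - A_\text{base})/(A_\text{post} + A_\text{base})$
  of duration-normalized trace AUC; classes INHIBITED (NMI < −0.33),
  EXCITED (NMI > 0.33), INSENSITIVE; the same index between pooled WAKE and
  NREM activity defines wake-/sleep-active neurons; response patterns are
  grouped by average-linkage hierarchical clustering and compared across
  conditions by joint-classification counts and Pearson correlation.
* **Population state space** — 15-s (or 30-s) bins of z-scored activity
  projected on the top two principal components, one Gaussian per
  condition.
* **Entropy** — per neuron, Shannon entropy $H = -\sum_i p_i \ln p_i$ of
  the activity distribution $p_i = S_i/\sum_i S_i$ over 5-s bins in a
  2-min window; a bootstrap over randomly drawn windows gives the percent
  entropy change of anesthesia/NREM versus wakefulness with a 95% CI.
* **Synthetic sessions** — a generator with ground truth (state-dependent
  EEG/EMG, per-neuron state tuning and anesthetic gains driving Poisson
  events under a GCaMP6s-like kernel, photometric bleaching) so every
  stage is validated by parameter recovery.

## Worked example

```python
from somnis import synth, spectral, depth, modulation

cfg = synth.anesthesia_config("ISO", seed=1, n_neurons=50)
session, truth = synth.make_session(cfg)

feats = spectral.epoch_features(session.ephys)
res = depth.depth_search(feats, session.events[0])
print(f"selected window: {res.selected_window[0]:.0f}-{res.selected_window[1]:.0f} s, DBI = {res.dbi:.3f}")

table = modulation.nmi_table(session.traces, "ISO",
                             session.events[0].baseline_window, res.selected_window)
print(table["response_class"].value_counts().to_dict())
print(f"median NMI = {table['nmi'].median():+.3f}")
```

prints

```
selected window: 420-1020 s, DBI = 0.230
{'INHIBITED': 35, 'INSENSITIVE': 8, 'EXCITED': 7}
median NMI = -0.503
```

The injection is at 360 s; the search correctly lands the 10-min window
inside the anesthesia plateau (which starts at 420 s after the 60-s onset
ramp), with a DBI far below the saline-control value (≈ 1.1). The NMI
table recovers the generator's response mix: most neurons inhibited, a
minority excited, median NMI near −0.5.

The same stages run end to end from one config:

```bash
somnis pipeline demo-config --seed 1 --out demo.yaml
somnis pipeline run --config demo.yaml --out demo_out
```

which writes per-stage CSV/JSON reports (hypnogram, depth windows, ΔF/F₀
traces, NMI table, state-space projections, entropy CIs) and a run log
with every parameter; reruns with the same seed are byte-identical.

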