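# mstates

EEG microstate analysis for clinical resting-state studies, with a synthetic
ground-truth cohort generator, implemented as a Python library plus a thin
command-line pipeline.

Resting-state EEG does not wander continuously: the scalp voltage topography
stays quasi-stable for tens of milliseconds at a time, then reorganizes
abruptly. These quasi-stable periods — *microstates*, conventionally four
classes labeled A–D — are summarized per subject by their mean **duration**
(s), **occurrence** (s⁻¹), **coverage** (time fraction) and **transition
probabilities**, and these parameters are studied as candidate
electrophysiological markers of Alzheimer's disease, alongside
neuropsychological scores and CSF biomarkers (Aβ₁₋₄₂, Aβ₁₋₄₀, p-tau, t-tau,
NfL).

`mstates` covers the complete workflow:

* **preproc** — zero-phase band-pass (0.1–40 Hz) and notch (48–52 Hz)
  filtering, downsampling to 500 Hz, non-overlapping 2-s epochs, rule-based
  bad-channel detection with neighbor interpolation, ±100 µV epoch
  rejection, whole-brain average reference;
* **clustering** — topographies at peaks of the Global Field Power
  `GFP(t) = √(Σ_c (v_c(t) − v̄(t))² / C)` extracted from 2–20 Hz data, then
  polarity-invariant atomize-and-agglomerate hierarchical clustering (AAHC);
  model order chosen from the Global Explained Variance
  `GEV = Σ_t (GFP_t · Corr(v_t, T_{L(t)}))² / Σ_t GFP_t²`
  via an incremental-gain stopping rule (with a `force_k` override);
* **segmentation** — backfitting every sample to the best-correlated
  template (polarity-invariant), run-length segmentation, the four
  parameter families, with `coverage = duration × occurrence` holding as an
  exact identity;
* **stats** — χ² for contingency tables, Shapiro-gated t / Mann–Whitney-U
  group comparisons with Benjamini–Hochberg FDR within variable families,
  partial rank correlation adjusted for sex/age/education, stepwise linear
  regression;
* **classify** — CART decision tree on the 28-column microstate feature
  vector, stratified 8:2 split, five-fold cross-validation, ROC/AUC;
* **synth** — a semi-Markov generator (gamma dwell times, transitions at
  oscillation troughs) producing EEG with known templates, dynamics, group
  effects and *planted* covariate correlations, so every stage is testable
  against ground truth.

## Worked example

`examples/01_simulate_and_segment.py` simulates one 60-channel, 60-s
recording with four known templates at SNR 5 and runs the analytic core:

```
kept 30/30 epochs (60 s), bad channels: none
1200 GFP-peak maps; GEV by k: 2: 0.819, 3: 0.906, 4: 0.961, 5: 0.965, ...
selected k = 4  (smallest k whose GEV gain to k+1 drops below 0.01)
recovered-vs-true template |correlation|: 0.997, 0.998, 0.999, 0.999

per-class microstate parameters (recovered):
class  duration(ms)  occurrence(/s)  coverage
  A        64.5          3.73     0.241
  B        64.1          3.70     0.237
  C        69.7          3.83     0.267
  D        64.3          3.97     0.255
mean duration 65.6 ms, mean occurrence 15.23 /s, GEV 0.961

ground truth: mean dwell 66.2 ms (coverage is uniform by construction)
```

The GEV gain collapses after k = 4 (the number of generating templates), the
recovered maps correlate ≥ 0.997 with the truth, and durations around 65 ms
with occurrences near 4 s⁻¹ recover the configured 66 ms dwell — the scale
reported for real elderly cohorts. The other examples cover the statistics
battery (`02`, including recovery of a planted partial correlation of
−0.40 between class-C duration and CSF Aβ₁₋₄₂), classification (`03`) and
the one-call pipeline (`04`). The same pipeline runs from the shell:

```bash
mstates all --config config.yaml --seed 1 --out results/
```

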