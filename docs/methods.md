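# Methods

This note documents the models, estimators and numerical choices behind
`mstates`, what the synthetic generator does and does not emulate, and the
known limitations. Units are microvolts, seconds and Hz throughout; sample
indices are 0-based and run intervals half-open.

## The microstate model

The scalp potential `v(t) ∈ ℝ^C` (average-referenced, so `Σ_c v_c(t) = 0`)
is modeled as a sequence of quasi-stable topographies: at each moment one of
k unit-norm template maps `T_1 … T_k` is active up to scale and sign,

    v(t) ≈ a(t) · s(t) · T_{L(t)} + noise,      s(t) ∈ {−1, +1},

where `L(t)` is the label process and the sign flips reflect oscillatory
field reversals. All comparisons between topographies are therefore
*polarity-invariant*: the spatial Pearson correlation enters as an absolute
value, everywhere (clustering, template alignment, backfitting).

Because maps are average-referenced, the Pearson spatial correlation equals
the cosine between maps, and with unit-norm templates

    GFP(t) · Corr(v(t), T) = (v(t) · T) / √C,

so the GEV of a labeling reduces to `Σ_t (v_t · T_{L(t)})² / (C · Σ_t GFP_t²)`.

## Preprocessing

Fixed order: band-pass + notch → resample → epoch → channel repair → epoch
rejection → average reference. Filters are 4th-order Butterworth applied
forward-backward (zero phase, so state boundaries are not shifted), with
the signal padded by roughly three periods of the filter's slowest edge —
scipy's default pad of a few dozen samples is far too short for a 0.1 Hz
high-pass and leaves visible transients. Resampling is polyphase with
anti-aliasing; upsampling is rejected as never needed.

Bad channels are flagged by three rules, each a deliberately simple,
testable surrogate for what is usually visual judgement (and labeled as
such in reports): (a) |v| > 100 µV in more than 20 % of epochs; (b)
peak-to-peak below 0.1 µV in more than 20 % of epochs; (c) the channel's
median per-epoch residual from the mean of its 4 nearest neighbors,
normalized by the RMS of that neighborhood, is both a robust-z outlier
across channels (z > 4) and exceeds 1.5. The normalization in (c) matters:
raw RMS deviation or decorrelation measures flag perfectly healthy rim and
low-signal channels, because smooth topographic gradients make electrodes
genuinely differ from their neighbors. Flagged channels are replaced by the
inverse-distance-weighted mean of their 4 nearest good neighbors; more than
25 % flagged channels aborts the run. Epochs containing any sample beyond
±100 µV after repair are dropped.

The microstate band (2–20 Hz) is a separately filtered copy of the clean
epochs; the broadband copy is retained for reporting. An optional hook
accepts an externally computed linear decomposition (unmixing matrix +
component exclusion list) and projects those components out; the package
never computes such a decomposition itself.

## Clustering and model-order selection

Topographies are sampled at strict local maxima of the GFP within each
epoch (edges excluded; peaks closer than `min_separation` keep the larger).
AAHC starts from singleton clusters and repeatedly dissolves the cluster
with the smallest explained-variance contribution
`Σ_{t∈cluster} (GFP_t |Corr(v_t, T_cluster)|)²`, reassigning each freed map
to the surviving cluster with the highest polarity-invariant correlation.
Cluster centroids are the first principal axis of the member maps (raw, so
each map is implicitly GFP-weighted), re-centered and normalized — a mean
of sign-ambiguous maps can cancel, a principal axis cannot. Ties are
deterministic: equal contribution dissolves the smaller cluster, then the
lower index; equal correlation assigns to the lower index.

Two refinements stabilize the greedy descent once it reaches the recorded
range (count ≤ k_max), both deterministic:

* a polarity-invariant k-means polish (reassign all maps, recompute
  principal-axis centroids, iterate to a fixed point; a cluster emptied by
  reassignment is re-seeded with the worst-explained map);
* an ISODATA-style escape move — split the cluster with the most
  unexplained variance along the principal axis of its residuals, merge the
  closest centroid pair, keep the result only if GEV strictly increases.

Without these, the literal greedy descent occasionally records a provably
suboptimal partition (atomizing a coherent but low-total-contribution
cluster orphans its members irrecoverably), which corrupts model-order
selection; with them, AAHC matches exhaustive partition search on small
oracle problems and the truth-seeded optimum on simulated recordings.

Model order: the smallest k whose GEV gain to k+1 falls below
`gev_gain_threshold` (default 0.01, search range 2–8); if the gain never
drops below threshold, k_max; `force_k` pins the choice (clinical studies
conventionally fix k = 4). Group templates average the per-subject sets
after optimal bipartite matching (maximizing total polarity-invariant
correlation, signs aligned), and for k = 4 are reordered against built-in
idealized A–D gradients so class labels are reproducible.

## Backfitting and dynamics metrics

Every sample of the 2–20 Hz epochs is labeled with the template of maximal
|spatial correlation| (ties → lowest class index). Samples with GFP below
1e-4 of the epoch's median GFP are treated as zero-variance (measurement
floor) and inherit the previous label, the first samples of an epoch taking
the next valid label. `min_segment_ms` (default 0 — no temporal smoothing)
optionally reassigns runs shorter than the given duration to the
better-correlated neighbor label.

Runs never span epoch boundaries; epoch-edge runs are flagged truncated but
*included* in duration averages, which keeps
`coverage_c = duration_c × occurrence_c` exact. Definitions:
`duration_c` = mean run length of class c; `occurrence_c` = class-c runs per
second; `coverage_c` = fraction of samples; `mean_duration` = total labeled
time / total runs; `mean_occurrence` = total runs / time = Σ_c occurrence_c;
transition probabilities count consecutive within-epoch run pairs and are
jointly normalized over all k(k−1) ordered pairs, so the off-diagonal
entries sum to 1. A class with zero runs reports missing (NaN), not zero.
Published cohort tables print a "mean duration" exceeding every per-class
duration, which no weighted mean of class durations can produce; this
package keeps the total-time/total-runs definition and does not attempt to
reverse-engineer that value.

## Statistics

Two-sided tests, α = 0.05 everywhere. Group comparison: Shapiro–Wilk in
both groups at α = 0.05 decides between the equal-variance t-test and the
Mann–Whitney U, the latter reported as a tie-corrected normal-approximation
z. Benjamini–Hochberg FDR is applied *within* variable families (global
rows, durations, occurrences, coverages, transitions) — the family
partition is not dictated by the underlying test battery and changes
adjusted p, so it is configurable and recorded in the provenance. (BH
adjusted p-values are order-invariant and rank-preserving but not
idempotent; re-adjusting adjusted values inflates them.)

Partial rank correlation: x and y rank-transformed (average ranks),
residualized on [1, covariates] by least squares, Pearson correlation of
residuals, p from t on n − q − 2 df. With no covariates this is exactly
Spearman's ρ. Covariates enter unranked; the common statistical-package
variant ranks them too, and the test suite reconciles the two by feeding
the reference implementation pre-ranked covariates.

Stepwise regression: forward entry (smallest coefficient p < 0.05) then
backward removal (largest p > 0.10), iterated to a fixed point; candidates
nearly collinear with the included set (residual R² < 1e-8) never enter;
an empty model is a valid outcome. Standardized and unstandardized
coefficients are both reported with 95 % CIs, plus the full selection trace.

## Classification

CART (Gini, library defaults, fixed seed, no hyperparameter tuning) on the
28-column feature vector: 4 durations + 4 occurrences + 4 coverages + 12
transition probabilities + mean duration + mean occurrence + GEV + total
time. The 8:2 split is stratified — with ~38 controls an unstratified 20 %
draw can produce unusable partitions — and 8:2 of 94 subjects yields 19
test subjects (a published report with test support 29 is inconsistent
with its own stated ratio; the ratio wins here). Five-fold stratified CV
estimates generalization on the training set; the evaluated model is refit
on all training data. ROC scores are leaf class fractions; AUC is
trapezoidal.

## The synthetic generator

What it emulates: eyes-closed resting EEG dominated by k = 4 recurring
topographies. Smooth dipolar/quadrupolar template maps (random combinations
of degree-1/2 spherical harmonics on a spiral electrode cap, pairwise
|corr| < 0.8); a semi-Markov label process with gamma dwell times (defaults:
mean 66 ms per class, CV 0.3, uniform transitions — matching the 60–75 ms
dwell and 3.5–4.5 s⁻¹ occurrence scale of elderly cohorts); a signed 10 Hz
carrier `sin(2πft)` under whose rectified-sine amplitude envelope the GFP
peaks ~20 times per second; spatially smooth sensor noise (Gaussian,
kernel width ≈ inter-electrode spacing, which makes bad-channel detection
nontrivial) scaled to RMS(signal)/RMS(noise) = SNR (default 5).

Two generator choices deserve emphasis, both grounded in the microstate
model itself:

* **Signed carrier.** A rectified carrier `|sin|` concentrates its energy
  at DC and 2f; the 2–20 Hz microstate band removes the DC part and leaves
  a signal that nulls every 1/(4f) s, which band-limited filtering converts
  into artificial inter-state mixtures — template recovery then saturates
  near |corr| 0.94 and backfit durations near 18 ms *independent of SNR*.
  The signed carrier has identical amplitude envelope and GFP peak spacing,
  stays inside the band, and its polarity reversals are exactly what
  polarity-invariant analysis is built for.
* **Trough-synchronized transitions** (`transition_sync_s`, default 50 ms =
  the carrier's trough spacing; dwells round to the nearest positive
  multiple, the switch taking effect on the sample after the trough). In
  the microstate picture topographies are stable around GFP peaks and
  reorganize near field minima; switching at arbitrary phase instead
  produces filter-smeared two-state mixture maps at GFP peaks that a
  genuine 4-state process does not contain, inflating GEV gains beyond k=4.
  Set `transition_sync_s=None` for a plain semi-Markov process.

The dwell CV default of 0.3 keeps dwells well above the 2–20 Hz filter's
impulse-response width; much shorter runs would be pure filter smear rather
than quasi-stable periods. Under these defaults the model-order rule
selects k = 4 on ≥ 90 % of seeds and recovered group templates correlate
≥ 0.95 with the truth at SNR ≥ 5.

Cohorts: the patient group's dynamics receive an additive class-C dwell
shift (default +6 ms); covariates (demographics, cognitive scores, CSF
panels — the latter patient-group only) are drawn around literature-scale
means. Planted correlations use the exact mixture
`cov = μ + σ(ρ·z_metric + √(1−ρ²)·ε)` with ε orthogonalized against the
metric, so the sample Pearson correlation equals ρ exactly rather than only
in expectation. All generators are pure functions of (spec, seed) via numpy
SeedSequence spawning.

What it does *not* emulate, hence what passing tests do not show about real
data: ocular/muscle/cardiac artifacts (no decomposition-based cleaning is
exercised), 1/f background spectra and alpha waxing-waning, volume-conducted
source mixing, non-stationary dwell statistics, electrode drift or true
line-noise shapes. Published group-level effect sizes on real cohorts are
not reproducible from synthetic data; the pipeline's statistical battery is
validated by construction (planted effects, null calibration), not by
matching a real cohort's tables.

## Numerical choices and degenerate inputs

* Backfit duration bias: band-limited filtering smears sharp state
  switches over ~1/bandwidth, so unsmoothed backfit labels chatter near run
  boundaries and mean durations read low (~28 ms for a 66 ms truth at any
  SNR under default conditions). The dwell-recovery validation therefore
  runs with `min_segment_ms=20`; the pipeline default stays 0, matching the
  convention of reporting unsmoothed segmentations.
* Zero-variance maps: correlation with a zero map is undefined and raises;
  samples below the per-epoch GFP floor inherit labels as described above.
* All peak maps collinear → clustering degenerates to a single class,
  returned with a warning rather than an error.
* Zero transitions → transition matrix reported missing (NaN), not zero;
  a class with zero runs likewise.
* GEV is non-decreasing in k on the same peak set (enforced to 1e-6 in
  tests); sign-flipping any subset of input maps changes nothing anywhere.
* Stage seeds derive from the global seed as `SeedSequence([seed, stage
  index])`, so each stage is independently reproducible.

## Known limitations

EDF files can be read (via mne) but not written — no EDF writer is
available in the supported dependency set — so recordings export to the
package's text dump and to FIF. The AAHC implementation targets cohort-size
peak sets (~10³–10⁴ maps per subject); it is quadratic-ish in peaks and not
meant for continuous high-density overnight data. Only two-group designs
are supported in the comparison battery, and the regression/classification
layers assume complete cases.
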