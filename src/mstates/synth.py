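"""Synthetic EEG cohorts with known microstate ground truth.

The generator emulates eyes-closed resting-state EEG dominated by a small
number of recurring quasi-stable topographies: a semi-Markov state sequence
(gamma-distributed dwell times, so mean dwell and dispersion decouple)
selects which template topography is active; the scalp signal is that
template under a rectified alpha-band amplitude envelope plus spatially
smooth sensor noise.  Cohort covariates (demographics, cognitive scores,
CSF biomarkers) are drawn around literature-scale means, and selected
microstate metrics can carry *planted* correlations with covariates via an
exact linear mixture, so the target correlation is analytic rather than
tuned.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import TemplateSet, default_labels
from .errors import InvalidArgumentError
from .layout import SensorLayout, make_layout
from .preproc import Recording
from .segmentation import LabelSequence, MicrostateMetrics, compute_metrics, segment_runs

#: Default sampling rate of synthetic recordings, Hz.
DEFAULT_SFREQ = 500.0
#: Default GFP of the noise-free signal at envelope maxima, uV.
DEFAULT_PEAK_GFP = 10.0


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicsSpec:
    """Semi-Markov microstate dynamics.

    ``mean_dwell`` is the mean dwell time per class in seconds (scalar or
    per-class); ``dwell_dispersion`` is the coefficient of variation of the
    gamma dwell distribution; ``transition_weights`` is a k x k nonnegative
    matrix with zero diagonal whose rows, normalized, give the next-class
    distribution.  Defaults give four classes with ~66 ms dwells and uniform
    transitions, matching the dwell (60-75 ms) and occurrence (3.5-4.5 /s)
    ranges typical of resting-state cohorts.  The default dispersion (CV
    0.3) keeps dwells tightly grouped around their mean: runs much shorter
    than the 2-20 Hz filter's impulse response would be pure filter-smeared
    mixtures of adjacent states rather than genuine quasi-stable periods,
    which is not what the generator is meant to emulate.

    ``transition_sync_s`` quantizes state switches to multiples of the given
    interval — by default the trough spacing of the 10 Hz amplitude envelope
    (50 ms).  In the microstate picture the scalp field topography is stable
    around GFP peaks and reorganizes near field minima, so transitions land
    at amplitude troughs rather than at arbitrary oscillation phase; set it
    to ``None`` for a plain (unsynchronized) semi-Markov process.
    """

    k: int = 4
    mean_dwell: float | tuple[float, ...] = 0.066
    dwell_dispersion: float = 0.3
    transition_weights: np.ndarray | None = None
    transition_sync_s: float | None = 0.05

    def dwell_means(self) -> np.ndarray:
        m = np.broadcast_to(np.asarray(self.mean_dwell, dtype=float), (self.k,)).copy()
        if np.any(m <= 0):
            raise InvalidArgumentError("mean_dwell must be positive")
        return m

    def weights(self) -> np.ndarray:
        if self.transition_weights is None:
            w = np.ones((self.k, self.k))
        else:
            w = np.asarray(self.transition_weights, dtype=float).copy()
        if w.shape != (self.k, self.k):
            raise InvalidArgumentError("transition_weights must be k x k")
        if np.any(w < 0):
            raise InvalidArgumentError("transition_weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        rowsum = w.sum(axis=1, keepdims=True)
        if np.any(rowsum == 0):
            raise InvalidArgumentError("every class needs a positive outgoing weight")
        return w / rowsum

    def with_dwell_shift(self, shifts: dict[int, float]) -> "DynamicsSpec":
        """A copy with additive per-class dwell shifts (seconds)."""
        m = self.dwell_means()
        for cls, s in shifts.items():
            m[cls] += s
        return DynamicsSpec(
            k=self.k,
            mean_dwell=tuple(m),
            dwell_dispersion=self.dwell_dispersion,
            transition_weights=self.transition_weights,
        )


#: Covariate definitions: column -> (AD mean, AD sd, HC mean, HC sd).
#: NaN for a group means the covariate is not collected there (CSF panels
#: are acquired in the patient group only).
COVARIATE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "age": (62.22, 8.41, 60.28, 7.10),
    "education": (8.23, 4.36, 12.41, 2.65),
    "mmse": (18.72, 6.36, 28.46, 1.40),
    "moca": (13.39, 6.44, 26.39, 1.83),
    "adl": (28.31, 7.32, 20.18, 0.77),
    "scwt_d": (40.0, 12.0, 30.0, 8.0),
    "scwt_w": (55.0, 15.0, 40.0, 10.0),
    "scwt_cw": (95.0, 25.0, 70.0, 18.0),
    "vft_s": (8.5, 3.0, 14.0, 3.5),
    "abeta42": (729.61, 395.49, np.nan, np.nan),
    "abeta40": (8885.68, 3651.20, np.nan, np.nan),
    "abeta_ratio": (0.09, 0.04, np.nan, np.nan),
    "ptau181": (111.94, 51.63, np.nan, np.nan),
    "ttau": (546.01, 262.74, np.nan, np.nan),
    "nfl": (1408.62, 1097.07, np.nan, np.nan),
}

#: Probability of male sex per group (patients 25/56, controls 14/38).
_P_MALE = {"AD": 25 / 56, "HC": 14 / 38}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with planted group effects and correlations.

    ``n_per_group`` is (n_AD, n_HC).  ``group_effects`` maps a class label
    (e.g. ``"C"``) to an additive mean-dwell shift in seconds applied to the
    patient group.  ``planted_correlations`` lists (metric column, covariate
    column, target rho) triples realized within the patient group by the
    exact mixture  cov = mu + sigma * (rho * z_metric + sqrt(1-rho^2) * eps).
    ``noise_sd`` optionally overrides a covariate's sd.
    """

    n_per_group: tuple[int, int] = (56, 38)
    group_effects: dict[str, float] = field(
        default_factory=lambda: {"C": 0.006})
    planted_correlations: tuple[tuple[str, str, float], ...] = (
        ("duration_C", "abeta42", -0.40),
        ("mean_duration", "scwt_w", 0.45),
    )
    noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_per_group) < 2:
            raise InvalidArgumentError("need at least 2 subjects per group")
        targets = [c for _, c, _ in self.planted_correlations]
        if len(set(targets)) != len(targets):
            raise InvalidArgumentError("each covariate may carry at most one planted rho")
        for _, cov, rho in self.planted_correlations:
            if not abs(rho) < 1:
                raise InvalidArgumentError("|target rho| must be < 1")
            if cov not in COVARIATE_TABLE:
                raise InvalidArgumentError(f"unknown covariate {cov!r}")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def _harmonic_basis(layout: SensorLayout) -> np.ndarray:
    """Low-order real spherical harmonics sampled at the electrodes.

    Degree-1 and degree-2 terms give smooth, dipolar/quadrupolar scalp
    patterns; random combinations of them mimic the large-scale structure of
    empirical microstate maps.
    """
    x, y, z = layout.positions.T
    funcs = [x, y, z, x * y, x * z, y * z, x**2 - y**2, 3 * z**2 - 1]
    basis = []
    for f in funcs:
        f = f - f.mean()
        n = np.linalg.norm(f)
        if n > 1e-12:
            basis.append(f / n)
    return np.array(basis)


def make_templates(layout: SensorLayout, k: int, seed: int,
                   max_abs_corr: float = 0.8) -> TemplateSet:
    """Random smooth template topographies, mutually non-collinear.

    Maps are random combinations of low-order spherical harmonics, rejected
    until every pair has |spatial correlation| below ``max_abs_corr``.
    Deterministic given the seed.
    """
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    if k > layout.n_channels - 1:
        raise InvalidArgumentError("k must be <= n_channels - 1")
    rng = np.random.default_rng(seed)
    basis = _harmonic_basis(layout)
    accepted: list[np.ndarray] = []
    for _ in range(10_000):
        coef = rng.standard_normal(basis.shape[0])
        m = coef @ basis
        m = m - m.mean()
        n = np.linalg.norm(m)
        if n < 1e-9:
            continue
        m = m / n
        if all(abs(float(m @ a)) < max_abs_corr for a in accepted):
            accepted.append(m)
        if len(accepted) == k:
            return TemplateSet(maps=np.array(accepted), class_labels=default_labels(k))
    raise InvalidArgumentError(
        f"could not draw {k} maps with pairwise |corr| < {max_abs_corr}")


# ---------------------------------------------------------------------------
# State sequences and recordings
# ---------------------------------------------------------------------------

def simulate_labels(dyn: DynamicsSpec, n_samples: int, sfreq: float,
                    seed: int) -> np.ndarray:
    """Semi-Markov per-sample class labels.

    Dwell times are gamma with per-class mean ``mean_dwell`` and coefficient
    of variation ``dwell_dispersion`` (shape 1/cv^2, scale mean*cv^2); each
    run lasts at least one sample, and successive classes are drawn from the
    normalized transition weights, so consecutive runs always differ.  With
    ``transition_sync_s`` set, each dwell is rounded to the nearest positive
    multiple of that interval (rounding to nearest preserves the mean) and
    the switch takes effect on the sample *after* the trough, so the
    zero-amplitude trough sample still belongs to the outgoing state.
    """
    if n_samples < 1:
        raise InvalidArgumentError("n_samples must be >= 1")
    if sfreq <= 0:
        raise InvalidArgumentError("sfreq must be positive")
    rng = np.random.default_rng(seed)
    means = dyn.dwell_means()
    cv = dyn.dwell_dispersion
    if cv <= 0:
        raise InvalidArgumentError("dwell_dispersion must be positive")
    shape = 1.0 / cv**2
    weights = dyn.weights()
    quantum = 0
    if dyn.transition_sync_s is not None:
        quantum = max(1, int(round(dyn.transition_sync_s * sfreq)))
    labels = np.empty(n_samples + 1, dtype=int)
    pos = 0
    state = int(rng.integers(dyn.k))
    while pos < len(labels):
        dwell_s = rng.gamma(shape, means[state] * cv**2)
        if quantum:
            length = quantum * max(1, int(round(dwell_s * sfreq / quantum)))
        else:
            length = max(1, int(round(dwell_s * sfreq)))
        end = min(pos + length, len(labels))
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(dyn.k, p=weights[state]))
    if quantum:
        # switch on the sample after the trough: shift labels right by one
        labels = np.concatenate([[labels[0]], labels[:-1]])
    return labels[:n_samples]


def synthesize_recording(
    templates: TemplateSet,
    labels: np.ndarray,
    layout: SensorLayout,
    sfreq: float = DEFAULT_SFREQ,
    osc_freq: float = 10.0,
    snr: float = 5.0,
    seed: int = 0,
    peak_gfp: float = DEFAULT_PEAK_GFP,
) -> Recording:
    """Scalp EEG from a label sequence: oscillating templates plus smooth noise.

    signal(t) = peak_gfp * sqrt(C) * sin(2 pi osc_freq t) * T_label(t):
    a signed alpha-class carrier whose field reverses polarity every half
    cycle — the oscillatory reversals that polarity-invariant microstate
    analysis is built around — under a rectified-sine amplitude envelope
    |sin|, so the GFP peaks twice per carrier cycle and at envelope maxima
    the noise-free topography equals the active template up to scale.  The
    signed carrier keeps the in-band (2-20 Hz) content of each dwell intact;
    a rectified carrier would put all its energy at DC and twice the carrier
    frequency, which the microstate band-pass mangles into artificial
    inter-state mixtures.  Sensor noise is Gaussian, smoothed across
    neighboring channels (making bad-channel detection nontrivial), and
    scaled so that RMS(signal)/RMS(noise) = ``snr``.  The carrier is
    deterministic: two seeds differ only in the noise.
    """
    if not 0 < osc_freq < sfreq / 2:
        raise InvalidArgumentError("osc_freq must lie in (0, sfreq/2)")
    if snr <= 0:
        raise InvalidArgumentError("snr must be positive")
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or len(labels) == 0:
        raise InvalidArgumentError("labels must be a nonempty 1-D sequence")
    if templates.n_channels != layout.n_channels:
        raise InvalidArgumentError("templates/layout channel mismatch")
    n = len(labels)
    t = np.arange(n) / sfreq
    carrier = np.sin(2 * np.pi * osc_freq * t)
    scale = peak_gfp * np.sqrt(layout.n_channels)
    signal = templates.maps[labels].T * (scale * carrier)  # (C, n)

    rng = np.random.default_rng(seed)
    white = rng.standard_normal((layout.n_channels, n))
    d2 = np.sum(
        (layout.positions[:, None, :] - layout.positions[None, :, :]) ** 2, axis=-1)
    kernel = np.exp(-d2 / (2 * 0.4**2))
    kernel /= kernel.sum(axis=1, keepdims=True)
    noise = kernel @ white
    rms_sig = np.sqrt(np.mean(signal**2))
    rms_noise = np.sqrt(np.mean(noise**2))
    noise *= rms_sig / (snr * rms_noise)
    return Recording(data=signal + noise, sfreq=sfreq, layout=layout)


def default_recording(seed: int, duration_s: float = 60.0,
                      n_channels: int = 60, snr: float = 5.0,
                      sfreq: float = DEFAULT_SFREQ,
                      ) -> tuple[Recording, np.ndarray, TemplateSet, SensorLayout]:
    """One recording under the generator's default study conditions.

    60-channel cap, four default-dynamics template classes, 60 s at 500 Hz,
    SNR 5.  All randomness (templates, label sequence, sensor noise) derives
    from ``seed`` through a SeedSequence, so the tuple is a pure function of
    the arguments.  Returns (recording, true labels, true templates, layout).
    """
    ss = np.random.SeedSequence([int(seed), 0])
    s_templates, s_labels, s_noise = (int(c.generate_state(1)[0] % (2**31))
                                      for c in ss.spawn(3))
    layout = make_layout(n_channels)
    dyn = DynamicsSpec()
    templates = make_templates(layout, dyn.k, seed=s_templates)
    labels = simulate_labels(dyn, int(round(duration_s * sfreq)), sfreq,
                             seed=s_labels)
    rec = synthesize_recording(templates, labels, layout, sfreq=sfreq,
                               snr=snr, seed=s_noise)
    return rec, labels, templates, layout


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _labels_to_metrics(labels: np.ndarray, sfreq: float, k: int) -> MicrostateMetrics:
    ls = LabelSequence(labels=labels[None, :], sfreq=sfreq, k=k,
                       epoch_ids=np.array([0]))
    return compute_metrics(segment_runs(ls))


@dataclass
class SyntheticSubject:
    """One simulated participant: ground-truth labels, metrics, recording."""

    subject_id: str
    group: str
    true_labels: np.ndarray
    true_metrics: MicrostateMetrics
    recording: Recording | None


def simulate_cohort(
    spec: CohortSpec,
    layout: SensorLayout | None = None,
    templates: TemplateSet | None = None,
    dyn: DynamicsSpec | None = None,
    duration_s: float = 60.0,
    sfreq: float = DEFAULT_SFREQ,
    snr: float = 5.0,
    osc_freq: float = 10.0,
    make_recordings: bool = True,
    n_channels: int = 60,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Simulate a two-group cohort and its covariate table.

    Patient-group dwell shifts from ``spec.group_effects`` are applied to
    the dynamics before simulating; planted correlations are realized
    against the *ground-truth* metrics (computed from the generating label
    sequences), so downstream estimates recover them up to measurement
    attenuation.  With ``make_recordings=False`` only label sequences and
    metrics are produced (cheap; used for statistical calibration studies).

    Returns (subjects, table); the table has one row per subject with
    columns ``subject, group, sex, age, education, <scores>, <csf>``.
    """
    spec.validate()
    if layout is None:
        layout = make_layout(n_channels)
    if dyn is None:
        dyn = DynamicsSpec()
    if templates is None and make_recordings:
        templates = make_templates(layout, dyn.k, seed=spec.seed)
    label_names = default_labels(dyn.k)
    shifts = {}
    for lab, s in spec.group_effects.items():
        if lab not in label_names:
            raise InvalidArgumentError(f"group_effects refers to unknown class {lab!r}")
        shifts[label_names.index(lab)] = s
    dyn_by_group = {"HC": dyn, "AD": dyn.with_dwell_shift(shifts) if shifts else dyn}

    n_samples = int(round(duration_s * sfreq))
    n_ad, n_hc = spec.n_per_group
    groups = ["AD"] * n_ad + ["HC"] * n_hc
    ss = np.random.SeedSequence(spec.seed)
    subj_seeds = ss.spawn(len(groups))
    cov_rng = np.random.default_rng(ss.spawn(1)[0])

    subjects: list[SyntheticSubject] = []
    for i, group in enumerate(groups):
        child = subj_seeds[i].generate_state(2)
        labels = simulate_labels(dyn_by_group[group], n_samples, sfreq,
                                 seed=int(child[0]))
        rec = None
        if make_recordings:
            rec = synthesize_recording(templates, labels, layout, sfreq=sfreq,
                                       osc_freq=osc_freq, snr=snr,
                                       seed=int(child[1]))
        subjects.append(SyntheticSubject(
            subject_id=f"S{i + 1:03d}",
            group=group,
            true_labels=labels,
            true_metrics=_labels_to_metrics(labels, sfreq, dyn.k),
            recording=rec,
        ))

    table = _covariate_table(spec, subjects, cov_rng)
    return subjects, table


def _covariate_table(spec: CohortSpec, subjects: list[SyntheticSubject],
                     rng: np.random.Generator) -> pd.DataFrame:
    groups = np.array([s.group for s in subjects])
    n = len(subjects)
    rows: dict[str, np.ndarray] = {
        "subject": np.array([s.subject_id for s in subjects], dtype=object),
        "group": groups.astype(object),
    }
    rows["sex"] = np.array(
        [("M" if rng.random() < _P_MALE[g] else "F") for g in groups], dtype=object)

    planted = {cov: (metric, rho) for metric, cov, rho in spec.planted_correlations}
    metric_rows = pd.DataFrame([s.true_metrics.to_row() for s in subjects])

    for cov, (mu_ad, sd_ad, mu_hc, sd_hc) in COVARIATE_TABLE.items():
        sd_override = spec.noise_sd.get(cov)
        vals = np.full(n, np.nan)
        for grp, mu, sd in (("AD", mu_ad, sd_ad), ("HC", mu_hc, sd_hc)):
            mask = groups == grp
            if np.isnan(mu):
                continue
            sd_g = sd_override if sd_override is not None else sd
            eps = rng.standard_normal(mask.sum())
            if cov in planted and grp == "AD":
                metric, rho = planted[cov]
                m = metric_rows.loc[mask, metric].to_numpy(dtype=float)
                z = (m - m.mean()) / m.std(ddof=0)
                # orthogonalize the noise against the metric so the sample
                # Pearson correlation is exactly rho, not just in expectation
                eps = eps - (eps @ z) / (z @ z) * z
                eps = (eps - eps.mean()) / eps.std(ddof=0)
                vals[mask] = mu + sd_g * (rho * z + np.sqrt(1 - rho**2) * eps)
            else:
                vals[mask] = mu + sd_g * eps
        rows[cov] = vals
    df = pd.DataFrame(rows)
    df.insert(3, "age", df.pop("age"))
    df.insert(4, "education", df.pop("education"))
    return df
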