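"""Backfitting and microstate dynamics metrics.

Backfitting assigns every EEG sample to the template with maximal
polarity-invariant spatial correlation, producing a per-sample label
sequence.  The sequence is collapsed into maximal constant-label runs
(never spanning epoch boundaries), from which the standard microstate
parameters are computed:

duration_c    mean run length of class c, seconds
occurrence_c  runs of class c per second of analyzed time
coverage_c    fraction of samples labeled c
TP(i -> j)    transitions i->j as a fraction of all inter-class transitions

These definitions make ``coverage_c = duration_c * occurrence_c`` an exact
algebraic identity, and mean occurrence the sum of the per-class
occurrences.  Runs truncated by an epoch edge are included in the duration
averages (excluding them would break the coverage identity) but flagged so
the alternative can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import TemplateSet, compute_gev, default_labels
from .errors import InvalidArgumentError
from .preproc import EpochSet

_NORM_EPS = 1e-12


@dataclass
class LabelSequence:
    """Per-sample microstate labels for the kept epochs.

    ``labels`` is (n_kept_epochs, n_samples_per_epoch) with class indices in
    0..k-1; ``epoch_ids`` maps rows back to original epoch indices.
    """

    labels: np.ndarray
    sfreq: float
    k: int
    epoch_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise InvalidArgumentError("labels must be (n_epochs, n_samples)")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise InvalidArgumentError("labels out of range for k classes")


@dataclass
class Run:
    """A maximal constant-label segment within one epoch."""

    class_index: int
    start: int  # sample within epoch
    length: int  # samples
    epoch: int
    truncated: bool  # touches an epoch edge


@dataclass
class RunList:
    runs: list[Run]
    sfreq: float
    k: int
    n_samples: int  # total labeled samples

    def __len__(self) -> int:
        return len(self.runs)


def backfit(ep: EpochSet, templates: TemplateSet,
            min_segment_ms: float = 0.0) -> LabelSequence:
    """Label every sample with its best-correlated template.

    Polarity-invariant: the winning template maximizes |Pearson spatial
    correlation|; ties go to the lowest class index.  Samples with (numerically)
    zero spatial variance — GFP below 1e-4 of the epoch's median GFP, i.e. at
    the measurement-noise floor — inherit the previous sample's label (the
    first samples of an epoch take the next valid label).  ``min_segment_ms`` optionally
    reassigns runs shorter than the given duration to the neighboring label
    with higher correlation; the default (0) applies no temporal smoothing.
    """
    kept = ep.kept()
    centered = kept - kept.mean(axis=1, keepdims=True)
    n_ep, n_ch, n_s = centered.shape
    # correlation with unit-norm zero-mean templates reduces to |dot| / norm;
    # the norm is label-independent so argmax |dot| suffices
    dots = np.einsum("ecs,kc->eks", centered, templates.maps)
    labels = np.argmax(np.abs(dots), axis=1)  # (E, S)
    norms = np.linalg.norm(centered, axis=1)  # (E, S)
    for e in range(n_ep):
        floor = max(_NORM_EPS, 1e-4 * float(np.median(norms[e])))
        dead = norms[e] < floor
        if dead.any():
            lab = labels[e]
            idx = np.flatnonzero(~dead)
            if len(idx) == 0:
                lab[:] = 0
            else:
                # forward fill from previous valid sample, then back fill head
                prev = idx[np.searchsorted(idx, np.arange(n_s), side="right") - 1]
                prev[: idx[0]] = idx[0]
                lab[:] = lab[prev]
            labels[e] = lab
    ls = LabelSequence(
        labels=labels,
        sfreq=ep.sfreq,
        k=templates.k,
        epoch_ids=np.flatnonzero(ep.kept_mask),
    )
    if min_segment_ms > 0:
        _smooth_short_segments(ls, centered, templates, min_segment_ms)
    return ls


def _smooth_short_segments(ls: LabelSequence, centered: np.ndarray,
                           templates: TemplateSet, min_segment_ms: float) -> None:
    min_len = max(1, int(round(min_segment_ms / 1000.0 * ls.sfreq)))
    dots = np.abs(np.einsum("ecs,kc->eks", centered, templates.maps))
    for e in range(ls.labels.shape[0]):
        lab = ls.labels[e]
        changed = True
        while changed:
            changed = False
            for r in _rle(lab):
                if r[2] < min_len:
                    left = lab[r[1] - 1] if r[1] > 0 else None
                    right = lab[r[1] + r[2]] if r[1] + r[2] < len(lab) else None
                    cands = [c for c in (left, right) if c is not None and c != r[0]]
                    if not cands:
                        continue
                    seg = slice(r[1], r[1] + r[2])
                    best = max(cands, key=lambda c: dots[e, c, seg].sum())
                    lab[seg] = best
                    changed = True
                    break


def _rle(lab: np.ndarray) -> list[tuple[int, int, int]]:
    """(class, start, length) runs of a 1-D label array."""
    if len(lab) == 0:
        return []
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(lab)]])
    return [(int(lab[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def segment_runs(ls: LabelSequence) -> RunList:
    """Collapse a label sequence into maximal constant-label runs per epoch.

    Runs never span epoch boundaries; the first and last run of each epoch
    are flagged as truncated (their true dwell extends beyond the epoch).
    """
    runs: list[Run] = []
    n_e, n_s = ls.labels.shape
    for e in range(n_e):
        rle = _rle(ls.labels[e])
        for j, (cls, start, length) in enumerate(rle):
            runs.append(Run(
                class_index=cls,
                start=start,
                length=length,
                epoch=int(ls.epoch_ids[e]),
                truncated=(j == 0 or j == len(rle) - 1),
            ))
    return RunList(runs=runs, sfreq=ls.sfreq, k=ls.k, n_samples=ls.labels.size)


@dataclass
class MicrostateMetrics:
    """Per-subject microstate parameters.

    Classes with zero runs get NaN duration/occurrence (missing, not zero).
    ``transition_matrix`` is jointly normalized over all ordered inter-class
    pairs: the off-diagonal entries sum to 1 when any transition occurred.
    """

    k: int
    class_labels: tuple[str, ...]
    duration: np.ndarray  # (k,) seconds
    occurrence: np.ndarray  # (k,) per second
    coverage: np.ndarray  # (k,) fraction
    mean_duration: float
    mean_occurrence: float
    gev: float
    total_time: float
    transition_matrix: np.ndarray  # (k, k), zero diagonal

    def to_row(self) -> dict[str, float]:
        """Flatten to one tidy row (the 28-column feature vector for k=4)."""
        row: dict[str, float] = {}
        for i, lab in enumerate(self.class_labels):
            row[f"duration_{lab}"] = self.duration[i]
        for i, lab in enumerate(self.class_labels):
            row[f"occurrence_{lab}"] = self.occurrence[i]
        for i, lab in enumerate(self.class_labels):
            row[f"coverage_{lab}"] = self.coverage[i]
        for i, a in enumerate(self.class_labels):
            for j, b in enumerate(self.class_labels):
                if i != j:
                    row[f"tp_{a}_{b}"] = self.transition_matrix[i, j]
        row["mean_duration"] = self.mean_duration
        row["mean_occurrence"] = self.mean_occurrence
        row["gev"] = self.gev
        row["total_time"] = self.total_time
        return row


def transition_probabilities(rl: RunList) -> np.ndarray:
    """Joint transition probabilities between consecutive runs.

    Transitions are counted between consecutive runs within each epoch,
    never across epochs, and normalized by the total transition count so the
    k*(k-1) off-diagonal entries sum to 1.  With zero transitions the matrix
    is all-NaN off the diagonal (missing, not zero).
    """
    k = rl.k
    counts = np.zeros((k, k))
    by_epoch: dict[int, list[Run]] = {}
    for r in rl.runs:
        by_epoch.setdefault(r.epoch, []).append(r)
    for runs in by_epoch.values():
        for a, b in zip(runs[:-1], runs[1:]):
            counts[a.class_index, b.class_index] += 1
    total = counts.sum()
    if total == 0:
        tm = np.full((k, k), np.nan)
        np.fill_diagonal(tm, 0.0)
        return tm
    tm = counts / total
    np.fill_diagonal(tm, 0.0)
    return tm


def compute_metrics(rl: RunList, gev: float = np.nan,
                    class_labels: tuple[str, ...] | None = None) -> MicrostateMetrics:
    """Microstate parameters from a run list (definitions in module docstring)."""
    if len(rl.runs) == 0:
        raise InvalidArgumentError("need at least one run")
    k = rl.k
    labels = class_labels if class_labels is not None else default_labels(k)
    total_time = rl.n_samples / rl.sfreq
    n_runs = np.zeros(k)
    time_in = np.zeros(k)
    for r in rl.runs:
        n_runs[r.class_index] += 1
        time_in[r.class_index] += r.length / rl.sfreq
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = np.where(n_runs > 0, time_in / np.maximum(n_runs, 1), np.nan)
    occurrence = np.where(n_runs > 0, n_runs / total_time, np.nan)
    coverage = time_in / total_time
    return MicrostateMetrics(
        k=k,
        class_labels=tuple(labels),
        duration=duration,
        occurrence=occurrence,
        coverage=coverage,
        mean_duration=total_time / len(rl.runs),
        mean_occurrence=len(rl.runs) / total_time,
        gev=gev,
        total_time=total_time,
        transition_matrix=transition_probabilities(rl),
    )


def metrics_table(rows: list[tuple[str, str, MicrostateMetrics]]) -> pd.DataFrame:
    """Tidy per-subject metrics: one row per (subject, group, metrics)."""
    records = []
    for subject, group, m in rows:
        rec = {"subject": subject, "group": group}
        rec.update(m.to_row())
        records.append(rec)
    return pd.DataFrame.from_records(records)
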