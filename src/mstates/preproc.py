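"""Preprocessing of continuous EEG into clean, average-referenced epochs.

The fixed pipeline order is: band-pass + notch filter -> resample ->
non-overlapping epochs -> bad-channel detection and interpolation ->
amplitude-based epoch rejection -> average reference.  All filters are
zero-phase (forward-backward Butterworth) so microstate boundaries are not
phase-shifted.

Units are microvolts, seconds and Hz throughout; sample indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import DataQualityError, InvalidArgumentError
from .layout import SensorLayout

#: Default amplitude-rejection threshold, uV.
DEFAULT_AMP_THRESH = 100.0
#: Default flat-line threshold (peak-to-peak per epoch), uV.
DEFAULT_FLAT_THRESH = 0.1
#: Default robust z threshold for neighbor-deviation channel flagging.
DEFAULT_NEIGHBOR_Z = 4.0
#: Fraction of epochs in which a per-epoch rule must fire to flag a channel.
BAD_EPOCH_FRACTION = 0.20
#: Abort when more than this fraction of channels is flagged bad.
MAX_BAD_FRACTION = 0.25


@dataclass
class Recording:
    """Continuous multichannel EEG in uV.

    ``data`` is (n_channels, n_samples); ``annotations`` is a list of
    (label, onset_s, duration_s) tuples carried through the pipeline.
    """

    data: np.ndarray
    sfreq: float
    layout: SensorLayout
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != self.layout.n_channels:
            raise InvalidArgumentError("data rows must match layout channel count")
        if self.sfreq <= 0:
            raise InvalidArgumentError("sfreq must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class EpochSet:
    """Equal-length epochs in uV: (n_epochs, n_channels, n_samples_per_epoch)."""

    epochs: np.ndarray
    sfreq: float
    layout: SensorLayout
    kept_mask: np.ndarray | None = None
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise InvalidArgumentError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.shape != (self.epochs.shape[0],):
                raise InvalidArgumentError("kept_mask must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def epoch_length(self) -> int:
        return self.epochs.shape[2]

    def kept(self) -> np.ndarray:
        """The kept epochs only, (n_kept, n_channels, n_samples)."""
        return self.epochs[self.kept_mask]

    @property
    def total_time(self) -> float:
        """Retained time in seconds (kept epochs x epoch length)."""
        return self.n_kept * self.epoch_length / self.sfreq


def _zero_phase(sos: np.ndarray, data: np.ndarray, sfreq: float,
                low_edge: float, axis: int = -1) -> np.ndarray:
    """Forward-backward filtering with padding matched to the slowest edge.

    scipy's default pad length is a few dozen samples, far too short for
    sub-hertz high-pass edges; here the signal is odd-extended by about
    three periods of the lowest critical frequency.
    """
    n = data.shape[axis]
    padlen = min(n - 1, max(int(3 * sfreq / max(low_edge, 1e-3)), 50))
    return signal.sosfiltfilt(sos, data, axis=axis, padlen=padlen)


def _validate_band(low: float, high: float, sfreq: float, what: str) -> None:
    if not (0 <= low < high < sfreq / 2):
        raise InvalidArgumentError(
            f"{what} ({low}, {high}) Hz invalid for sampling rate {sfreq} Hz"
        )


def apply_filters(
    rec: Recording,
    band: tuple[float, float] = (0.1, 40.0),
    notch: tuple[float, float] | None = (48.0, 52.0),
    order: int = 4,
) -> Recording:
    """Zero-phase band-pass then band-stop (notch) filtering.

    Butterworth filters of the given order, applied forward-backward
    (``sosfiltfilt``), so the effective attenuation is doubled and the phase
    response is zero.
    """
    low, high = band
    _validate_band(low, high, rec.sfreq, "band")
    nyq = rec.sfreq / 2
    if low > 0:
        sos = signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
        out = _zero_phase(sos, rec.data, rec.sfreq, low_edge=low, axis=1)
    else:
        sos = signal.butter(order, high / nyq, btype="lowpass", output="sos")
        out = _zero_phase(sos, rec.data, rec.sfreq, low_edge=high, axis=1)
    if notch is not None:
        nlow, nhigh = notch
        _validate_band(nlow, nhigh, rec.sfreq, "notch")
        sos_n = signal.butter(order, [nlow / nyq, nhigh / nyq], btype="bandstop", output="sos")
        out = _zero_phase(sos_n, out, rec.sfreq, low_edge=nhigh - nlow, axis=1)
    return replace(rec, data=out)


def resample(rec: Recording, target_sfreq: float) -> Recording:
    """Anti-aliased polyphase downsampling to ``target_sfreq``.

    Upsampling is rejected: the pipeline only ever decimates (e.g. 1000 Hz
    acquisitions to 500 Hz).
    """
    if target_sfreq > rec.sfreq:
        raise InvalidArgumentError("upsampling not supported")
    if target_sfreq <= 0:
        raise InvalidArgumentError("target_sfreq must be positive")
    if target_sfreq == rec.sfreq:
        return replace(rec, data=rec.data.copy())
    from fractions import Fraction

    frac = Fraction(target_sfreq / rec.sfreq).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=out, sfreq=target_sfreq)


def make_epochs(rec: Recording, length_s: float = 2.0) -> EpochSet:
    """Cut the recording into non-overlapping epochs of ``length_s`` seconds.

    A trailing partial segment is discarded.
    """
    if length_s <= 0:
        raise InvalidArgumentError("length_s must be positive")
    n_per = int(round(length_s * rec.sfreq))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        warnings.warn("recording shorter than one epoch; empty EpochSet")
        epochs = np.empty((0, rec.n_channels, n_per))
    else:
        epochs = (
            rec.data[:, : n_epochs * n_per]
            .reshape(rec.n_channels, n_epochs, n_per)
            .transpose(1, 0, 2)
            .copy()
        )
    return EpochSet(epochs=epochs, sfreq=rec.sfreq, layout=rec.layout)


def repair_bad_channels(
    ep: EpochSet,
    amp_thresh: float = DEFAULT_AMP_THRESH,
    flat_thresh: float = DEFAULT_FLAT_THRESH,
    neighbor_z: float = DEFAULT_NEIGHBOR_Z,
) -> EpochSet:
    """Flag and interpolate bad channels.

    A channel is flagged when any of three rules fires:

    a. amplitude — |v| exceeds ``amp_thresh`` in more than 20% of epochs;
    b. flat line — per-epoch peak-to-peak below ``flat_thresh`` in more than
       20% of epochs;
    c. neighbor deviation — the channel's median per-epoch residual from
       the mean of its 4 nearest neighbors, normalized by the RMS of the
       neighborhood, is both a robust-z outlier across channels (z >
       ``neighbor_z``) and larger than the neighborhood scale itself
       (ratio > 1.5).  The normalization keeps smooth topographic
       gradients — which make rim channels genuinely differ from their
       neighbors in amplitude — from registering as faults; a channel
       dominated by independent noise exceeds both gates.

    Flagged channels are replaced, sample by sample, with the
    inverse-distance-weighted mean of their 4 nearest *good* neighbors.
    These thresholds are automated surrogates for what is usually a visual
    judgement and are recorded alongside the output for that reason.
    """
    if min(amp_thresh, flat_thresh, neighbor_z) <= 0:
        raise InvalidArgumentError("thresholds must be positive")
    if ep.n_epochs == 0:
        return ep
    x = ep.epochs  # (E, C, S)
    n_epochs, n_channels, _ = x.shape

    frac_amp = np.mean(np.abs(x).max(axis=2) > amp_thresh, axis=0)  # per channel
    ptp = x.max(axis=2) - x.min(axis=2)
    frac_flat = np.mean(ptp < flat_thresh, axis=0)

    neighbors = ep.layout.nearest_neighbors(4)
    neigh = x[:, neighbors, :]  # (E, C, 4, S)
    neigh_mean = neigh.mean(axis=2)
    resid = np.sqrt(np.mean((x - neigh_mean) ** 2, axis=2))  # (E, C)
    scale = np.sqrt(np.mean(neigh**2, axis=(2, 3)))
    med_dev = np.median(resid / np.maximum(scale, 1e-12), axis=0)
    center = np.median(med_dev)
    mad = np.median(np.abs(med_dev - center))
    if mad > 0:
        z = (med_dev - center) / (1.4826 * mad)
    else:
        z = np.zeros(n_channels)
    neigh_bad = (z > neighbor_z) & (med_dev > 1.5)

    bad = (frac_amp > BAD_EPOCH_FRACTION) | (frac_flat > BAD_EPOCH_FRACTION) | neigh_bad
    bad_idx = np.flatnonzero(bad)
    if len(bad_idx) > MAX_BAD_FRACTION * n_channels:
        raise DataQualityError(
            f"{len(bad_idx)}/{n_channels} channels flagged bad (> {MAX_BAD_FRACTION:.0%})"
        )
    out = x.copy()
    if len(bad_idx):
        good = np.flatnonzero(~bad)
        pos = ep.layout.positions
        for c in bad_idx:
            d = np.linalg.norm(pos[good] - pos[c], axis=1)
            nearest = good[np.argsort(d)[:4]]
            w = 1.0 / np.maximum(np.linalg.norm(pos[nearest] - pos[c], axis=1), 1e-12)
            w = w / w.sum()
            out[:, c, :] = np.einsum("j,ejs->es", w, x[:, nearest, :])
    names = [ep.layout.channel_names[c] for c in bad_idx]
    return EpochSet(
        epochs=out,
        sfreq=ep.sfreq,
        layout=ep.layout,
        kept_mask=ep.kept_mask.copy(),
        bad_channels=names,
    )


def reject_epochs(ep: EpochSet, amp_thresh: float = DEFAULT_AMP_THRESH) -> EpochSet:
    """Drop epochs containing any sample outside +/- ``amp_thresh`` uV."""
    if amp_thresh <= 0:
        raise InvalidArgumentError("amp_thresh must be positive")
    ok = np.abs(ep.epochs).max(axis=(1, 2)) <= amp_thresh
    kept = ep.kept_mask & ok
    if ep.n_epochs > 0 and not kept.any():
        raise DataQualityError("all epochs rejected by amplitude criterion")
    return EpochSet(
        epochs=ep.epochs,
        sfreq=ep.sfreq,
        layout=ep.layout,
        kept_mask=kept,
        bad_channels=list(ep.bad_channels),
    )


def average_reference(ep: EpochSet) -> EpochSet:
    """Re-reference every sample to the instantaneous mean across channels."""
    if ep.epochs.shape[1] < 2:
        raise InvalidArgumentError("average reference needs >= 2 channels")
    out = ep.epochs - ep.epochs.mean(axis=1, keepdims=True)
    return EpochSet(
        epochs=out,
        sfreq=ep.sfreq,
        layout=ep.layout,
        kept_mask=ep.kept_mask.copy(),
        bad_channels=list(ep.bad_channels),
    )


def bandpass_epochs(ep: EpochSet, band: tuple[float, float], order: int = 4) -> EpochSet:
    """Zero-phase band-pass each epoch along time, then re-average-reference.

    Used to derive the 2-20 Hz copy of the epochs on which GFP peaks are
    extracted and backfitting is performed; the broadband copy is kept for
    reporting.
    """
    low, high = band
    _validate_band(low, high, ep.sfreq, "band")
    nyq = ep.sfreq / 2
    sos = signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    out = _zero_phase(sos, ep.epochs, ep.sfreq, low_edge=low, axis=2)
    filtered = EpochSet(
        epochs=out,
        sfreq=ep.sfreq,
        layout=ep.layout,
        kept_mask=ep.kept_mask.copy(),
        bad_channels=list(ep.bad_channels),
    )
    return average_reference(filtered)


@dataclass
class PreprocResult:
    """Broadband and microstate-band epoch sets produced by :func:`preprocess`."""

    broad: EpochSet
    narrow: EpochSet

    @property
    def total_time(self) -> float:
        return self.broad.total_time


def preprocess(
    rec: Recording,
    band: tuple[float, float] = (0.1, 40.0),
    notch: tuple[float, float] | None = (48.0, 52.0),
    target_sfreq: float = 500.0,
    epoch_s: float = 2.0,
    amp_thresh: float = DEFAULT_AMP_THRESH,
    flat_thresh: float = DEFAULT_FLAT_THRESH,
    neighbor_z: float = DEFAULT_NEIGHBOR_Z,
    microstate_band: tuple[float, float] = (2.0, 20.0),
    unmixing: np.ndarray | None = None,
    exclude_components: list[int] | None = None,
) -> PreprocResult:
    """Run the fixed preprocessing chain on a continuous recording.

    ``unmixing``/``exclude_components`` form a hook for an externally
    computed linear decomposition (e.g. an ICA run elsewhere): if given, the
    listed components are projected out of the continuous data after
    filtering.  The pipeline never computes such a decomposition itself.
    """
    rec = apply_filters(rec, band=band, notch=notch)
    if unmixing is not None and exclude_components:
        w = np.asarray(unmixing, dtype=float)
        sources = w @ rec.data
        sources[list(exclude_components), :] = 0.0
        rec = replace(rec, data=np.linalg.pinv(w) @ sources)
    if target_sfreq < rec.sfreq:
        rec = resample(rec, target_sfreq)
    ep = make_epochs(rec, epoch_s)
    ep = repair_bad_channels(ep, amp_thresh=amp_thresh, flat_thresh=flat_thresh,
                             neighbor_z=neighbor_z)
    ep = reject_epochs(ep, amp_thresh=amp_thresh)
    broad = average_reference(ep)
    narrow = bandpass_epochs(broad, microstate_band)
    return PreprocResult(broad=broad, narrow=narrow)
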