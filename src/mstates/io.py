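"""Reading and writing recordings, epochs, templates and tables.

The package's own text "dump" format for recordings is a JSON header line
(sampling rate, channel names, unit-sphere positions) followed by one
whitespace-separated row of channel values (uV) per sample — lossless for
round-trips and diff-friendly.  EDF and FIF containers are read via mne;
recordings can be written to FIF.  Tables are CSV with a header, UTF-8,
'.' decimal separator, and missing values as empty fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import TemplateSet
from .errors import InvalidArgumentError
from .layout import SensorLayout, make_layout
from .preproc import EpochSet, Recording

_DUMP_MAGIC = "mstates-recording-v1"


def write_recording_dump(rec: Recording, path: str | Path) -> None:
    """Write a recording to the package's text dump format."""
    path = Path(path)
    header = {
        "format": _DUMP_MAGIC,
        "sfreq": rec.sfreq,
        "channel_names": list(rec.layout.channel_names),
        "positions": rec.layout.positions.tolist(),
        "annotations": rec.annotations,
        "n_samples": rec.n_samples,
    }
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g")


def read_recording_dump(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording_dump`."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise InvalidArgumentError(f"{path}: not a recording dump") from exc
        if header.get("format") != _DUMP_MAGIC:
            raise InvalidArgumentError(f"{path}: unknown dump format")
        data = np.loadtxt(fh, ndmin=2).T
    if data.shape[1] != header["n_samples"]:
        raise InvalidArgumentError(
            f"{path}: truncated dump ({data.shape[1]} of {header['n_samples']} samples)")
    layout = SensorLayout(
        channel_names=tuple(header["channel_names"]),
        positions=np.asarray(header["positions"]),
    )
    return Recording(
        data=data,
        sfreq=header["sfreq"],
        layout=layout,
        annotations=[tuple(a) for a in header.get("annotations", [])],
    )


def _layout_from_mne(raw) -> SensorLayout:
    """Build a layout from an mne Raw's montage, or fail listing channels."""
    import mne

    montage = raw.get_montage()
    if montage is None:
        try:
            raw = raw.copy().set_montage("standard_1005", on_missing="raise")
            montage = raw.get_montage()
        except Exception as exc:
            raise InvalidArgumentError(
                f"no sensor positions for channels {raw.ch_names}: {exc}") from exc
    pos_map = montage.get_positions()["ch_pos"]
    missing = [ch for ch in raw.ch_names if ch not in pos_map or
               np.any(~np.isfinite(pos_map[ch]))]
    if missing:
        raise InvalidArgumentError(f"channels without positions: {missing}")
    pos = np.array([pos_map[ch] for ch in raw.ch_names])
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorLayout(channel_names=tuple(raw.ch_names), positions=pos / norms)


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read EDF, FIF, or the package's synthetic dump into a Recording (uV)."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".edf": "edf", ".fif": "fif", ".txt": "dump", ".dump": "dump"}.get(
            suffix)
        if format is None:
            raise InvalidArgumentError(f"cannot infer format of {path}")
    if format == "dump":
        return read_recording_dump(path)
    import mne

    if format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif format == "fif":
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    else:
        raise InvalidArgumentError(f"unknown format {format!r}")
    layout = _layout_from_mne(raw)
    data_uv = raw.get_data() * 1e6  # mne works in volts
    return Recording(data=data_uv, sfreq=float(raw.info["sfreq"]), layout=layout)


def write_recording_fif(rec: Recording, path: str | Path) -> None:
    """Write a recording to a FIF container via mne (data stored in volts)."""
    import mne

    info = mne.create_info(list(rec.layout.channel_names), rec.sfreq, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    montage = mne.channels.make_dig_montage(
        ch_pos={ch: rec.layout.positions[i] * 0.095  # ~9.5 cm head radius
                for i, ch in enumerate(rec.layout.channel_names)})
    raw.set_montage(montage, verbose="error")
    raw.save(path, overwrite=True, verbose="error")


def write_epochs(ep: EpochSet, path: str | Path, thresholds: dict | None = None) -> None:
    """Save an epoch set to .npz with a JSON sidecar of processing metadata."""
    path = Path(path)
    np.savez(path, epochs=ep.epochs, kept_mask=ep.kept_mask,
             positions=ep.layout.positions)
    sidecar = {
        "sfreq": ep.sfreq,
        "channel_names": list(ep.layout.channel_names),
        "bad_channels": list(ep.bad_channels),
        "kept_mask": ep.kept_mask.tolist(),
        "thresholds": thresholds or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    layout = SensorLayout(
        channel_names=tuple(sidecar["channel_names"]),
        positions=arrays["positions"],
    )
    return EpochSet(
        epochs=arrays["epochs"],
        sfreq=sidecar["sfreq"],
        layout=layout,
        kept_mask=arrays["kept_mask"],
        bad_channels=list(sidecar["bad_channels"]),
    )


def write_templates(ts: TemplateSet, layout: SensorLayout, path: str | Path) -> None:
    """Channel-annotated delimited template matrix with a JSON header line."""
    path = Path(path)
    header = {
        "k": ts.k,
        "class_labels": list(ts.class_labels),
        "channel_names": list(layout.channel_names),
        "normalization": "zero-mean, unit Euclidean norm per map",
    }
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        df = pd.DataFrame(ts.maps.T, index=layout.channel_names,
                          columns=list(ts.class_labels))
        df.to_csv(fh)


def read_templates(path: str | Path) -> tuple[TemplateSet, list[str]]:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        df = pd.read_csv(fh, index_col=0)
    ts = TemplateSet(maps=df.to_numpy().T, class_labels=tuple(header["class_labels"]))
    return ts, header["channel_names"]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with header; UTF-8; '.' decimals; missing values as empty fields."""
    if len(table) == 0:
        raise InvalidArgumentError("refusing to write an empty table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
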