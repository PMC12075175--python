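"""Session and feature-tensor persistence.

Two on-disk session formats are supported:

* an HDF5 container with datasets ``/emg`` (samples x channels, float64),
  ``/labels`` (int64), ``/channel_map`` (channels x 2) and root attributes
  ``fs`` and ``schema_version`` -- the native, lossless format;
* an RFC-4180 CSV dialect with header ``t,ch01..chNN,label`` (UTF-8,
  '.' decimal), convenient for inspection and small fixtures.

Both round-trip: ``read_session(write_session(rec))`` reproduces the signal
bit-exactly (HDF5) and labels/metadata exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .recording import EmgRecording, SchemaError

SCHEMA_VERSION = 1


def write_session(rec: EmgRecording, path: str | Path) -> Path:
    """Write a session to ``path``; format chosen by suffix (.h5/.hdf5 or .csv)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        _write_h5(rec, path)
    elif path.suffix.lower() == ".csv":
        _write_csv(rec, path)
    else:
        raise SchemaError(f"unknown session format '{path.suffix}' (use .h5 or .csv)")
    return path


def read_session(path: str | Path) -> EmgRecording:
    """Read and validate a session written by :func:`write_session`."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return _read_h5(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    raise SchemaError(f"unknown session format '{path.suffix}' (use .h5 or .csv)")


def _write_h5(rec: EmgRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=rec.data)
        f.create_dataset("labels", data=rec.labels)
        if rec.channel_map is not None:
            f.create_dataset("channel_map", data=rec.channel_map)
        f.attrs["fs"] = rec.fs
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["meta_json"] = json.dumps(rec.meta, default=str)


def _read_h5(path: Path) -> EmgRecording:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unknown schema version {version} in {path}")
        if "emg" not in f or "labels" not in f:
            raise SchemaError(f"{path} lacks /emg or /labels datasets")
        data = f["emg"][()]
        labels = f["labels"][()]
        channel_map = f["channel_map"][()] if "channel_map" in f else None
        fs = float(f.attrs["fs"])
        meta = json.loads(f.attrs.get("meta_json", "{}"))
    if labels.shape[0] != data.shape[0]:
        raise SchemaError(f"label/sample length mismatch in {path}")
    return EmgRecording(data=data, fs=fs, labels=labels, channel_map=channel_map, meta=meta)


def _write_csv(rec: EmgRecording, path: Path) -> None:
    n_ch = rec.n_channels
    header = "t," + ",".join(f"ch{c + 1:02d}" for c in range(n_ch)) + ",label"
    t = np.arange(rec.n_samples) / rec.fs
    table = np.column_stack([t, rec.data, rec.labels.astype(float)])
    fmt = ["%.9g"] * (n_ch + 1) + ["%d"]
    np.savetxt(path, table, delimiter=",", header=header, comments="", fmt=fmt)


def _read_csv(path: Path) -> EmgRecording:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    cols = header.split(",")
    if len(cols) < 3 or cols[0] != "t" or cols[-1] != "label":
        raise SchemaError(f"CSV header must be 't,ch01..chNN,label', got '{header}'")
    n_ch = len(cols) - 2
    if cols[1:-1] != [f"ch{c + 1:02d}" for c in range(n_ch)]:
        raise SchemaError(f"unexpected channel columns in '{header}'")
    try:
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise SchemaError(f"malformed CSV body in {path}: {exc}") from exc
    if table.shape[1] != n_ch + 2:
        raise SchemaError(f"CSV rows have {table.shape[1]} fields, expected {n_ch + 2}")
    t = table[:, 0]
    if len(t) > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise SchemaError("non-uniform time column")
        fs = 1.0 / dt[0]
    else:
        fs = 1.0
    labels = table[:, -1]
    if not np.allclose(labels, np.round(labels)):
        raise SchemaError("label column must be integer gesture ids")
    return EmgRecording(data=table[:, 1:-1], fs=fs, labels=labels.astype(np.int64))


def select_density(rec: EmgRecording, mode: str) -> EmgRecording:
    """Reduce a session to the requested electrode density.

    ``medium`` keeps all channels (identity).  ``low`` keeps one channel per
    sensor node: the within-node *middle* position (position 2 of 1..3), i.e.
    7 of 21 channels for the default armband.  Idempotent in both modes.
    """
    if mode == "medium":
        return rec
    if mode != "low":
        raise ValueError(f"density mode must be 'medium' or 'low', got '{mode}'")
    if rec.channel_map is None:
        raise SchemaError("select_density('low') requires a channel_map")
    nodes = np.unique(rec.channel_map[:, 0])
    positions = rec.channel_map[:, 1]
    middle = int(np.median(np.unique(positions)))
    keep = []
    for node in nodes:
        idx = np.flatnonzero((rec.channel_map[:, 0] == node) & (positions == middle))
        if idx.size != 1:
            raise SchemaError(f"node {node} lacks a unique middle channel (position {middle})")
        keep.append(idx[0])
    keep = np.array(keep)
    meta = dict(rec.meta)
    meta["density"] = "low"
    return EmgRecording(data=rec.data[:, keep], fs=rec.fs, labels=rec.labels.copy(),
                        channel_map=rec.channel_map[keep], meta=meta)


def write_features(tensor: np.ndarray, labels: np.ndarray, path: str | Path,
                   axis_labels: dict | None = None) -> Path:
    """Store a [samples, time_steps, channels, features] tensor with labels."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=tensor)
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["axes"] = json.dumps(axis_labels or {})
    return path


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "features" not in f or "labels" not in f:
            raise SchemaError(f"{path} lacks /features or /labels")
        tensor = f["features"][()]
        labels = f["labels"][()]
        axes = json.loads(f.attrs.get("axes", "{}"))
    if tensor.shape[0] != labels.shape[0]:
        raise SchemaError("feature/label sample count mismatch")
    return tensor, labels, axes
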