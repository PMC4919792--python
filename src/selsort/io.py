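"""Shared file readers and writers (HDF5, CSV, JSON).

Traces travel as HDF5 (``/trace`` dataset with a ``sampling_rate``
attribute) or single-column CSV; ground truth as JSON. The MAT-file
benchmark dialect lives in :mod:`selsort.synthgen` next to the generator.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


class FileFormatError(ValueError):
    """A file is missing a required variable or is malformed."""


def write_trace_h5(path, samples, sampling_rate: float, rec_id: str = "") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace", data=np.asarray(samples, dtype=np.float64))
        d.attrs["sampling_rate"] = float(sampling_rate)
        d.attrs["id"] = rec_id


def read_trace_h5(path):
    """Return ``(samples, sampling_rate, id)`` from an HDF5 trace file."""
    with h5py.File(path, "r") as f:
        if "trace" not in f:
            raise FileFormatError(f"{path}: missing dataset 'trace'")
        d = f["trace"]
        return (
            np.asarray(d[...], dtype=np.float64),
            float(d.attrs.get("sampling_rate", 24000.0)),
            str(d.attrs.get("id", "")),
        )


def write_trace_csv(path, samples) -> None:
    pd.DataFrame({"voltage": np.asarray(samples, dtype=np.float64)}).to_csv(
        path, index=False
    )


def read_trace_csv(path):
    df = pd.read_csv(path)
    if "voltage" in df.columns:
        col = df["voltage"]
    else:
        col = df.iloc[:, 0]
    return col.to_numpy(dtype=np.float64)


def write_events_csv(path, indices, values=None) -> None:
    indices = np.asarray(indices, dtype=np.int64)
    if values is None:
        values = np.full(indices.shape, np.nan)
    pd.DataFrame({"index": indices, "value": np.asarray(values)}).to_csv(
        path, index=False
    )


def read_events_csv(path):
    df = pd.read_csv(path)
    return df["index"].to_numpy(dtype=np.int64)


def write_labels_csv(path, event_indices, labels) -> None:
    pd.DataFrame(
        {
            "event_index": np.asarray(event_indices, dtype=np.int64),
            "label": np.asarray(labels, dtype=np.int64),
        }
    ).to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
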