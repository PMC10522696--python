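"""HDF5 session container I/O.

Layout: ``/lfp`` and ``/mua`` are (channels, time, trials) float datasets,
``/time_ms`` the time axis, ``/trials/<column>`` the embedded trial table
(strings stored as UTF-8), and ``/meta`` attributes carry sampling metadata
plus a JSON blob with free-form metadata (ground truth for synthetic
sessions). Round trips are lossless: arrays bit-exact, table values equal.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import SessionRecording
from .errors import SchemaError

SCHEMA_VERSION = "1"


def write_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write a session to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.lfp)
        f.create_dataset("mua", data=rec.mua)
        f.create_dataset("time_ms", data=rec.time_ms)
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["sample_rate_hz"] = rec.sample_rate_hz
        meta.attrs["channel_spacing_mm"] = rec.channel_spacing_mm
        meta.attrs["time_zero"] = rec.time_zero
        meta.attrs["units"] = "lfp: V (arbitrary scale); mua: envelope z-units; time: ms"
        meta.attrs["extra_json"] = json.dumps(rec.meta, default=str)
        tgrp = f.create_group("trials")
        for col in rec.trials.columns:
            vals = rec.trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                tgrp.create_dataset(col, data=np.asarray(vals, dtype=object),
                                    dtype=h5py.string_dtype("utf-8"))
            else:
                tgrp.create_dataset(col, data=vals)
        tgrp.attrs["columns"] = json.dumps(list(rec.trials.columns))
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read a session container, validating schema and shapes."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"cannot open container {path}: {exc}") from exc
    with f:
        for name in ("lfp", "mua", "time_ms", "meta", "trials"):
            if name not in f:
                raise SchemaError(f"missing group/dataset '{name}' in {path}")
        meta = f["meta"]
        version = meta.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unknown schema version {version!r}")
        lfp = f["lfp"][()]
        mua = f["mua"][()]
        time_ms = f["time_ms"][()]
        if lfp.shape != mua.shape:
            raise SchemaError("field 'mua': shape mismatch with 'lfp'")
        cols = json.loads(f["trials"].attrs.get("columns", "[]"))
        data = {}
        for col in cols:
            if col not in f["trials"]:
                raise SchemaError(f"field 'trials/{col}' missing")
            vals = f["trials"][col][()]
            if vals.dtype.kind in "OS":
                vals = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                 for v in vals], dtype=object)
            data[col] = vals
        trials = pd.DataFrame(data)
        extra = json.loads(meta.attrs.get("extra_json", "{}"))
        return SessionRecording(
            lfp=lfp, mua=mua, time_ms=time_ms,
            sample_rate_hz=float(meta.attrs["sample_rate_hz"]),
            channel_spacing_mm=float(meta.attrs["channel_spacing_mm"]),
            trials=trials, meta=extra)
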