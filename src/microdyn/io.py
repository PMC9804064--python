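"""Scan and manifest I/O.

One scan is stored as a delimited matrix file (parcels x samples,
tab-separated by default) plus a JSON sidecar holding the sampling rate
and metadata. Values are written at full double precision so a
write/read round trip is lossless up to decimal representation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import ParcelTimeSeries

__all__ = ["write_scan", "read_scan", "sidecar_path", "write_json", "read_json"]


def sidecar_path(matrix_path: str | Path) -> Path:
    return Path(matrix_path).with_suffix(".json")


def write_scan(ts: ParcelTimeSeries, path: str | Path, delimiter: str = "\t") -> Path:
    """Write ``ts`` to ``path`` (matrix) + a ``.json`` sidecar; returns the matrix path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ts.data, fmt="%.17g", delimiter=delimiter)
    meta = {
        "fs": ts.fs,
        "parcel_labels": list(ts.parcel_labels),
        "scan_id": ts.scan_id,
        "group": ts.group,
        "n_parcels": ts.n_parcels,
        "n_samples": ts.n_samples,
    }
    write_json(meta, sidecar_path(path))
    return path


def read_scan(path: str | Path, delimiter: str | None = None) -> ParcelTimeSeries:
    """Read a scan written by :func:`write_scan`.

    ``delimiter=None`` autodetects tab vs comma from the first line, so both
    TSV and plain CSV matrices parse identically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scan matrix not found: {path}")
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"sidecar header not found: {side}")
    meta = read_json(side)
    for key in ("fs", "parcel_labels"):
        if key not in meta:
            raise ValueError(f"sidecar {side} missing required field {key!r}")
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "\t" if "\t" in first else ","
    data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if "n_parcels" in meta and data.shape[0] != meta["n_parcels"]:
        raise ValueError(
            f"header/matrix shape mismatch for {path}: header says "
            f"{meta['n_parcels']} parcels, matrix has {data.shape[0]} rows"
        )
    if "n_samples" in meta and data.shape[1] != meta["n_samples"]:
        raise ValueError(
            f"header/matrix shape mismatch for {path}: header says "
            f"{meta['n_samples']} samples, matrix has {data.shape[1]} columns"
        )
    return ParcelTimeSeries(
        data=data,
        fs=float(meta["fs"]),
        parcel_labels=list(meta["parcel_labels"]),
        scan_id=str(meta.get("scan_id", path.stem)),
        group=str(meta.get("group", "NA")),
    )


def write_json(obj: object, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")
    return path


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj: object):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
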