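"""Text-format I/O: TSV traces with JSON sidecars, pixel matrices, configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .simulate import Protocol, Trace

__all__ = [
    "write_trace_tsv",
    "read_trace_tsv",
    "write_pixel_matrix",
    "read_pixel_matrix",
    "load_config",
    "save_config",
    "config_hash",
]


def write_trace_tsv(trace: Trace, path) -> Path:
    """Two-column TSV (time_s, current_pA) plus a ``<path>.json`` metadata
    sidecar carrying sample rate, applied filters, seed and protocol."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([trace.t, trace.i_pA]),
        delimiter="\t",
        header="time_s\tcurrent_pA",
        comments="",
        fmt="%.9g",
    )
    meta = {
        "sample_rate_hz": trace.sample_rate_hz,
        **{k: v for k, v in trace.metadata.items()},
    }
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(json.dumps(meta, indent=1, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_trace_tsv(path) -> Trace:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    sidecar = path.with_name(path.name + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    fs = meta.pop("sample_rate_hz", None)
    if fs is None:
        dt = np.median(np.diff(data[:, 0]))
        fs = 1.0 / dt
    protocol = None
    if "protocol" in meta:
        protocol = Protocol.from_dict(meta["protocol"])
    return Trace(data[:, 0], data[:, 1], float(fs), meta, protocol)


def write_pixel_matrix(matrix: np.ndarray, path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(matrix, dtype=int), fmt="%d")
    return path


def read_pixel_matrix(path) -> np.ndarray:
    arr = np.loadtxt(path, dtype=int)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for artifact provenance."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]
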