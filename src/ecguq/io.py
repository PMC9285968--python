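"""Plain-text I/O for space-time field matrices and run manifests.

A field file is a CSV matrix: the first column holds the curvilinear
collocation coordinate ``s_i``, the header row holds the time instants in
ms, and the body holds the field values at full double precision, so that a
write/read round trip is the identity.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_field", "read_field", "config_hash", "write_manifest", "read_manifest"]


def write_field(path: str | Path, values: np.ndarray, s: np.ndarray,
                times: np.ndarray) -> None:
    """Write a field matrix (rows = s_i, columns = t_j) as CSV."""
    values = np.asarray(values, dtype=float)
    if values.shape != (np.size(s), np.size(times)):
        raise ValueError("values must have shape (len(s), len(times))")
    df = pd.DataFrame(values, index=np.asarray(s, dtype=float),
                      columns=np.asarray(times, dtype=float))
    df.index.name = "s"
    df.to_csv(path, float_format="%.17g")


def read_field(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a field CSV; returns ``(values, s, times)`` with times ascending.

    Columns are reordered by their declared time value, so a file with
    permuted columns reads back into canonical time order.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty field file")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    if not header or header[0] != "s":
        raise ValueError(f"{path}:1: malformed header, expected first column 's'")
    try:
        times = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}:1: non-numeric time column in header: {exc}") from exc
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    order = np.argsort(times, kind="stable")
    return df.to_numpy()[:, order], df.index.to_numpy(dtype=float), times[order]


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True, default=str))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
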