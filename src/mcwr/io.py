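"""Plain-text I/O: headerless CSV matrices, JSON/YAML run configs, and
round-trip-exact result tables (floats written with 17 significant digits)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_samples",
    "read_config",
    "write_stats",
    "write_metadata",
]

_FLOAT_FMT = "%.17g"


def read_matrix(path) -> np.ndarray:
    """Headerless CSV of floats, row-major."""
    M = np.loadtxt(path, delimiter=",", ndmin=2)
    return M


def write_matrix(path, M) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(M, dtype=float)),
               delimiter=",", fmt=_FLOAT_FMT)


def read_samples(path) -> dict:
    """Per-stage reward observations: one CSV row per stage, ragged rows
    allowed, blank rows meaning a non-reproductive stage."""
    out = {}
    for j, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip().strip(",")
        if not line:
            continue
        out[j] = np.array([float(x) for x in line.split(",")])
    return out


def read_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        return yaml.safe_load(text)


def write_stats(path, table: pd.DataFrame) -> None:
    table.to_csv(path, float_format=_FLOAT_FMT)


def write_metadata(path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
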