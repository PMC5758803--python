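"""Readers and writers for the package's plain-text interchange formats.

Traces travel as CSV with a ``time_s`` column plus one ``neuron_<id>`` column
per ROI; the protocol as JSON; ground truth, event logs and all result tables
as CSV; population and spatial results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .signal import RoiTrace
from .stats import PopulationSummary, SpatialHeterogeneityResult

__all__ = [
    "read_traces_csv",
    "read_ground_truth_csv",
    "write_population_json",
    "write_spatial_json",
]


def read_traces_csv(path: str | Path) -> list[RoiTrace]:
    """Load ROI traces from a ``time_s`` + ``neuron_<id>`` column table."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise InvalidArgumentError(f"{path}: missing required column 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidArgumentError(f"{path}: need >= 2 frames")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise InvalidArgumentError(f"{path}: frame times are not uniform")
    frame_rate = 1.0 / float(np.mean(dt))
    traces = []
    for col in df.columns:
        if not col.startswith("neuron_"):
            continue
        traces.append(
            RoiTrace(
                neuron_id=col.removeprefix("neuron_"),
                frame_rate_hz=frame_rate,
                f=df[col].to_numpy(dtype=float),
                t0_s=float(t[0]),
            )
        )
    if not traces:
        raise InvalidArgumentError(f"{path}: no neuron_<id> columns found")
    return traces


def read_ground_truth_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"neuron_id", "bf_hz", "is_echo", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"{path}: missing columns {sorted(missing)}")
    df["neuron_id"] = df["neuron_id"].map(lambda v: f"{v:03d}" if isinstance(v, (int, np.integer)) else str(v))
    return df


def _jsonable(v):
    if v is None or isinstance(v, (str, bool, int)):
        return v
    if isinstance(v, float):
        return None if not np.isfinite(v) else v
    if isinstance(v, (np.floating, np.integer)):
        return _jsonable(v.item())
    raise TypeError(f"cannot serialize {type(v)}")


def write_population_json(summary: PopulationSummary, path: str | Path) -> None:
    payload = {k: _jsonable(v) for k, v in summary.as_dict().items()}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def write_spatial_json(result: SpatialHeterogeneityResult | None, path: str | Path) -> None:
    if result is None:
        payload = {"available": False}
    else:
        payload = {k: _jsonable(v) for k, v in result.__dict__.items()}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
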