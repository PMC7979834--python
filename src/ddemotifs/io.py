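"""Readers and writers for trajectories, curves, maps and reports.

Time series and curves travel as CSV (pandas round-trip, 17 significant
digits); reports and solver metadata as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import Trajectory

__all__ = [
    "trajectory_frame",
    "write_trajectory",
    "read_trajectory_csv",
    "write_curve",
    "write_report",
]

_FLOAT_FMT = "%.17g"


def trajectory_frame(traj: Trajectory, dt: float | None = None, t_start: float = 0.0) -> pd.DataFrame:
    """Trajectory as a DataFrame with header T,<node>,... (mesh or uniform)."""
    if dt is None:
        ts = traj.times
        vals = traj.values
    else:
        from .solver import resample_uniform

        ts, vals = resample_uniform(traj, dt, t_start)
    if vals.ndim == 3:
        raise ValueError("ensemble trajectories are exported one member at a time")
    return pd.DataFrame({"T": ts, **{nm: vals[:, i] for i, nm in enumerate(traj.node_names)}})


def write_trajectory(
    traj: Trajectory, path: str | Path, dt: float | None = None, t_start: float = 0.0
) -> Path:
    """CSV export plus a JSON sidecar with solver metadata."""
    path = Path(path)
    frame = trajectory_frame(traj, dt=dt, t_start=t_start)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {k: v for k, v in traj.metadata.items()}
    meta["node_names"] = list(traj.node_names)
    meta["t_end"] = traj.t_end
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: the default C parser is not correctly rounded and
    # would break bit-identity of the 17-digit export
    frame = pd.read_csv(path, float_precision="round_trip")
    if "T" not in frame.columns:
        raise ValueError(f"{path} is not a trajectory export (missing T column)")
    return frame


def write_curve(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, complex):
            return {"re": o.real, "im": o.imag}
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=default))
    return path
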