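"""Reading and writing trajectory tables and reports.

The canonical trajectory table is a tidy CSV with one row per cell per
sample: ``cell_id, step, t_min, x_um, y_um`` — the same schema for simulated
output and for imported manual-tracking data, so either side of a
comparison can come from a file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import Trajectory

__all__ = [
    "trajectories_to_frame",
    "frame_to_trajectories",
    "write_trajectories",
    "read_trajectories",
    "import_imagej_tracks",
    "write_report",
]

COLUMNS = ["cell_id", "step", "t_min", "x_um", "y_um"]


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for step, (x, y) in enumerate(tr.positions):
            rows.append((tr.cell_id, step, step * tr.dt, x, y))
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_trajectories(df: pd.DataFrame, min_samples: int = 2) -> list[Trajectory]:
    """Rebuild Trajectory objects from a tidy table; cells with fewer than
    ``min_samples`` samples are dropped (short manual tracks)."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table is missing columns {missing}")
    out = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("step")
        if len(g) < min_samples:
            continue
        t = g["t_min"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        out.append(
            Trajectory(
                cell_id=int(cid),
                positions=g[["x_um", "y_um"]].to_numpy(dtype=float),
                dt=dt,
            )
        )
    return out


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False)


def read_trajectories(path: str | Path, min_samples: int = 2) -> list[Trajectory]:
    return frame_to_trajectories(pd.read_csv(path), min_samples=min_samples)


def import_imagej_tracks(
    path: str | Path, pixel_size_um: float, frame_minutes: float
) -> list[Trajectory]:
    """Import an ImageJ Manual Tracking export (track id, slice, x, y in
    pixels) given the pixel size and frame interval."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"could not find any of {names} in {list(df.columns)}")

    track = pick("track n°", "track no", "track", "track id", "tracknb")
    slice_col = pick("slice n°", "slice no", "slice", "frame")
    xcol = pick("x", "x (px)")
    ycol = pick("y", "y (px)")
    tidy = pd.DataFrame(
        {
            "cell_id": df[track].astype(int),
            "step": df[slice_col].astype(int) - df[slice_col].astype(int).min(),
            "x_um": df[xcol].astype(float) * pixel_size_um,
            "y_um": df[ycol].astype(float) * pixel_size_um,
        }
    )
    tidy["t_min"] = tidy["step"] * frame_minutes
    return frame_to_trajectories(tidy[COLUMNS])


def _to_native(obj):
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_native(report), indent=2))
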