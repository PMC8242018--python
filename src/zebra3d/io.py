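"""CSV dialects for tracking exports, LED traces and fused trajectories.

Formats are deliberately plain:

* per-view tracking: ``frame,time_s,x,y`` (ventral) / ``frame,time_s,x,z``
  (lateral), missing positions as empty fields;
* LED trace: ``frame,intensity``;
* 3D trajectory: ``frame,time_s,x,y,z,phase,interpolated``
  (ground-truth paths omit the ``interpolated`` column).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import IntensityTrace, TrackSeries, Trajectory3D


def write_track_csv(series: TrackSeries, path: str | Path) -> None:
    a1, a2 = series.axes
    df = pd.DataFrame({"frame": series.frame, "time_s": series.time_s,
                       a1: series.c1, a2: series.c2})
    df.to_csv(path, index=False)


def read_track_csv(path: str | Path, view: str, fps: float) -> TrackSeries:
    df = pd.read_csv(path)
    from .core import VIEW_AXES
    a1, a2 = VIEW_AXES[view]
    return TrackSeries(view, df["frame"].to_numpy(), df["time_s"].to_numpy(),
                       df[a1].to_numpy(float), df[a2].to_numpy(float), fps)


def write_intensity_csv(trace: IntensityTrace, path: str | Path) -> None:
    pd.DataFrame({"frame": trace.frame,
                  "intensity": trace.intensity}).to_csv(path, index=False)


def read_intensity_csv(path: str | Path) -> IntensityTrace:
    df = pd.read_csv(path)
    return IntensityTrace(df["frame"].to_numpy(), df["intensity"].to_numpy())


def write_trajectory_csv(traj: Trajectory3D, path: str | Path,
                         include_interpolated: bool = True) -> None:
    cols = {"frame": np.arange(traj.n_frames), "time_s": traj.time_s,
            "x": traj.xyz[:, 0], "y": traj.xyz[:, 1], "z": traj.xyz[:, 2],
            "phase": traj.phase}
    if include_interpolated:
        cols["interpolated"] = traj.interpolated.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, fps: float,
                        tank: tuple[float, float, float]) -> Trajectory3D:
    df = pd.read_csv(path)
    xyz = df[["x", "y", "z"]].to_numpy(float)
    interp = (df["interpolated"].to_numpy(bool)
              if "interpolated" in df.columns
              else np.zeros(len(df), dtype=bool))
    phase = df["phase"].fillna("").to_numpy(object) if "phase" in df.columns \
        else np.full(len(df), "", dtype=object)
    return Trajectory3D(df["time_s"].to_numpy(float), xyz, phase, interp,
                        fps, tank)
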