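"""Readers and writers for trajectory and fingerprint tables.

Trajectory tables follow the dialect of common tracking software: one row
per particle per frame with columns ``particle, frame, x, y`` (names
remappable).  Fingerprint tables carry one row per trajectory with the 20
feature columns plus labels.  Floats are written with 12 significant
digits so CSV round-trips are lossless well below 1e-9 um.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import FEATURE_NAMES, Trajectory, TrajectoryError

DEFAULT_COLUMNS = {"particle": "particle", "frame": "frame", "x": "x", "y": "y"}

FLOAT_FORMAT = "%.12g"


def read_trajectories(
    path,
    dt: float = 1.0,
    length_unit: float = 1.0,
    columns: Mapping[str, str] | None = None,
    allow_gaps: bool = False,
) -> list[Trajectory]:
    """Read a trajectory CSV into a list of :class:`Trajectory`.

    Parameters
    ----------
    path : CSV file with one row per particle per frame.
    dt : frame interval in seconds.
    length_unit : micrometers per input length unit (e.g. 0.001 for
        positions recorded in nanometers, or the pixel size in um for
        positions in pixels).
    columns : optional remapping {canonical: actual} for the column
        names ``particle``, ``frame``, ``x``, ``y``.
    allow_gaps : if False (strict mode, default), missing frame indices
        inside a trajectory raise; if True, frames are kept as given and
        treated as contiguous time points spaced ``dt`` apart.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise TrajectoryError(f"missing required column(s): {missing}")

    pcol, fcol = colmap["particle"], colmap["frame"]
    dup = df.duplicated(subset=[pcol, fcol], keep=False)
    if dup.any():
        offenders = (df.loc[dup, [pcol, fcol]].drop_duplicates()
                     .itertuples(index=False, name=None))
        raise TrajectoryError(
            "duplicate (particle, frame) rows: "
            + ", ".join(map(str, list(offenders)[:10])))

    trajectories = []
    for pid, grp in df.groupby(pcol, sort=True):
        grp = grp.sort_values(fcol)
        frames = grp[fcol].to_numpy(dtype=np.int64)
        if not allow_gaps and np.any(np.diff(frames) != 1):
            raise TrajectoryError(
                f"particle {pid}: non-contiguous frames (pass allow_gaps=True "
                "to treat frames as contiguous)")
        if allow_gaps:
            frames = np.arange(len(frames), dtype=np.int64)
        trajectories.append(Trajectory(
            particle_id=pid,
            frames=frames,
            x=grp[colmap["x"]].to_numpy(dtype=float) * length_unit,
            y=grp[colmap["y"]].to_numpy(dtype=float) * length_unit,
            dt=dt,
        ))
    return trajectories


def write_trajectories(trajectories: Iterable[Trajectory], path) -> None:
    """Write trajectories to CSV in the canonical particle/frame/x/y dialect."""
    frames = [
        pd.DataFrame({
            "particle": traj.particle_id,
            "frame": traj.frames,
            "x": traj.x,
            "y": traj.y,
        })
        for traj in trajectories
    ]
    if not frames:
        raise ValueError("refusing to write an empty trajectory collection")
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def write_fingerprints(table: pd.DataFrame, path) -> None:
    """Write a fingerprint table to CSV (lossless to float printing precision)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty fingerprint table")
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fingerprints(path) -> pd.DataFrame:
    """Read a fingerprint table written by :func:`write_fingerprints`."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"fingerprint table missing feature column(s): {missing}")
    return df
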