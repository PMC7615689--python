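"""Trajectory CSV readers/writers.

The interchange format is tidy long CSV, one row per frame:
``subject_id, group, trial, street, frame, x, y, vx, vy, key_h, key_v,
reset_flag``.  Positions are serialised with enough significant digits
for a lossless (bit-equal) round trip of double-precision states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .kinematics import Trajectory

__all__ = ["TrajectoryRecord", "write_trajectories", "read_trajectories"]

_COLUMNS = ["subject_id", "group", "trial", "street", "frame",
            "x", "y", "vx", "vy", "key_h", "key_v", "reset_flag"]


@dataclass(frozen=True)
class TrajectoryRecord:
    """A trajectory plus its experiment coordinates."""

    subject_id: int
    group: str
    trial: int
    street: int
    trajectory: Trajectory


def write_trajectories(records: Iterable[TrajectoryRecord], path: str | Path) -> None:
    """Write trajectories to CSV (positions at 17 significant digits)."""
    frames = []
    for rec in records:
        t = rec.trajectory
        frames.append(pd.DataFrame({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "trial": rec.trial,
            "street": rec.street,
            "frame": t.frames,
            "x": t.positions[:, 0], "y": t.positions[:, 1],
            "vx": t.velocities[:, 0], "vy": t.velocities[:, 1],
            "key_h": t.keys[:, 0].astype(int),
            "key_v": t.keys[:, 1].astype(int),
            "reset_flag": t.resets.astype(int),
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)[_COLUMNS]
    else:
        df = pd.DataFrame(columns=_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path: str | Path, strict: bool = False) -> list[TrajectoryRecord]:
    """Read trajectories written by :func:`write_trajectories`.

    Frames of each (subject, trial, street) must be strictly
    increasing; out-of-order rows are re-sorted with a warning, or
    raise :class:`~streetnav.errors.ParseError` when ``strict``.
    An empty file yields an empty list with a warning.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trajectory file", stacklevel=2)
        return []
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: empty trajectory file", stacklevel=2)
        return []
    for col in ("subject_id", "trial", "street", "frame"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"  # header is line 1
            raise ParseError(f"{path}: malformed value in {col!r} near line {line}") from exc

    records = []
    for (sid, group, trial, street), sub in df.groupby(
            ["subject_id", "group", "trial", "street"], sort=True):
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            if strict:
                raise ParseError(
                    f"{path}: frames out of order for subject {sid} "
                    f"trial {trial} street {street}")
            warnings.warn(
                f"{path}: re-sorting out-of-order frames (subject {sid}, "
                f"trial {trial}, street {street})", stacklevel=2)
            sub = sub.sort_values("frame")
        t = Trajectory(
            street=None,
            frames=sub["frame"].to_numpy(),
            positions=sub[["x", "y"]].to_numpy(),
            velocities=sub[["vx", "vy"]].to_numpy(),
            keys=sub[["key_h", "key_v"]].to_numpy().astype(bool),
            resets=sub["reset_flag"].to_numpy().astype(bool),
            outcome="completed",
            n_resets=int(sub["reset_flag"].sum()),
        )
        records.append(TrajectoryRecord(int(sid), str(group), int(trial), int(street), t))
    return records
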