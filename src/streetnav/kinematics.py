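"""Frame-based two-key cursor control law.

Each of the two keys accelerates the cursor along one screen axis by a
fixed amount per display frame while held, and the velocity decays at
the same rate when released; per-axis speed is capped.  If the cursor
leaves the corridor (distance to the centreline exceeds half the street
width) it is reset to the street start; a street is complete when the
cursor's arc-length position enters the final fraction of the street
(the end zone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import InvalidParameterError
from .geometry import Street

__all__ = [
    "KinematicsConfig",
    "CursorState",
    "Trajectory",
    "StreetRun",
    "step",
    "advance_street",
    "run_street_scored",
]


@dataclass(frozen=True)
class KinematicsConfig:
    """Control-law constants (height units and display frames).

    Defaults follow the paradigm: acceleration 0.001 height units per
    frame while a key is held (and symmetric deceleration on release),
    a 0.3 height-unit velocity cap, a 60 Hz frame rate, and an end zone
    spanning the last 5% of street length.
    """

    accel_per_frame: float = 0.001
    max_velocity: float = 0.3
    frame_rate: float = 60.0
    end_zone_fraction: float = 0.05
    frame_cap: int = 3600  # 60 s per street; guarantees termination

    def __post_init__(self) -> None:
        if min(self.accel_per_frame, self.max_velocity, self.frame_rate) <= 0:
            raise InvalidParameterError("kinematics constants must be positive")
        if not 0.0 < self.end_zone_fraction < 1.0:
            raise InvalidParameterError("end_zone_fraction must lie in (0, 1)")
        if self.frame_cap <= 0:
            raise InvalidParameterError("frame_cap must be positive")


@dataclass(frozen=True, slots=True)
class CursorState:
    """Cursor position, per-axis speed (always >= 0) and frame counter."""

    x: float
    y: float
    vx: float
    vy: float
    frame: int


def step(
    state: CursorState,
    keys: tuple[bool, bool],
    config: KinematicsConfig,
    directions: tuple[int, int] = (1, 1),
) -> CursorState:
    """Advance the control law by one frame.

    Per axis: speed grows by the acceleration constant while the key is
    held and shrinks by the same amount when released, clamped to
    [0, max_velocity]; the position then moves by the speed along the
    signed axis direction.
    """
    a, vmax = config.accel_per_frame, config.max_velocity
    vx = state.vx + a if keys[0] else state.vx - a
    vy = state.vy + a if keys[1] else state.vy - a
    vx = 0.0 if vx < 0.0 else (vmax if vx > vmax else vx)
    vy = 0.0 if vy < 0.0 else (vmax if vy > vmax else vy)
    return CursorState(
        state.x + vx * directions[0],
        state.y + vy * directions[1],
        vx,
        vy,
        state.frame + 1,
    )


@dataclass
class Trajectory:
    """Per-frame record of one street attempt (including failed attempts)."""

    street: Street
    frames: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    keys: np.ndarray
    resets: np.ndarray
    outcome: str  # "completed" | "aborted"
    n_resets: int

    @property
    def completed(self) -> bool:
        return self.outcome == "completed"

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class StreetRun:
    """Scored summary of one street attempt (no per-frame storage)."""

    outcome: str
    n_resets: int
    n_frames: int
    movement_time: float | None  # seconds, onset to completion
    rms_error: float | None      # height units

    @property
    def completed(self) -> bool:
        return self.outcome == "completed"


Policy = Callable[[CursorState], tuple[bool, bool]]


def _loop(policy, street, config, directions, record):
    tracker = street.tracker()
    half_width = street.width / 2.0
    goal = (1.0 - config.end_zone_fraction) * tracker.length
    sx, sy = street.start
    state = CursorState(sx, sy, 0.0, 0.0, 0)
    start_dist = tracker.locate(sx, sy)[1]

    frames, pos, vel, keys_rec, resets = [], [], [], [], []
    onset = None
    n_resets = 0
    outcome = "aborted"
    end_frame = None
    sumsq = 0.0
    n_scored = 0

    for _ in range(config.frame_cap):
        keys = policy(state)
        state = step(state, keys, config, directions)
        if onset is None and (state.vx > 0.0 or state.vy > 0.0):
            onset = state.frame
        s, dist = tracker.locate(state.x, state.y)
        reset = dist > half_width
        if reset:
            n_resets += 1
            state = CursorState(sx, sy, 0.0, 0.0, state.frame)
            tracker.reset_hint()
            dist = start_dist
        if record:
            frames.append(state.frame)
            pos.append((state.x, state.y))
            vel.append((state.vx, state.vy))
            keys_rec.append(keys)
            resets.append(reset)
        if onset is not None and state.frame >= onset:
            sumsq += dist * dist
            n_scored += 1
        if not reset and s >= goal:
            outcome = "completed"
            end_frame = state.frame
            break

    mt = rms = None
    if outcome == "completed" and onset is not None:
        mt = (end_frame - onset) / config.frame_rate
        rms = (sumsq / n_scored) ** 0.5
    run = StreetRun(outcome, n_resets, state.frame, mt, rms)
    if not record:
        return run, None
    traj = Trajectory(
        street=street,
        frames=np.asarray(frames, dtype=int),
        positions=np.asarray(pos, dtype=float),
        velocities=np.asarray(vel, dtype=float),
        keys=np.asarray(keys_rec, dtype=bool),
        resets=np.asarray(resets, dtype=bool),
        outcome=outcome,
        n_resets=n_resets,
    )
    return run, traj


def advance_street(
    policy: Policy,
    street: Street,
    config: KinematicsConfig | None = None,
    directions: tuple[int, int] = (1, 1),
) -> Trajectory:
    """Run a control policy on one street, recording every frame.

    The policy is called once per frame with the current
    :class:`CursorState` and returns the pair of key states.  The
    trajectory terminates on street completion or at the frame cap
    (outcome ``"aborted"``; never an exception).
    """
    config = config or KinematicsConfig()
    _, traj = _loop(policy, street, config, directions, record=True)
    return traj


def run_street_scored(
    policy: Policy,
    street: Street,
    config: KinematicsConfig | None = None,
    directions: tuple[int, int] = (1, 1),
) -> StreetRun:
    """Like :func:`advance_street` but accumulates scores on the fly.

    Returns movement time (onset to completion, seconds) and the RMS
    distance to the ideal line over the movement epoch, including the
    frames of failed attempts before resets.  Used by the cohort
    pipeline where storing per-frame records would be wasteful.
    """
    config = config or KinematicsConfig()
    run, _ = _loop(policy, street, config, directions, record=False)
    return run
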