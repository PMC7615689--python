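"""Dependent variables: movement time, RMS error, performance index.

Per street, movement time is the time from cursor-movement onset to
street completion and error is the root-mean-square distance between
the cursor and the ideal line, sampled at the display frame rate and
including the frames of failed attempts before corridor resets.
Per trial, both are averaged over the six streets.  The performance
index combines them against pilot-calibrated constants:

    Pe = a / error,   Pm = movement_time / b,   PI = Pm * Pe

where ``a`` (constant error) and ``b`` (constant movement time) are the
pilot-sample means.  ``pm_inverted=True`` switches to Pm = b / mt so
that faster *and* more accurate both increase PI; the default keeps the
printed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError, NotScorableError, UndefinedPIError
from .geometry import Street
from .kinematics import KinematicsConfig, Trajectory

__all__ = [
    "NormalizationConstants",
    "StreetScore",
    "TrialScore",
    "movement_time",
    "street_error",
    "score_street",
    "calibrate_constants",
    "performance_index",
    "trial_score",
]


@dataclass(frozen=True)
class NormalizationConstants:
    """Pilot-calibrated constants: a = constant error, b = constant time."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise InvalidParameterError("normalisation constants must be positive")


@dataclass(frozen=True)
class StreetScore:
    movement_time: float  # seconds
    error: float          # height units, RMS

    def __post_init__(self) -> None:
        if self.movement_time < 0 or self.error < 0:
            raise InvalidParameterError("street scores must be >= 0")


@dataclass(frozen=True)
class TrialScore:
    trial_index: int
    movement_time: float  # mean over the trial's streets, seconds
    error: float          # mean over the trial's streets, height units
    pe: float
    pm: float
    pi: float


def _onset_index(trajectory: Trajectory) -> int:
    moving = (trajectory.velocities[:, 0] > 0) | (trajectory.velocities[:, 1] > 0)
    idx = np.flatnonzero(moving)
    if idx.size == 0:
        raise NotScorableError("cursor never moved")
    return int(idx[0])


def movement_time(trajectory: Trajectory, config: KinematicsConfig | None = None) -> float:
    """Seconds from movement onset to street completion."""
    config = config or KinematicsConfig()
    if not trajectory.completed:
        raise NotScorableError("cannot score an aborted trajectory")
    i = _onset_index(trajectory)
    return float(trajectory.frames[-1] - trajectory.frames[i]) / config.frame_rate


def street_error(trajectory: Trajectory, street: Street | None = None) -> float:
    """RMS distance to the ideal line over the movement epoch.

    All frames from onset to completion contribute, including the
    frames of failed attempts before resets (a wall hit must not be
    error-free).
    """
    if not trajectory.completed:
        raise NotScorableError("cannot score an aborted trajectory")
    street = street if street is not None else trajectory.street
    i = _onset_index(trajectory)
    d = street.distances_to(trajectory.positions[i:])
    return float(np.sqrt(np.mean(d * d)))


def score_street(trajectory: Trajectory, config: KinematicsConfig | None = None) -> StreetScore:
    return StreetScore(movement_time(trajectory, config), street_error(trajectory))


def calibrate_constants(pilot_scores: Iterable[StreetScore]) -> NormalizationConstants:
    """Average a pilot sample's error and movement time into (a, b)."""
    scores = list(pilot_scores)
    if not scores:
        raise InvalidParameterError("pilot score set is empty")
    a = float(np.mean([s.error for s in scores]))
    b = float(np.mean([s.movement_time for s in scores]))
    return NormalizationConstants(a=a, b=b)


def performance_index(
    mt: float,
    error: float,
    constants: NormalizationConstants,
    pm_inverted: bool = False,
) -> float:
    """PI = Pm * Pe from trial-level movement time and error."""
    if mt <= 0 or error <= 0:
        raise UndefinedPIError("PI undefined for zero movement time or error")
    pe = constants.a / error
    pm = constants.b / mt if pm_inverted else mt / constants.b
    return pm * pe


def trial_score(
    trial_index: int,
    street_scores: Sequence[StreetScore],
    constants: NormalizationConstants,
    pm_inverted: bool = False,
) -> TrialScore:
    """Aggregate street scores into one trial score.

    Movement time and error are street means; PI is computed from the
    trial-level (street-averaged) values, not averaged from per-street
    PIs.
    """
    if not street_scores:
        raise InvalidParameterError("trial has no street scores")
    mt = float(np.mean([s.movement_time for s in street_scores]))
    err = float(np.mean([s.error for s in street_scores]))
    if mt <= 0 or err <= 0:
        raise UndefinedPIError("PI undefined for zero movement time or error")
    pe = constants.a / err
    pm = constants.b / mt if pm_inverted else mt / constants.b
    return TrialScore(trial_index, mt, err, pe, pm, pm * pe)
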