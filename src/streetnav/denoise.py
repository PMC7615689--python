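"""Trial-difficulty denoising of training-task dependent variables.

Street angles differ systematically in bimanual demand, so some trials
are harder than others by construction of the pseudo-random schedule.
To avoid confounding learning-related change with trial difficulty,
street difficulty is quantified as the grand mean of the dependent
variable per street angle (within and across subjects, per training
task), trial difficulty as the mean street difficulty of the trial's
six streets, and the difficulty-attributable component of the
group-level trial series — the mean-centred fitted values of an OLS
regression of group performance on trial difficulty — is subtracted
from every subject's series.  Only a common per-trial offset is
removed: no data are lost and between-subject variance at each trial
is preserved exactly.

A strict-literal mode (``mode="residual"``) subtracts the regression's
raw residuals instead; it is provided for comparison but removes the
learning-related component along with difficulty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingAngleError

__all__ = [
    "DifficultyProfile",
    "street_difficulty_profile",
    "trial_difficulty",
    "denoise_trials",
    "DenoiseResult",
]


@dataclass(frozen=True)
class DifficultyProfile:
    """Per-angle grand mean of one dependent variable for one task."""

    task: str
    variable: str
    means: pd.Series  # indexed by angle

    def __getitem__(self, angle: float) -> float:
        return float(self.means.loc[angle])


def street_difficulty_profile(
    street_scores: pd.DataFrame,
    variable: str,
    task: str = "",
    angle_col: str = "angle",
    grid: Sequence[float] | None = None,
) -> DifficultyProfile:
    """Average ``variable`` per street angle over all street occurrences.

    ``street_scores`` is a long table with one row per street attempt
    (within and across subjects of one training task).  If ``grid`` is
    given, every grid angle must be observed.
    """
    if street_scores.empty:
        raise InvalidParameterError("no street scores provided")
    means = street_scores.groupby(angle_col)[variable].mean().sort_index()
    if grid is not None:
        missing = sorted(set(np.round(grid, 9)) - set(np.round(means.index, 9)))
        if missing:
            raise MissingAngleError(f"angles never observed: {missing}")
    if not np.isfinite(means.to_numpy()).all():
        raise InvalidParameterError("difficulty profile contains non-finite values")
    return DifficultyProfile(task=task, variable=variable, means=means)


def trial_difficulty(
    trial_angles: np.ndarray,
    profile: DifficultyProfile,
) -> np.ndarray:
    """Mean street difficulty per trial.

    ``trial_angles`` has shape (n_trials, streets_per_trial).
    """
    angles = np.asarray(trial_angles, dtype=float)
    lut = profile.means
    flat = lut.reindex(np.round(angles.ravel(), 9)).to_numpy()
    if np.isnan(flat).any():
        raise MissingAngleError("trial contains an angle missing from the profile")
    return flat.reshape(angles.shape).mean(axis=1)


@dataclass(frozen=True)
class DenoiseResult:
    values: np.ndarray        # denoised (n_subjects, n_trials)
    slope: float
    intercept: float
    removed: np.ndarray       # per-trial component that was subtracted
    degenerate: bool = False


def denoise_trials(
    subject_values: np.ndarray,
    difficulty: np.ndarray,
    mode: str = "fitted",
) -> DenoiseResult:
    """Remove the difficulty-attributable component from trial series.

    Parameters
    ----------
    subject_values : ndarray, shape (n_subjects, n_trials)
        Per-subject, per-trial dependent variable (movement time or
        error) for one training task.
    difficulty : ndarray, shape (n_trials,)
        Trial difficulties from :func:`trial_difficulty`.
    mode : {"fitted", "residual"}
        "fitted" (default) subtracts the mean-centred fitted values of
        the group-mean-on-difficulty regression; "residual" subtracts
        the raw residuals (strict-literal reading, removes learning).

    With constant difficulty the input is returned unchanged with a
    warning.  Denoising is idempotent: the denoised group means are
    exactly orthogonal to difficulty, so a second pass removes nothing.
    """
    y = np.asarray(subject_values, dtype=float)
    x = np.asarray(difficulty, dtype=float)
    if y.ndim != 2 or y.shape[1] != x.size:
        raise InvalidParameterError("subject_values must be (n_subjects, n_trials)")
    if x.size < 3:
        raise InvalidParameterError("need at least 3 trials")
    if mode not in ("fitted", "residual"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    group = y.mean(axis=0)
    if np.ptp(x) == 0.0:
        warnings.warn("constant trial difficulty: nothing to remove", stacklevel=2)
        return DenoiseResult(y.copy(), 0.0, float(group.mean()), np.zeros_like(x), True)
    xc = x - x.mean()
    slope = float(xc @ (group - group.mean()) / (xc @ xc))
    intercept = float(group.mean() - slope * x.mean())
    if mode == "fitted":
        removed = slope * xc                     # mean-centred fitted component
    else:
        removed = group - (slope * x + intercept)  # raw residuals
    return DenoiseResult(y - removed[None, :], slope, intercept, removed, False)
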