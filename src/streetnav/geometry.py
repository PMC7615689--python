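"""Street geometry, transfer transpositions and trial scheduling.

The task is a cursor-navigation game: each *street* is a corridor the
cursor must traverse.  Training streets are straight, angled between 0°
(horizontal, one hand) and 90° (vertical, the other hand); intermediate
angles require coordinated two-hand input.  Transfer streets are curved.
A *trial* is a path of six consecutive streets; a training session is
100 trials whose street order is pseudo-randomised under a balance
constraint (every street repeated equally often) and a carry-over
constraint (consecutive streets differ by at least 22.5°).

Coordinates are resolution independent "height units" (1.0 = height of
the task window).  Centrelines are stored in *window-centred*
coordinates (origin at the centre of the task window) so that the
transfer-task reflections are exact sign flips; use
:func:`to_window_coords` to convert to a bottom-left origin for export.
"""

from __future__ import annotations

import json
import math
import random
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .errors import InvalidParameterError, SchedulingInfeasibleError

__all__ = [
    "DEFAULT_STREET_WIDTH",
    "DEFAULT_STREET_LENGTH",
    "TRAINING_DELTAS",
    "TRAINING_TASKS",
    "TRANSFER_VARIANTS",
    "StraightStreet",
    "CurvedStreet",
    "TrainingTaskSpec",
    "TransferVariant",
    "Trial",
    "SpacingSummary",
    "build_training_angles",
    "neighbour_spacing_summary",
    "training_task_spec",
    "schedule_angles",
    "schedule_training_session",
    "build_transfer_streets",
    "point_to_ideal_distance",
    "to_window_coords",
    "schedule_to_table",
    "schedule_to_json",
]

# Street width/length are not design constants of the paradigm itself;
# these defaults give Figure-1-like corridors with a nonzero error range.
DEFAULT_STREET_WIDTH = 0.06
DEFAULT_STREET_LENGTH = 0.5

#: Minimum angular difference Δ between the streets of each training task.
TRAINING_DELTAS = {
    "Train-I": 22.5,
    "Train-II": 18.0,
    "Train-III": 11.25,
    "Train-IV": 6.425,
    "Train-V": 2.0,
}
TRAINING_TASKS = tuple(TRAINING_DELTAS)

_DEG = math.pi / 180.0


# ---------------------------------------------------------------------------
# streets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StraightStreet:
    """A straight corridor defined by its angle in the movement frame.

    The ideal line runs from ``start`` to
    ``start + length * (cos(angle), sin(angle))``.
    """

    angle: float
    length: float = DEFAULT_STREET_LENGTH
    width: float = DEFAULT_STREET_WIDTH
    start: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle <= 90.0:
            raise InvalidParameterError(f"street angle must lie in [0, 90], got {self.angle}")
        if self.length <= 0 or self.width <= 0:
            raise InvalidParameterError("street length and width must be positive")

    @property
    def end(self) -> tuple[float, float]:
        c, s = math.cos(self.angle * _DEG), math.sin(self.angle * _DEG)
        return (self.start[0] + self.length * c, self.start[1] + self.length * s)

    def tracker(self) -> "_StraightTracker":
        return _StraightTracker(self)

    def distances_to(self, points: np.ndarray) -> np.ndarray:
        """Vectorised Heron distance from ``points`` (n, 2) to the ideal line."""
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        a = np.asarray(self.start)
        b = np.asarray(self.end)
        return _heron_distance_vec(p, a, b)


@dataclass(frozen=True)
class CurvedStreet:
    """A curved corridor defined by a polyline centreline.

    ``centreline`` is an ``(n, 2)`` array in window-centred height units,
    ordered along arc length with strictly positive segment lengths.
    """

    centreline: np.ndarray
    width: float = DEFAULT_STREET_WIDTH
    variant_id: int = 1

    def __post_init__(self) -> None:
        cl = np.asarray(self.centreline, dtype=float)
        if cl.ndim != 2 or cl.shape[0] < 2 or cl.shape[1] != 2:
            raise InvalidParameterError("centreline must be an (n>=2, 2) array")
        seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
        if np.any(seg <= 0):
            raise InvalidParameterError("centreline segments must have positive length")
        if self.width <= 0:
            raise InvalidParameterError("street width must be positive")
        object.__setattr__(self, "centreline", cl)
        object.__setattr__(self, "_cumlen", np.concatenate(([0.0], np.cumsum(seg))))

    @property
    def length(self) -> float:
        return float(self._cumlen[-1])

    @property
    def start(self) -> tuple[float, float]:
        return (float(self.centreline[0, 0]), float(self.centreline[0, 1]))

    def resampled(self, step: float = 0.002) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length resampling of the centreline at spacing ``step``.

        Returns ``(points, arc_positions)``; cached per street and step.
        """
        cache = self.__dict__.setdefault("_resample_cache", {})
        if step not in cache:
            n = max(int(math.ceil(self.length / step)) + 1, 2)
            s = np.linspace(0.0, self.length, n)
            x = np.interp(s, self._cumlen, self.centreline[:, 0])
            y = np.interp(s, self._cumlen, self.centreline[:, 1])
            cache[step] = (np.column_stack([x, y]), s)
        return cache[step]

    def point_at(self, s: float) -> tuple[float, float]:
        s = min(max(s, 0.0), self.length)
        x = float(np.interp(s, self._cumlen, self.centreline[:, 0]))
        y = float(np.interp(s, self._cumlen, self.centreline[:, 1]))
        return (x, y)

    def tracker(self, step: float = 0.002) -> "_CurvedTracker":
        return _CurvedTracker(self, step)

    def distances_to(self, points: np.ndarray, step: float = 0.002) -> np.ndarray:
        """Nearest-neighbour distance of ``points`` (n, 2) to the centreline."""
        dense, _ = self.resampled(step)
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        d2 = ((p[:, None, :] - dense[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(d2.min(axis=1))

    def reflected(self, flip_vertical: bool, flip_horizontal: bool) -> "CurvedStreet":
        """Mirror the centreline about the window axes (exact sign flips)."""
        cl = self.centreline.copy()
        if flip_vertical:
            cl[:, 0] = -cl[:, 0]
        if flip_horizontal:
            cl[:, 1] = -cl[:, 1]
        return CurvedStreet(cl, self.width, self.variant_id)


Street = Union[StraightStreet, CurvedStreet]


class _StraightTracker:
    """Closed-form arc projection / lateral distance for a straight street."""

    __slots__ = ("x0", "y0", "c", "s", "length")

    def __init__(self, street: StraightStreet):
        self.x0, self.y0 = street.start
        self.c = math.cos(street.angle * _DEG)
        self.s = math.sin(street.angle * _DEG)
        self.length = street.length

    def locate(self, x: float, y: float) -> tuple[float, float]:
        dx, dy = x - self.x0, y - self.y0
        along = dx * self.c + dy * self.s
        lateral = abs(-dx * self.s + dy * self.c)
        if along < 0.0:
            along = 0.0
        elif along > self.length:
            along = self.length
        return along, lateral

    def point_at(self, s: float) -> tuple[float, float]:
        s = min(max(s, 0.0), self.length)
        return (self.x0 + s * self.c, self.y0 + s * self.s)

    def reset_hint(self) -> None:  # symmetry with _CurvedTracker
        pass


class _CurvedTracker:
    """Incremental nearest-neighbour tracking along a resampled centreline.

    Keeps the index of the last nearest sample as a search hint; the
    cursor advances a few samples per frame, so a bounded local search
    (expanded whenever the minimum sits on the window edge) finds the
    global nearest point for corridor-shaped queries.
    """

    __slots__ = ("xs", "ys", "arc", "n", "length", "_hint")

    def __init__(self, street: CurvedStreet, step: float = 0.002):
        dense, s = street.resampled(step)
        self.xs = dense[:, 0].tolist()
        self.ys = dense[:, 1].tolist()
        self.arc = s.tolist()
        self.n = len(self.arc)
        self.length = street.length
        self._hint = 0

    def locate(self, x: float, y: float) -> tuple[float, float]:
        xs, ys = self.xs, self.ys
        lo = max(self._hint - 12, 0)
        hi = min(self._hint + 40, self.n)
        while True:
            best_j = lo
            best = (xs[lo] - x) ** 2 + (ys[lo] - y) ** 2
            for j in range(lo + 1, hi):
                d2 = (xs[j] - x) ** 2 + (ys[j] - y) ** 2
                if d2 < best:
                    best = d2
                    best_j = j
            grown = False
            if best_j == lo and lo > 0:
                lo = max(lo - 40, 0)
                grown = True
            if best_j == hi - 1 and hi < self.n:
                hi = min(hi + 40, self.n)
                grown = True
            if not grown:
                break
        self._hint = best_j
        return self.arc[best_j], math.sqrt(best)

    def point_at(self, s: float) -> tuple[float, float]:
        if s <= 0.0:
            return self.xs[0], self.ys[0]
        if s >= self.length:
            return self.xs[-1], self.ys[-1]
        j = bisect_right(self.arc, s)
        s0, s1 = self.arc[j - 1], self.arc[j]
        w = (s - s0) / (s1 - s0)
        return (
            self.xs[j - 1] * (1 - w) + self.xs[j] * w,
            self.ys[j - 1] * (1 - w) + self.ys[j] * w,
        )

    def reset_hint(self) -> None:
        self._hint = 0


# ---------------------------------------------------------------------------
# training angle grids
# ---------------------------------------------------------------------------

def build_training_angles(min_angular_difference: float) -> list[float]:
    """Arithmetic grid of street angles from 0° to 90° for a spacing Δ.

    The grid always contains 0 and 90 and uses the spacing closest to Δ
    that divides 90 evenly: ``round(90/Δ) + 1`` angles at spacing
    ``90 / round(90/Δ)``.  Δ = 22.5 gives the five angles
    {0, 22.5, 45, 67.5, 90}; Δ = 2 gives 46 angles.

    Parameters
    ----------
    min_angular_difference : float
        Nominal minimum angular difference Δ in degrees, 0 < Δ <= 90.
    """
    delta = float(min_angular_difference)
    if not 0.0 < delta <= 90.0:
        raise InvalidParameterError(f"Δ must lie in (0, 90], got {delta}")
    k = max(int(round(90.0 / delta)), 1)
    return list(np.linspace(0.0, 90.0, k + 1))


@dataclass(frozen=True)
class SpacingSummary:
    mean: float
    se: float
    n_gaps: int

    def __iter__(self):
        return iter((self.mean, self.se))


def neighbour_spacing_summary(deltas: Sequence[float]) -> SpacingSummary:
    """Mean and standard error of successive Δ differences across tasks.

    For the five task spacings (22.5, 18, 11.25, 6.425, 2) the gaps
    between neighbouring tasks average 5.13° with SE 0.55°, i.e. the
    task set spans low-to-high variability on an approximately linear
    scale.  With a single gap the SE is undefined and returned as 0
    with a warning.
    """
    d = np.asarray(list(deltas), dtype=float)
    if d.size < 2:
        raise InvalidParameterError("need at least two Δ values")
    if np.any(np.diff(d) > 0):
        raise InvalidParameterError("Δ values must be sorted descending")
    gaps = -np.diff(d)
    mean = float(gaps.mean())
    if gaps.size == 1:
        warnings.warn("single gap: standard error undefined, returning 0", stacklevel=2)
        return SpacingSummary(mean, 0.0, 1)
    se = float(gaps.std(ddof=1) / math.sqrt(gaps.size))
    return SpacingSummary(mean, se, int(gaps.size))


# ---------------------------------------------------------------------------
# task specs and scheduling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingTaskSpec:
    """One of the five training tasks (street set plus session layout)."""

    name: str
    min_angular_difference: float
    angles: tuple[float, ...] = ()
    n_trials: int = 100
    streets_per_trial: int = 6
    min_consecutive_difference: float = 22.5

    def __post_init__(self) -> None:
        if not self.angles:
            object.__setattr__(
                self, "angles", tuple(build_training_angles(self.min_angular_difference))
            )
        a = np.asarray(self.angles)
        if a[0] != 0.0 or a[-1] != 90.0:
            raise InvalidParameterError("angle grid must span 0..90 inclusive")
        if np.any(np.diff(a) <= 0):
            raise InvalidParameterError("angles must be strictly ascending")
        if self.n_trials <= 0 or self.streets_per_trial <= 0:
            raise InvalidParameterError("trial counts must be positive")

    @property
    def n_streets(self) -> int:
        return len(self.angles)


def training_task_spec(name: str, **overrides) -> TrainingTaskSpec:
    """Standard spec for one of Train-I .. Train-V."""
    if name not in TRAINING_DELTAS:
        raise InvalidParameterError(f"unknown training task {name!r}")
    return TrainingTaskSpec(name=name, min_angular_difference=TRAINING_DELTAS[name], **overrides)


@dataclass(frozen=True)
class Trial:
    """One path: an ordered sequence of six streets."""

    index: int
    streets: tuple[Street, ...]


@dataclass(frozen=True)
class TransferVariant:
    """Transfer-task transposition: which window axes are mirrored.

    S keeps the trained mapping (cursor moves right/up); M transposes
    one direction (left/up, vertical-axis mirror); L transposes both
    (left/down, both axes mirrored).
    """

    name: str
    flip_vertical: bool
    flip_horizontal: bool
    movement_directions: tuple[int, int]

    @property
    def n_flips(self) -> int:
        return int(self.flip_vertical) + int(self.flip_horizontal)


TRANSFER_VARIANTS = {
    "S": TransferVariant("S", False, False, (1, 1)),
    "M": TransferVariant("M", True, False, (-1, 1)),
    "L": TransferVariant("L", True, True, (-1, -1)),
}


def schedule_angles(
    spec: TrainingTaskSpec,
    seed: int,
    max_restarts: int = 10_000,
) -> np.ndarray:
    """Pseudo-randomised street-angle sequence for one training session.

    Every angle of the task's grid is repeated equally often (counts
    differ by at most one when the 600 street slots do not divide
    evenly) and consecutive streets — including across trial
    boundaries — differ by at least ``spec.min_consecutive_difference``.
    Built by seeded sequential sampling with restarts on dead ends.
    """
    angles = list(spec.angles)
    total = spec.n_trials * spec.streets_per_trial
    min_diff = spec.min_consecutive_difference - 1e-9
    if total > 1 and not any(
        abs(a - b) >= min_diff for i, a in enumerate(angles) for b in angles[i + 1:]
    ):
        raise SchedulingInfeasibleError(
            f"no two angles of {spec.name} are >= {spec.min_consecutive_difference}° apart"
        )
    rng = random.Random(seed)

    def _round(pool: list[float], prev: float | None) -> list[float] | None:
        # one constrained random ordering of `pool`; None on a dead end
        remaining = list(pool)
        out: list[float] = []
        for _ in range(len(pool)):
            feas = [a for a in remaining if prev is None or abs(a - prev) >= min_diff]
            if not feas:
                return None
            a = rng.choice(feas)
            remaining.remove(a)
            out.append(a)
            prev = a
        return out

    # maximally balanced multiset: full copies of the grid plus a partial
    # round of the leftover slots; each round is a constrained permutation.
    # The finished sequence is rotated by a random offset so that round
    # boundaries do not align with trial boundaries (otherwise tasks whose
    # grid size equals the trial length would get identical trial
    # compositions); the rotation requires the ends to satisfy the
    # constraint too, checked below.
    n_full, extra = divmod(total, len(angles))
    for _ in range(max_restarts):
        rounds = [list(angles) for _ in range(n_full)]
        if extra:
            rounds.append(rng.sample(angles, extra))
        seq: list[float] = []
        prev = None
        ok = True
        for pool in rounds:
            for _attempt in range(200):
                perm = _round(pool, prev)
                if perm is not None:
                    break
            else:
                ok = False
                break
            seq.extend(perm)
            prev = perm[-1]
        if ok and (total < 2 or abs(seq[-1] - seq[0]) >= min_diff):
            k = rng.randrange(total)
            return np.asarray(seq[k:] + seq[:k])
    raise SchedulingInfeasibleError(
        f"could not schedule {spec.name} within {max_restarts} restarts"
    )


def schedule_training_session(
    spec: TrainingTaskSpec,
    seed: int,
    width: float = DEFAULT_STREET_WIDTH,
    length: float = DEFAULT_STREET_LENGTH,
) -> list[Trial]:
    """Full training session: ``spec.n_trials`` trials of six streets each."""
    seq = schedule_angles(spec, seed)
    trials = []
    for t in range(spec.n_trials):
        chunk = seq[t * spec.streets_per_trial:(t + 1) * spec.streets_per_trial]
        streets = tuple(StraightStreet(float(a), length=length, width=width) for a in chunk)
        trials.append(Trial(index=t + 1, streets=streets))
    return trials


# ---------------------------------------------------------------------------
# transfer streets
# ---------------------------------------------------------------------------

# Fixed family of six slightly different smooth curves: a diagonal chord
# plus two low-frequency sinusoidal deflections, zero at both endpoints.
# (A1, f1, phi1, A2, f2, phi2) per curve; coordinates window-centred.
_CURVE_PARAMS = (
    (0.085, 1.0, 0.00, 0.030, 2.0, 1.15),
    (0.075, 1.0, 0.55, 0.042, 2.0, 2.60),
    (0.095, 1.0, 1.10, 0.026, 2.0, 0.35),
    (0.070, 1.0, 1.70, 0.048, 2.0, 4.20),
    (0.090, 1.0, 2.30, 0.034, 2.0, 5.10),
    (0.080, 1.0, 2.90, 0.040, 2.0, 3.45),
)
_CHORD_START = (0.15, 0.10)   # fractional window coordinates (bottom-left origin)
_CHORD_END = (0.85, 0.90)


def _base_curve(variant_id: int, window_aspect: float, n_points: int) -> np.ndarray:
    a1, f1, p1, a2, f2, p2 = _CURVE_PARAMS[variant_id - 1]
    t = np.linspace(0.0, 1.0, n_points)
    x0 = (_CHORD_START[0] - 0.5) * window_aspect
    y0 = _CHORD_START[1] - 0.5
    x1 = (_CHORD_END[0] - 0.5) * window_aspect
    y1 = _CHORD_END[1] - 0.5
    cx = x0 + t * (x1 - x0)
    cy = y0 + t * (y1 - y0)
    chord = math.hypot(x1 - x0, y1 - y0)
    nx, ny = -(y1 - y0) / chord, (x1 - x0) / chord  # unit normal to the chord
    d = np.sin(math.pi * t) * (
        a1 * np.sin(2 * math.pi * f1 * t + p1) + a2 * np.sin(2 * math.pi * f2 * t + p2)
    )
    return np.column_stack([cx + d * nx, cy + d * ny])


def build_transfer_streets(
    variant: TransferVariant | str,
    width: float = DEFAULT_STREET_WIDTH,
    window_aspect: float = 1.0,
    n_points: int = 201,
) -> list[CurvedStreet]:
    """The six curved streets of one transfer variant.

    The S streets define the family; M mirrors them about the vertical
    window axis and L about both axes, so the three variants share
    identical shapes and arc lengths and differ only in the required
    movement directions.
    """
    if isinstance(variant, str):
        variant = TRANSFER_VARIANTS[variant]
    streets = []
    for k in range(1, 7):
        base = CurvedStreet(_base_curve(k, window_aspect, n_points), width=width, variant_id=k)
        streets.append(base.reflected(variant.flip_vertical, variant.flip_horizontal))
    return streets


def transfer_trial(variant: TransferVariant | str, index: int, seed: int, **kwargs) -> Trial:
    """One transfer trial: the six curves of ``variant`` in seeded order."""
    streets = build_transfer_streets(variant, **kwargs)
    rng = random.Random(seed)
    order = list(range(6))
    rng.shuffle(order)
    return Trial(index=index, streets=tuple(streets[i] for i in order))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _heron_distance_vec(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    la = float(np.linalg.norm(b - a))
    if la <= 0:
        raise InvalidParameterError("degenerate street: zero-length ideal line")
    lb = np.linalg.norm(p - a, axis=1)
    lc = np.linalg.norm(p - b, axis=1)
    s = (la + lb + lc) / 2.0
    area_sq = np.clip(s * (s - la) * (s - lb) * (s - lc), 0.0, None)
    return 2.0 * np.sqrt(area_sq) / la


def point_to_ideal_distance(
    point: Sequence[float],
    street: Street,
    resample_step: float = 0.002,
) -> float:
    """Distance from a cursor position to the street's ideal line.

    Straight streets use the triangle-area (Heron) construction over
    (line start, line end, point); curved streets use the nearest
    neighbour on a densely resampled centreline.
    """
    if isinstance(street, StraightStreet):
        p = np.asarray(point, dtype=float).reshape(1, 2)
        return float(_heron_distance_vec(p, np.asarray(street.start), np.asarray(street.end))[0])
    return float(street.distances_to(np.asarray(point), step=resample_step)[0])


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------

def to_window_coords(points: np.ndarray, window_aspect: float = 1.0) -> np.ndarray:
    """Convert window-centred coordinates to bottom-left-origin coordinates."""
    p = np.asarray(points, dtype=float).copy()
    p[..., 0] += window_aspect / 2.0
    p[..., 1] += 0.5
    return p


def schedule_to_table(trials: Sequence[Trial]):
    """Long-format table (trial, street, angle-or-curve id) of a schedule."""
    import pandas as pd

    rows = []
    for trial in trials:
        for j, street in enumerate(trial.streets, start=1):
            if isinstance(street, StraightStreet):
                rows.append((trial.index, j, street.angle, None))
            else:
                rows.append((trial.index, j, None, street.variant_id))
    return pd.DataFrame(rows, columns=["trial", "street", "angle", "curve_id"])


def schedule_to_json(trials: Sequence[Trial], spec: TrainingTaskSpec, seed: int) -> str:
    """JSON document describing a scheduled session (angles only)."""
    payload = {
        "task": spec.name,
        "min_angular_difference": spec.min_angular_difference,
        "seed": seed,
        "trials": [
            [s.angle if isinstance(s, StraightStreet) else s.variant_id for s in t.streets]
            for t in trials
        ],
    }
    return json.dumps(payload, indent=2)
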