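"""Synthetic participants for the street-navigation paradigm.

The study population is emulated by *steering agents*: closed-loop
controllers that aim at a look-ahead point on the street centreline,
corrupt the ideal heading with zero-mean angular noise, and press the
key(s) whose axis ratio best matches the corrupted heading.  Practice
is modelled as an exponential decay of the angular noise and an
exponential approach of the preferred speed to its asymptote,

    sigma(t) = motor_noise_sd * exp(-learning_rate * (t - 1)) + noise_floor
    skill(t) = min(1, baseline_skill
                      + asymptote_gain * (1 - exp(-learning_rate * (t - 1))))

with t the 1-based trial index.  A 1-3 bimanual-competence covariate is
drawn with a configurable positive rank correlation with baseline
skill.  All group effects (per-task learning-rate scaling, the noise
penalty per transposed axis on transfer streets, the carry-over of
training experience into the post-transfer trials) live in
:class:`EffectConfig`; zeroing them yields a null world in which the
downstream statistics must come out null.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError
from .geometry import (
    TRAINING_TASKS,
    CurvedStreet,
    StraightStreet,
    Street,
    TransferVariant,
)
from .kinematics import CursorState

__all__ = [
    "AgentParams",
    "Agent",
    "EffectConfig",
    "PolicyConfig",
    "PopulationSpec",
    "sample_population",
    "population_table",
    "steering_policy",
    "angle_difficulty",
    "fit_learning_curve",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class AgentParams:
    """Latent parameters of one synthetic participant."""

    baseline_skill: float        # (0, 1]: fraction of the preferred-speed scale
    learning_rate: float         # per-trial exponential rate, >= 0
    asymptote_gain: float        # skill gained with unlimited practice
    motor_noise_sd: float        # initial steering-noise SD, degrees
    noise_floor: float           # irreducible steering noise, degrees
    competence: int              # self-reported bimanual competence, 1-3
    rng_seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_skill <= 1.0:
            raise InvalidParameterError("baseline_skill must lie in (0, 1]")
        if self.learning_rate < 0 or self.asymptote_gain < 0:
            raise InvalidParameterError("learning_rate and asymptote_gain must be >= 0")
        if self.motor_noise_sd < 0 or self.noise_floor < 0:
            raise InvalidParameterError("noise parameters must be >= 0")
        if self.competence not in (1, 2, 3):
            raise InvalidParameterError("competence must be 1, 2 or 3")

    def noise_sd(self, trial_index: float) -> float:
        """Steering-noise SD (degrees) on 1-based trial ``trial_index``."""
        return self.motor_noise_sd * math.exp(-self.learning_rate * (trial_index - 1)) \
            + self.noise_floor

    def skill(self, trial_index: float) -> float:
        """Preferred-speed fraction on 1-based trial ``trial_index``."""
        s = self.baseline_skill + self.asymptote_gain * (
            1.0 - math.exp(-self.learning_rate * (trial_index - 1))
        )
        return min(s, 1.0)


@dataclass(frozen=True)
class Agent:
    subject_id: int
    params: AgentParams
    training_task: str
    transfer_variant: str


@dataclass(frozen=True)
class EffectConfig:
    """Population- and group-level effect structure (all config, no code).

    ``task_lr_scale`` scales learning rates per training task (constant
    practice concentrates improvement, mirroring larger change scores
    in the least variable task); ``flip_noise_penalty`` multiplies the
    steering noise by ``1 + penalty * n_flips`` on transfer streets
    (transpositions disrupt the learned mapping);
    ``transfer_carryover`` credits that fraction of the training trials
    as experience in the post-transfer trials, discounted per flipped
    axis by ``flip_carryover_discount``.  :meth:`null_world` switches
    every group effect off.
    """

    baseline_skill_mean: float = 0.45
    baseline_skill_sd: float = 0.10
    learning_rate_mean: float = 0.030
    learning_rate_sd: float = 0.008
    motor_noise_mean: float = 12.0
    motor_noise_sd: float = 3.0
    noise_floor: float = 2.0
    asymptote_gain: float = 0.5
    competence_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    competence_skill_corr: float = 0.4
    competence_lr_effect: float = 0.12
    task_lr_scale: dict = field(default_factory=lambda: {
        "Train-I": 1.25, "Train-II": 1.0, "Train-III": 1.0,
        "Train-IV": 0.9, "Train-V": 0.9,
    })
    flip_noise_penalty: float = 0.12
    transfer_carryover: float = 0.30
    flip_carryover_discount: float = 0.25

    @classmethod
    def null_world(cls) -> "EffectConfig":
        return cls(
            competence_lr_effect=0.0,
            task_lr_scale={t: 1.0 for t in TRAINING_TASKS},
            flip_noise_penalty=0.0,
            transfer_carryover=0.0,
            flip_carryover_discount=0.0,
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Cohort layout: a 5 (training) x 3 (transfer) between-subject design."""

    n_per_group: int = 30
    training_tasks: tuple[str, ...] = TRAINING_TASKS
    transfer_variants: tuple[str, ...] = ("S", "M", "L")
    effects: EffectConfig = field(default_factory=EffectConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise InvalidParameterError("n_per_group must be positive")

    @property
    def n_groups(self) -> int:
        return len(self.training_tasks) * len(self.transfer_variants)


def sample_population(spec: PopulationSpec) -> list[Agent]:
    """Draw the synthetic cohort, deterministically given the master seed.

    Baseline skill and competence come from a Gaussian copula with the
    configured rank correlation; learning rates receive the per-task
    scaling and a multiplicative competence effect.
    """
    eff = spec.effects
    rng = np.random.default_rng(spec.master_seed)
    cuts = sps.norm.ppf(np.cumsum(eff.competence_probs[:2]))
    rho = eff.competence_skill_corr
    agents: list[Agent] = []
    sid = 0
    for task in spec.training_tasks:
        lr_scale = eff.task_lr_scale.get(task, 1.0)
        for variant in spec.transfer_variants:
            for _ in range(spec.n_per_group):
                z = rng.standard_normal()
                w = rng.standard_normal()
                c_latent = rho * z + math.sqrt(1.0 - rho ** 2) * w
                competence = 1 + int(c_latent > cuts[0]) + int(c_latent > cuts[1])
                baseline = float(np.clip(
                    eff.baseline_skill_mean + eff.baseline_skill_sd * z, 0.05, 1.0))
                lr = (eff.learning_rate_mean + eff.learning_rate_sd * rng.standard_normal())
                lr *= lr_scale * (1.0 + eff.competence_lr_effect * (competence - 2))
                lr = max(lr, 1e-4)
                noise = float(np.clip(
                    eff.motor_noise_mean + eff.motor_noise_sd * rng.standard_normal(),
                    1.0, None))
                sid += 1
                agents.append(Agent(
                    subject_id=sid,
                    params=AgentParams(
                        baseline_skill=baseline,
                        learning_rate=lr,
                        asymptote_gain=eff.asymptote_gain,
                        motor_noise_sd=noise,
                        noise_floor=eff.noise_floor,
                        competence=competence,
                        rng_seed=int(rng.integers(2 ** 31)),
                    ),
                    training_task=task,
                    transfer_variant=variant,
                ))
    return agents


def population_table(agents: list[Agent]):
    """Tidy per-subject parameter table."""
    import pandas as pd

    return pd.DataFrame([
        {
            "subject_id": a.subject_id,
            "training_task": a.training_task,
            "transfer_variant": a.transfer_variant,
            "competence": a.params.competence,
            "baseline_skill": a.params.baseline_skill,
            "learning_rate": a.params.learning_rate,
            "motor_noise_sd": a.params.motor_noise_sd,
            "rng_seed": a.params.rng_seed,
        }
        for a in agents
    ])


# ---------------------------------------------------------------------------
# steering policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolicyConfig:
    """Steering-controller constants.

    ``lookahead`` is the arc-length distance (height units) of the
    aim point ahead of the cursor's centreline projection;
    ``speed_scale`` maps skill 1.0 to a preferred speed in height
    units/frame (well below the 0.3 cap, as observed cursor speeds
    are).  Steering noise is scaled by a street-angle factor
    reflecting bimanual demand: ``axis_noise_floor`` for single-key
    streets (0° and 90°, where execution barely involves the second
    hand) rising by ``difficulty_weight`` times a normalised bump that
    peaks in the hard 10-40° and 50-80° bands.  ``curve_noise_factor``
    is the factor on curved streets, whose heading demands continuous
    re-coordination.
    """

    lookahead: float = 0.08
    speed_scale: float = 0.01
    dead_zone: float = 0.15
    axis_noise_floor: float = 0.2
    difficulty_weight: float = 1.0
    curve_noise_factor: float = 1.15


_BUMP_MAX = 0.25 / 0.7  # max of g - 0.7 g^2 over g in [0, 1]


def angle_difficulty(angle_deg: float) -> float:
    """Normalised bimanual-demand bump: 0 at 0°/90°, 1 near 29°/61°.

    ``(g - 0.7 g**2) / max`` with ``g = sin^2(2*angle)`` peaks at
    angles of about 29° and 61° (the hard 10-40° and 50-80° bands) and
    is slightly lower at 45° where both hands contribute equally.
    """
    g = math.sin(2.0 * angle_deg * _DEG) ** 2
    return (g - 0.7 * g * g) / _BUMP_MAX


def street_difficulty_factor(street: Street, config: PolicyConfig) -> float:
    """Multiplier on the steering-noise SD for one street."""
    if isinstance(street, StraightStreet):
        return config.axis_noise_floor + config.difficulty_weight * angle_difficulty(street.angle)
    return config.curve_noise_factor


def steering_policy(
    agent: AgentParams,
    trial_index: float,
    street: Street,
    directions: tuple[int, int] = (1, 1),
    rng: random.Random | None = None,
    noise_scale: float = 1.0,
    config: PolicyConfig | None = None,
):
    """Closed-loop control policy for one street attempt.

    Each frame the policy projects the cursor onto the centreline, aims
    at a look-ahead point, rotates the ideal heading by
    ``N(0, sigma(t))`` steering noise, and holds the key on each axis
    whose current speed is below the desired axis speed
    ``skill(t) * speed_scale * |heading component|``.

    ``trial_index`` may be fractional: it is the agent's *effective
    experience*, which for transfer trials includes any configured
    carry-over from training.
    """
    config = config or PolicyConfig()
    rng = rng or random.Random(agent.rng_seed)
    tracker = street.tracker()
    sigma = agent.noise_sd(trial_index) * noise_scale \
        * street_difficulty_factor(street, config) * _DEG
    v_des = agent.skill(trial_index) * config.speed_scale
    lookahead = config.lookahead
    dead_zone = config.dead_zone
    length = tracker.length
    dx, dy = directions
    gauss = rng.gauss
    atan2, cos, sin = math.atan2, math.cos, math.sin

    def policy(state: CursorState) -> tuple[bool, bool]:
        s, _ = tracker.locate(state.x, state.y)
        ts = s + lookahead
        if ts > length:
            ts = length
        tx, ty = tracker.point_at(ts)
        mx = (tx - state.x) * dx   # heading in the movement frame
        my = (ty - state.y) * dy
        ang = atan2(my, mx) + gauss(0.0, sigma)
        ux, uy = cos(ang), sin(ang)
        if ux < dead_zone:
            ux = 0.0
        if uy < dead_zone:
            uy = 0.0
        return (state.vx < v_des * ux, state.vy < v_des * uy)

    return policy


def effective_experience(
    n_training_trials: int,
    transfer_trial: int,
    phase: str,
    variant: TransferVariant,
    effects: EffectConfig,
    n_pre_trials: int = 5,
) -> float:
    """Effective 1-based experience index for a transfer trial.

    Pre-transfer trials count only themselves; post-transfer trials
    additionally credit ``transfer_carryover`` of the training trials,
    discounted per transposed axis.
    """
    if phase == "pre":
        return float(transfer_trial)
    carry = effects.transfer_carryover * (
        1.0 - effects.flip_carryover_discount * variant.n_flips)
    return n_pre_trials + max(carry, 0.0) * n_training_trials + transfer_trial


def transfer_noise_scale(variant: TransferVariant, effects: EffectConfig) -> float:
    return 1.0 + effects.flip_noise_penalty * variant.n_flips


# ---------------------------------------------------------------------------
# learning-curve recovery
# ---------------------------------------------------------------------------

def fit_learning_curve(values: np.ndarray) -> tuple[float, float, float]:
    """Fit ``A * exp(-r * (t - 1)) + C`` to a per-trial series.

    Returns ``(A, r, C)``.  Used to recover an agent's learning rate
    from its simulated per-trial error.  Initialised from a log-linear
    fit of the floor-subtracted early curve.
    """
    from scipy.optimize import curve_fit

    y = np.asarray(values, dtype=float)
    t = np.arange(1.0, y.size + 1.0)
    c0 = float(np.median(y[-max(y.size // 5, 3):]))
    a0 = max(float(np.mean(y[:3])) - c0, 1e-6)
    pos = y[: y.size // 2] - c0
    mask = pos > 0
    if mask.sum() >= 3:
        slope = np.polyfit(t[: y.size // 2][mask], np.log(pos[mask]), 1)[0]
        r0 = max(-slope, 1e-3)
    else:
        r0 = 0.02

    def model(tt, a, r, c):
        return a * np.exp(-r * (tt - 1.0)) + c

    popt, _ = curve_fit(
        model, t, y, p0=(a0, r0, c0),
        bounds=([0.0, 0.0, 0.0], [np.inf, 2.0, np.inf]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
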