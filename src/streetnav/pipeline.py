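"""End-to-end study pipeline on synthetic cohorts.

Stages: sample a population → schedule sessions → simulate street
attempts (pre-transfer, training, post-transfer) → score → calibrate
normalisation constants on a synthetic pilot → denoise training
movement time and error by trial difficulty → compute performance
indices and change scores → run the statistical analysis.

Two fidelity levels share the same agent learning model:

``"kinematic"``
    every street attempt is simulated frame by frame with the two-key
    control law and the steering policy (exact but slow — used for
    kinematics-facing analyses and smaller cohorts);
``"analytic"``
    street movement time and error are drawn from closed-form
    expectations of the same policy (traversal time at the agent's
    preferred speed, error proportional to the steering-noise SD, both
    modulated by the street's bimanual-difficulty factor) with
    log-normal trial-to-trial noise.  This surrogate makes full
    450-subject cohorts cheap and is the default for cohort-level
    statistics.

All randomness derives from a single master seed via
``numpy.random.SeedSequence`` spawning, so every stage is reproducible
and independently re-runnable.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from . import geometry, kinematics, scoring, stats
from .agents import (
    Agent,
    EffectConfig,
    PolicyConfig,
    PopulationSpec,
    angle_difficulty,
    effective_experience,
    sample_population,
    steering_policy,
    street_difficulty_factor,
    transfer_noise_scale,
)
from .denoise import denoise_trials, street_difficulty_profile, trial_difficulty
from .errors import DegenerateDesignError, InvalidParameterError
from .geometry import TRANSFER_VARIANTS, training_task_spec
from .kinematics import KinematicsConfig
from .scoring import NormalizationConstants, StreetScore, calibrate_constants

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "simulate_street_table",
    "simulate_cohort",
    "build_cohort_table",
    "analyze_cohort",
    "run_study",
    "StudyResult",
]

_DEG = math.pi / 180.0

# analytic-surrogate constants (calibrated once against the kinematic
# simulator at the default policy constants; see docs/methods.md)
_ERR_PER_RAD = 0.02      # RMS error per radian of steering noise
_RESET_TIME_COEF = 0.3   # movement-time inflation from imperfect steering
_MT_LOGNORM_SD = 0.10
_ERR_LOGNORM_SD = 0.20


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to regenerate one synthetic study."""

    population: PopulationSpec = field(default_factory=PopulationSpec)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    policy: PolicyConfig = field(default_factory=PolicyConfig)
    n_training_trials: int = 100
    n_transfer_trials: int = 5
    streets_per_trial: int = 6
    street_width: float = geometry.DEFAULT_STREET_WIDTH
    street_length: float = geometry.DEFAULT_STREET_LENGTH
    pilot_n_per_group: int = 5
    pm_inverted: bool = False
    denoise_mode: str = "fitted"
    fidelity: str = "analytic"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.fidelity not in ("analytic", "kinematic"):
            raise InvalidParameterError(f"unknown fidelity {self.fidelity!r}")
        if min(self.n_training_trials, self.n_transfer_trials, self.streets_per_trial) <= 0:
            raise InvalidParameterError("trial counts must be positive")


def _subject_seeds(master_seed: int, n: int, stage: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stage,))
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# street-level simulation
# ---------------------------------------------------------------------------

def _task_spec(config: StudyConfig, task: str) -> geometry.TrainingTaskSpec:
    return training_task_spec(
        task, n_trials=config.n_training_trials,
        streets_per_trial=config.streets_per_trial)


def _curve_lengths(config: StudyConfig) -> list[float]:
    streets = geometry.build_transfer_streets("S", width=config.street_width)
    return [s.length for s in streets]


def _analytic_scores(
    agent: Agent,
    experience: np.ndarray,
    difficulty: np.ndarray,
    lengths: np.ndarray,
    noise_scale: float,
    config: StudyConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form street scores for one agent (vectorised over streets)."""
    p = agent.params
    sigma = (p.motor_noise_sd * np.exp(-p.learning_rate * (experience - 1.0))
             + p.noise_floor) * noise_scale * difficulty * _DEG
    skill = np.minimum(
        p.baseline_skill + p.asymptote_gain * (1.0 - np.exp(-p.learning_rate * (experience - 1.0))),
        1.0)
    base_frames = lengths / (config.policy.speed_scale * skill)
    mt = base_frames / config.kinematics.frame_rate \
        * np.exp(_RESET_TIME_COEF * sigma) \
        * np.exp(rng.normal(0.0, _MT_LOGNORM_SD, sigma.size))
    err = _ERR_PER_RAD * sigma * np.exp(rng.normal(0.0, _ERR_LOGNORM_SD, sigma.size))
    return mt, err


def _kinematic_score(
    agent: Agent,
    street,
    experience: float,
    directions: tuple[int, int],
    noise_scale: float,
    config: StudyConfig,
    rng: random.Random,
) -> tuple[float, float] | None:
    policy = steering_policy(
        agent.params, experience, street, directions=directions,
        rng=rng, noise_scale=noise_scale, config=config.policy)
    run = kinematics.run_street_scored(policy, street, config.kinematics, directions)
    if not run.completed:
        return None
    return run.movement_time, run.rms_error


def simulate_street_table(
    config: StudyConfig,
    agents: Iterable[Agent] | None = None,
    stage: int = 1,
) -> pd.DataFrame:
    """Simulate every street attempt of every agent.

    Returns a long table with one row per street:
    subject_id, training_task, transfer_variant, competence, phase
    ("pre"/"train"/"post"), trial, street, angle (straight streets),
    curve_id (curved streets), movement_time, error.  Aborted streets
    (kinematic fidelity only) are dropped with a logged warning.
    """
    agents = list(agents) if agents is not None else sample_population(config.population)
    effects = config.population.effects
    seeds = _subject_seeds(config.master_seed, len(agents), stage)
    curve_lengths = np.asarray(_curve_lengths(config))
    curve_difficulty = np.full(6, config.policy.curve_noise_factor)
    spt = config.streets_per_trial

    rows: list[dict] = []
    n_aborted = 0
    for agent, seed in zip(agents, seeds):
        spec = _task_spec(config, agent.training_task)
        variant = TRANSFER_VARIANTS[agent.transfer_variant]
        nscale = transfer_noise_scale(variant, effects)
        angle_seq = geometry.schedule_angles(spec, seed)
        n_train_streets = spec.n_trials * spt

        if config.fidelity == "analytic":
            rng = np.random.default_rng(seed)
            # training
            exp_train = np.repeat(np.arange(1.0, spec.n_trials + 1.0), spt)
            diff_train = (config.policy.axis_noise_floor
                          + config.policy.difficulty_weight
                          * np.array([angle_difficulty(a) for a in angle_seq]))
            mt, err = _analytic_scores(
                agent, exp_train, diff_train,
                np.full(n_train_streets, config.street_length), 1.0, config, rng)
            _append_rows(rows, agent, "train", spt, mt, err, angles=angle_seq)
            # transfer, pre and post
            for phase in ("pre", "post"):
                order = _transfer_orders(config, seed, phase)
                exp = np.array([
                    effective_experience(spec.n_trials, t + 1, phase, variant, effects,
                                         config.n_transfer_trials)
                    for t in range(config.n_transfer_trials) for _ in range(spt)])
                mt, err = _analytic_scores(
                    agent, exp, curve_difficulty[order], curve_lengths[order],
                    nscale, config, rng)
                _append_rows(rows, agent, phase, spt, mt, err, curve_ids=order + 1)
        else:
            rng = random.Random(seed)
            streets_cache = geometry.build_transfer_streets(
                variant, width=config.street_width)
            for phase in ("pre", "train", "post"):
                if phase == "train":
                    directions = (1, 1)
                    for i, angle in enumerate(angle_seq):
                        trial = i // spt + 1
                        street = geometry.StraightStreet(
                            float(angle), length=config.street_length,
                            width=config.street_width)
                        out = _kinematic_score(
                            agent, street, float(trial), directions, 1.0, config, rng)
                        if out is None:
                            n_aborted += 1
                            continue
                        rows.append(_row(agent, "train", trial, i % spt + 1,
                                         out[0], out[1], angle=float(angle)))
                else:
                    directions = variant.movement_directions
                    order = _transfer_orders(config, seed, phase)
                    for i, k in enumerate(order):
                        trial = i // spt + 1
                        exp = effective_experience(
                            spec.n_trials, trial, phase, variant, effects,
                            config.n_transfer_trials)
                        out = _kinematic_score(
                            agent, streets_cache[k], exp, directions, nscale, config, rng)
                        if out is None:
                            n_aborted += 1
                            continue
                        rows.append(_row(agent, phase, trial, i % spt + 1,
                                         out[0], out[1], curve_id=int(k) + 1))
    if n_aborted:
        logger.warning("excluded %d aborted street attempts", n_aborted)
    return pd.DataFrame(rows)


def _transfer_orders(config: StudyConfig, seed: int, phase: str) -> np.ndarray:
    """Seeded pseudo-random curve order for all transfer trials of a phase."""
    rng = random.Random(f"{seed}:{phase}")  # str seeding is hash-independent
    order = []
    for _ in range(config.n_transfer_trials):
        perm = list(range(6))
        rng.shuffle(perm)
        order.extend(perm)
    return np.asarray(order)


def _row(agent, phase, trial, street, mt, err, angle=np.nan, curve_id=np.nan):
    return {
        "subject_id": agent.subject_id,
        "training_task": agent.training_task,
        "transfer_variant": agent.transfer_variant,
        "competence": agent.params.competence,
        "phase": phase,
        "trial": trial,
        "street": street,
        "angle": angle,
        "curve_id": curve_id,
        "movement_time": mt,
        "error": err,
    }


def _append_rows(rows, agent, phase, spt, mt, err, angles=None, curve_ids=None):
    for i in range(mt.size):
        rows.append(_row(
            agent, phase, i // spt + 1, i % spt + 1, float(mt[i]), float(err[i]),
            angle=float(angles[i]) if angles is not None else np.nan,
            curve_id=int(curve_ids[i]) if curve_ids is not None else np.nan,
        ))


# ---------------------------------------------------------------------------
# pilot calibration
# ---------------------------------------------------------------------------

def pilot_constants(config: StudyConfig) -> NormalizationConstants:
    """Normalisation constants (a, b) from a synthetic pilot cohort.

    The pilot is an independent sample with ``pilot_n_per_group``
    agents per cell (75 at the default 5/group), simulated under the
    same config at a seed derived from the master seed.
    """
    pilot_spec = replace(
        config.population, n_per_group=config.pilot_n_per_group,
        master_seed=config.master_seed + 104729)
    pilot_cfg = replace(config, population=pilot_spec)
    table = simulate_street_table(pilot_cfg, stage=2)
    return calibrate_constants(
        StreetScore(mt, err)
        for mt, err in zip(table["movement_time"], table["error"]))


# ---------------------------------------------------------------------------
# denoising and cohort assembly
# ---------------------------------------------------------------------------

def _denoise_training(street_table: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per-task trial-difficulty denoising of training mt and error.

    Returns a trial-level table (subject x trial) with raw and denoised
    movement time and error.
    """
    train = street_table[street_table["phase"] == "train"]
    out = []
    for task, sub in train.groupby("training_task", observed=True):
        trial_level = (sub.groupby(["subject_id", "trial"])
                       [["movement_time", "error"]].mean().reset_index())
        wide_mt = trial_level.pivot(index="subject_id", columns="trial",
                                    values="movement_time").sort_index()
        wide_err = trial_level.pivot(index="subject_id", columns="trial",
                                     values="error").sort_index()
        # trial-angle matrix: schedules differ per subject, so difficulty
        # is averaged over subjects' trial compositions per trial index
        denoised = {}
        for var, wide in (("movement_time", wide_mt), ("error", wide_err)):
            profile = street_difficulty_profile(sub, var, task=task)
            per_subj_diff = (
                sub.assign(street_diff=profile.means.reindex(sub["angle"]).to_numpy())
                .groupby(["subject_id", "trial"])["street_diff"].mean()
                .reset_index()
                .pivot(index="subject_id", columns="trial", values="street_diff")
                .sort_index())
            diff = per_subj_diff.mean(axis=0).to_numpy()
            res = denoise_trials(wide.to_numpy(), diff, mode=config.denoise_mode)
            denoised[var] = pd.DataFrame(res.values, index=wide.index,
                                         columns=wide.columns)
        for sid in wide_mt.index:
            for trial in wide_mt.columns:
                out.append({
                    "subject_id": sid, "training_task": task, "trial": int(trial),
                    "movement_time": wide_mt.loc[sid, trial],
                    "error": wide_err.loc[sid, trial],
                    "movement_time_dn": denoised["movement_time"].loc[sid, trial],
                    "error_dn": denoised["error"].loc[sid, trial],
                })
    return pd.DataFrame(out)


def build_cohort_table(
    street_table: pd.DataFrame,
    constants: NormalizationConstants,
    config: StudyConfig,
) -> pd.DataFrame:
    """One row per subject: group labels, competence, PI summaries.

    Training PIs are computed from denoised movement time and error;
    transfer PIs from raw values (curved streets share one difficulty).
    Columns: early_pi, late_pi, training_change, pre_pi, post_pi,
    transfer_change, mean_train_pi.
    """
    meta = (street_table.groupby("subject_id")
            [["training_task", "transfer_variant", "competence"]].first())
    train_dn = _denoise_training(street_table, config)

    def _pi(mt, err):
        pe = constants.a / err
        pm = constants.b / mt if config.pm_inverted else mt / constants.b
        return pm * pe

    train_dn["pi"] = _pi(train_dn["movement_time_dn"].clip(lower=1e-9),
                         train_dn["error_dn"].clip(lower=1e-9))
    transfer = street_table[street_table["phase"].isin(["pre", "post"])]
    ttrial = (transfer.groupby(["subject_id", "phase", "trial"])
              [["movement_time", "error"]].mean().reset_index())
    ttrial["pi"] = _pi(ttrial["movement_time"], ttrial["error"])

    rows = []
    for sid, sub in train_dn.groupby("subject_id"):
        sub = sub.sort_values("trial")
        tsub = ttrial[ttrial["subject_id"] == sid]
        cs = stats.change_scores(
            sub["pi"].to_numpy(),
            tsub.loc[tsub["phase"] == "pre", "pi"].to_numpy(),
            tsub.loc[tsub["phase"] == "post", "pi"].to_numpy(),
        )
        rows.append({
            "subject_id": sid,
            "training_task": meta.loc[sid, "training_task"],
            "transfer_variant": meta.loc[sid, "transfer_variant"],
            "competence": int(meta.loc[sid, "competence"]),
            "mean_train_pi": float(sub["pi"].mean()),
            "early_pi": cs.early_pi, "late_pi": cs.late_pi,
            "training_change": cs.training_change,
            "pre_pi": cs.pre_pi, "post_pi": cs.post_pi,
            "transfer_change": cs.transfer_change,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def analyze_cohort(cohort: pd.DataFrame) -> dict:
    """The study's statistical pipeline on a cohort table.

    Returns a dict with: the training-task validation ANOVA (mean
    training PI), the transfer ANCOVA (post PI with pre PI covariate),
    per-task paired early/late t-tests, the change-score ANOVA
    (training task x competence) and the training-transfer change
    correlation.
    """
    out: dict = {}
    out["training_validation"] = stats.one_way_anova(
        cohort, "mean_train_pi", "training_task", followups=True).to_dict()
    out["transfer_validation"] = stats.ancova(
        cohort, "post_pi", "transfer_variant", ["pre_pi"]).to_dict()
    out["learning"] = {
        task: stats.paired_t(
            sub["late_pi"], sub["early_pi"], name=f"{task} late vs early").to_dict()
        for task, sub in cohort.groupby("training_task", observed=True)
    }
    try:
        out["change_anova"] = stats.anova(
            cohort, "training_change", ["training_task", "competence"]).to_dict()
    except DegenerateDesignError:
        # empty task x competence cells (small cohorts): drop the interaction
        out["change_anova"] = stats.anova(
            cohort, "training_change", ["training_task", "competence"],
            interactions=False).to_dict()
    r, p = stats.training_transfer_correlation(cohort)
    out["training_transfer_correlation"] = {"r": r, "p": p, "n": int(len(cohort))}
    return out


@dataclass(frozen=True)
class StudyResult:
    config: StudyConfig
    constants: NormalizationConstants
    street_table: pd.DataFrame
    cohort: pd.DataFrame
    analysis: dict


def simulate_cohort(config: StudyConfig) -> tuple[pd.DataFrame, NormalizationConstants]:
    """Simulate the cohort street table and the pilot constants."""
    constants = pilot_constants(config)
    table = simulate_street_table(config)
    return table, constants


def run_study(config: StudyConfig | None = None) -> StudyResult:
    """Full pipeline: simulate, score, denoise, analyse."""
    config = config or StudyConfig()
    table, constants = simulate_cohort(config)
    cohort = build_cohort_table(table, constants, config)
    analysis = analyze_cohort(cohort)
    return StudyResult(config, constants, table, cohort, analysis)
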