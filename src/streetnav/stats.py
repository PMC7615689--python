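"""Statistical pipeline: change scores, ANOVA/ANCOVA, effect sizes, power.

Model fits are ordinary least squares (statsmodels) with Type-II sums
of squares; effect sizes are partial eta squared
``SS_effect / (SS_effect + SS_error)``, Cohen's f
``sqrt(eta2 / (1 - eta2))`` and Cohen's d (pooled SD for two-sample
tests, SD of differences for paired tests).  Post-hoc t-tests carry
Bonferroni-adjusted p-values with an explicit family size.  Design
planning inverts the noncentral-F power function of the
repeated-measures between-factors ANOVA with noncentrality

    lambda = N * m * f**2 / (1 + (m - 1) * rho)

(m repeated measurements with correlation rho), searching the smallest
total N that is a multiple of the group count and reaches the target
power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateDesignError,
    InvalidParameterError,
    NoSolutionError,
    UndefinedCorrelationError,
)

__all__ = [
    "EffectResult",
    "TTestResult",
    "AnovaReport",
    "ChangeScores",
    "change_scores",
    "anova",
    "one_way_anova",
    "ancova",
    "paired_t",
    "two_sample_t",
    "pearson_r",
    "pairwise_followups",
    "bonferroni",
    "eta2_to_f",
    "f_to_eta2",
    "between_factors_power",
    "required_sample_size",
    "training_transfer_correlation",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta2: float

    def to_dict(self) -> dict:
        return {
            "effect": self.name, "F": self.F, "df1": self.df1,
            "df2": self.df2, "p": self.p, "partial_eta2": self.partial_eta2,
        }


@dataclass(frozen=True)
class TTestResult:
    name: str
    t: float
    df: float
    p: float
    p_adjusted: float
    cohens_d: float
    mean_diff: float

    def to_dict(self) -> dict:
        return {
            "comparison": self.name, "t": self.t, "df": self.df, "p": self.p,
            "p_bonf": self.p_adjusted, "cohens_d": self.cohens_d,
            "mean_diff": self.mean_diff,
        }


@dataclass(frozen=True)
class AnovaReport:
    effects: tuple[EffectResult, ...]
    followups: tuple[TTestResult, ...] = ()

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "effects": [e.to_dict() for e in self.effects],
            "followups": [t.to_dict() for t in self.followups],
        }


# ---------------------------------------------------------------------------
# change scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChangeScores:
    early_pi: float
    late_pi: float
    training_change: float
    pre_pi: float
    post_pi: float
    transfer_change: float


def change_scores(
    training_pi: Sequence[float],
    pre_pi: Sequence[float],
    post_pi: Sequence[float],
    n_early: int = 10,
    n_late: int = 10,
) -> ChangeScores:
    """Early/late training means and pre/post transfer means with changes.

    Training change is late minus early (first/last ``n_early``/
    ``n_late`` trials); transfer change is post minus pre.
    """
    tr = np.asarray(training_pi, dtype=float)
    pre = np.asarray(pre_pi, dtype=float)
    post = np.asarray(post_pi, dtype=float)
    if tr.size < n_early + n_late:
        raise InvalidParameterError(
            f"need >= {n_early + n_late} training trials, got {tr.size}")
    if pre.size == 0 or post.size == 0:
        raise InvalidParameterError("need at least one pre and one post trial")
    early = float(tr[:n_early].mean())
    late = float(tr[-n_late:].mean())
    return ChangeScores(
        early_pi=early, late_pi=late, training_change=late - early,
        pre_pi=float(pre.mean()), post_pi=float(post.mean()),
        transfer_change=float(post.mean() - pre.mean()),
    )


# ---------------------------------------------------------------------------
# ANOVA / ANCOVA (statsmodels OLS, Type-II SS)
# ---------------------------------------------------------------------------

def _fit_anova(df: pd.DataFrame, formula: str, effect_labels: dict[str, str]) -> list[EffectResult]:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(formula, data=df).fit()
    if model.df_resid < 1:
        raise DegenerateDesignError("no residual degrees of freedom")
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise DegenerateDesignError("rank-deficient design matrix")
    table = sm.stats.anova_lm(model, typ=2)
    ss_res = float(table.loc["Residual", "sum_sq"])
    df_res = float(table.loc["Residual", "df"])
    out = []
    for term, label in effect_labels.items():
        ss = float(table.loc[term, "sum_sq"])
        d1 = float(table.loc[term, "df"])
        F = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        out.append(EffectResult(
            name=label, F=F, df1=d1, df2=df_res, p=p,
            partial_eta2=ss / (ss + ss_res),
        ))
    return out


def anova(
    df: pd.DataFrame,
    dv: str,
    between: Sequence[str] | str,
    interactions: bool = True,
) -> AnovaReport:
    """Between-subject factorial ANOVA with partial eta squared."""
    between = [between] if isinstance(between, str) else list(between)
    for b in between:
        if df[b].nunique() < 2:
            raise DegenerateDesignError(f"factor {b!r} has fewer than 2 levels")
    op = " * " if interactions and len(between) > 1 else " + "
    formula = f"{dv} ~ " + op.join(f"C({b})" for b in between)
    labels = {f"C({b})": b for b in between}
    if interactions and len(between) > 1:
        for r in range(2, len(between) + 1):
            for combo in combinations(between, r):
                labels[":".join(f"C({b})" for b in combo)] = ":".join(combo)
    return AnovaReport(effects=tuple(_fit_anova(df, formula, labels)))


def one_way_anova(
    df: pd.DataFrame,
    dv: str,
    between: str,
    followups: bool = False,
    family_size: int | None = None,
) -> AnovaReport:
    """One-way between-subject ANOVA, optionally with pairwise follow-ups."""
    report = anova(df, dv, between)
    if not followups:
        return report
    return AnovaReport(
        effects=report.effects,
        followups=tuple(pairwise_followups(df, dv, between, family_size=family_size)),
    )


def ancova(
    df: pd.DataFrame,
    dv: str,
    between: Sequence[str] | str,
    covariates: Sequence[str],
    interactions: bool = True,
) -> AnovaReport:
    """Between-subject AN(C)OVA with mean-centred numeric covariates."""
    between = [between] if isinstance(between, str) else list(between)
    if not covariates:
        return anova(df, dv, between, interactions)
    work = df.copy()
    for c in covariates:
        work[c] = work[c].astype(float) - work[c].astype(float).mean()
    op = " * " if interactions and len(between) > 1 else " + "
    formula = (
        f"{dv} ~ " + op.join(f"C({b})" for b in between)
        + " + " + " + ".join(covariates)
    )
    labels = {f"C({b})": b for b in between}
    if interactions and len(between) > 1:
        for r in range(2, len(between) + 1):
            for combo in combinations(between, r):
                labels[":".join(f"C({b})" for b in combo)] = ":".join(combo)
    labels.update({c: c for c in covariates})
    return AnovaReport(effects=tuple(_fit_anova(work, formula, labels)))


# ---------------------------------------------------------------------------
# t-tests and correlation
# ---------------------------------------------------------------------------

def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * family size)."""
    if family_size < 1:
        raise InvalidParameterError("family size must be >= 1")
    return min(1.0, p * family_size)


def paired_t(x: Sequence[float], y: Sequence[float], name: str = "paired",
             family_size: int = 1) -> TTestResult:
    """Paired-samples t-test; d = mean difference / SD of differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InvalidParameterError("paired samples must have equal size >= 2")
    res = sps.ttest_rel(x, y)
    diff = x - y
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else float("nan")
    return TTestResult(name, float(res.statistic), float(x.size - 1),
                       float(res.pvalue), bonferroni(float(res.pvalue), family_size),
                       d, float(diff.mean()))


def two_sample_t(x: Sequence[float], y: Sequence[float], name: str = "two-sample",
                 family_size: int = 1) -> TTestResult:
    """Independent two-sample t-test (pooled variance); pooled-SD Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("each sample needs >= 2 observations")
    res = sps.ttest_ind(x, y, equal_var=True)
    n1, n2 = x.size, y.size
    pooled = math.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    d = float((x.mean() - y.mean()) / pooled) if pooled > 0 else float("nan")
    return TTestResult(name, float(res.statistic), float(n1 + n2 - 2),
                       float(res.pvalue), bonferroni(float(res.pvalue), family_size),
                       d, float(x.mean() - y.mean()))


def pairwise_followups(
    df: pd.DataFrame,
    dv: str,
    between: str,
    family_size: int | None = None,
) -> list[TTestResult]:
    """All pairwise two-sample t-tests between factor levels.

    The Bonferroni family size defaults to the number of pairwise
    comparisons and is exposed explicitly because published follow-ups
    sometimes adjust for the number of levels instead.
    """
    levels = sorted(df[between].unique())
    pairs = list(combinations(levels, 2))
    fam = family_size if family_size is not None else len(pairs)
    out = []
    for a, b in pairs:
        res = two_sample_t(
            df.loc[df[between] == a, dv], df.loc[df[between] == b, dv],
            name=f"{a} vs {b}", family_size=fam)
        out.append(res)
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("a variable has zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def training_transfer_correlation(cohort: pd.DataFrame) -> tuple[float, float]:
    """Correlation between training change and transfer change."""
    return pearson_r(cohort["training_change"], cohort["transfer_change"])


# ---------------------------------------------------------------------------
# effect sizes and power
# ---------------------------------------------------------------------------

def eta2_to_f(partial_eta2: float) -> float:
    """Cohen's f from partial eta squared: f = sqrt(eta2 / (1 - eta2))."""
    if not 0.0 <= partial_eta2 < 1.0:
        raise InvalidParameterError("partial eta squared must lie in [0, 1)")
    return math.sqrt(partial_eta2 / (1.0 - partial_eta2))


def f_to_eta2(f: float) -> float:
    """Inverse of :func:`eta2_to_f`."""
    if f < 0:
        raise InvalidParameterError("Cohen's f must be >= 0")
    return f * f / (1.0 + f * f)


def between_factors_power(
    n_total: int,
    f: float,
    n_groups: int,
    n_measurements: int = 2,
    corr_repeated: float = 0.0,
    alpha: float = 0.05,
) -> float:
    """Power of the between-factors test of a repeated-measures ANOVA.

    Noncentral-F power with noncentrality
    ``N * m * f^2 / (1 + (m - 1) * rho)``, numerator df
    ``n_groups - 1`` and denominator df ``N - n_groups`` (the
    convention of standard a-priori power software).
    """
    df1 = n_groups - 1
    df2 = n_total - n_groups
    if df1 < 1 or df2 < 1:
        raise InvalidParameterError("need n_total > n_groups >= 2")
    lam = n_total * n_measurements * f * f / (1.0 + (n_measurements - 1) * corr_repeated)
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_sample_size(
    f: float,
    alpha: float = 0.05,
    power: float = 0.95,
    n_groups: int = 15,
    n_measurements: int = 2,
    corr_repeated: float = 0.0,
    max_n: int = 10 ** 6,
) -> int:
    """Smallest total N (multiple of the group count) reaching the power.

    For the study's planning inputs — f = 0.24, alpha = 0.05, power =
    0.95, 15 groups, 2 measurements, rho = 0.663 — the search returns
    N = 420.
    """
    if f <= 0:
        raise InvalidParameterError("Cohen's f must be > 0")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise InvalidParameterError("alpha and power must lie in (0, 1)")
    if not 0.0 <= corr_repeated < 1.0:
        raise InvalidParameterError("corr_repeated must lie in [0, 1)")
    n = n_groups * 2 if n_groups >= 2 else 4
    while n <= max_n:
        if between_factors_power(n, f, n_groups, n_measurements, corr_repeated, alpha) >= power:
            return n
        n += n_groups
    raise NoSolutionError(f"target power unreachable within N <= {max_n}")
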