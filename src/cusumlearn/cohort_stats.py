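"""Cohort comparison: 2x2 odds ratios, logistic fit, t-test, sensitivity grid.

The trainee-level endpoint is binary achievement (competent / not).
Cohorts are compared with the crude odds ratio from the 2x2 table
(Woolf log-OR confidence interval), cross-checked by a single-covariate
logistic regression fitted by iteratively reweighted least squares —
for a saturated one-covariate model the exponentiated slope equals the
crude OR, which makes the pair a built-in consistency check.  The
attempts-to-competence endpoint is compared with Welch's
unequal-variance t-test.  The sensitivity grid repeats the whole
analysis over a list of (p0, p1) boundary settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .boundaries import FailureRateSpec, compute_constants
from .learning_curve import (
    COMPETENT,
    attempts_to_competence,
    classify,
    series_from_frame,
)

__all__ = [
    "ContingencyTable2x2",
    "CohortComparison",
    "SensitivityRow",
    "odds_ratio",
    "logistic_fit",
    "SeparationError",
    "welch_t_test",
    "proportion_ratio",
    "compare_cohorts",
    "sensitivity_grid",
]

Z_95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Achievement counts by cohort: (yes, no) per arm."""

    study_yes: int
    study_no: int
    control_yes: int
    control_no: int

    def __post_init__(self) -> None:
        for name in ("study_yes", "study_no", "control_yes", "control_no"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def study_n(self) -> int:
        return self.study_yes + self.study_no

    @property
    def control_n(self) -> int:
        return self.control_yes + self.control_no

    def percentages(self) -> tuple[int, int]:
        """Integer achievement percentages, rounded half away from zero."""
        return (
            _round_half_away(100.0 * self.study_yes / self.study_n),
            _round_half_away(100.0 * self.control_yes / self.control_n),
        )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CohortComparison:
    """Full two-arm comparison at one boundary setting."""

    table: ContingencyTable2x2
    odds_ratio: Optional[float]
    or_ci_low: Optional[float]
    or_ci_high: Optional[float]
    or_pvalue: Optional[float]
    attempts_study: dict
    attempts_control: dict
    attempts_t: Optional[float]
    attempts_pvalue: Optional[float]
    continuity_corrected: bool = False
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        t = self.table
        pct_s, pct_c = t.percentages()
        return {
            "study_yes": t.study_yes,
            "study_no": t.study_no,
            "control_yes": t.control_yes,
            "control_no": t.control_no,
            "study_pct": pct_s,
            "control_pct": pct_c,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "or_pvalue": self.or_pvalue,
            "attempts_study": self.attempts_study,
            "attempts_control": self.attempts_control,
            "attempts_t": self.attempts_t,
            "attempts_pvalue": self.attempts_pvalue,
            "continuity_corrected": self.continuity_corrected,
            "notes": list(self.notes),
        }


@dataclass(frozen=True)
class SensitivityRow:
    """One (p0, p1) setting of the sensitivity analysis."""

    p0: float
    p1: float
    comparison: CohortComparison


class SeparationError(RuntimeError):
    """Raised when the logistic MLE is infinite (complete separation)."""


def odds_ratio(table: ContingencyTable2x2):
    """Crude odds ratio with Woolf 95% CI and log-OR z test.

    A Haldane–Anscombe continuity correction (0.5 added to every cell)
    is applied when any cell is zero; the returned dict flags it.
    With an arm containing no trainees at all (empty row) the OR is
    undefined and all numeric fields are None.

    Returns
    -------
    dict with keys ``or``, ``ci_low``, ``ci_high``, ``pvalue``,
    ``corrected``.
    """
    a, b = table.study_yes, table.study_no
    c, d = table.control_yes, table.control_no
    if (a + b == 0) or (c + d == 0):
        return {
            "or": None,
            "ci_low": None,
            "ci_high": None,
            "pvalue": None,
            "corrected": False,
        }
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = math.log(or_)
    z = log_or / se
    return {
        "or": or_,
        "ci_low": math.exp(log_or - Z_95 * se),
        "ci_high": math.exp(log_or + Z_95 * se),
        "pvalue": 2.0 * sps.norm.sf(abs(z)),
        "corrected": corrected,
    }


def logistic_fit(
    outcomes: Sequence[int],
    groups: Sequence,
    *,
    study_label=None,
    max_iter: int = 50,
    tol: float = 1e-10,
):
    """Logistic regression of achievement on a binary group indicator.

    Fitted by Newton scoring (iteratively reweighted least squares) on
    the two-column design [1, group].  ``exp(slope)`` equals the crude
    odds ratio of the corresponding 2x2 table; the Wald CI and p-value
    come from the observed information.

    Parameters
    ----------
    outcomes : sequence of 0/1
        Trainee-level achievement.
    groups : sequence
        Cohort label per trainee; exactly two distinct labels.
    study_label : optional
        Which label codes 1 (the "study" arm).  Defaults to the larger
        label after sorting, so ("study", "control") puts study = 1.

    Raises
    ------
    SeparationError
        If either arm's outcomes are all 0 or all 1 (infinite MLE).
    """
    y = np.asarray(outcomes, dtype=float)
    g = np.asarray(groups)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    labels = sorted(map(str, set(g.astype(str))))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required; got {labels}")
    if study_label is None:
        study_label = labels[-1]
    x = (g.astype(str) == str(study_label)).astype(float)
    if x.sum() == 0 or x.sum() == len(x):
        raise ValueError("both groups must be present")

    for arm in (0.0, 1.0):
        arm_y = y[x == arm]
        if arm_y.min() == arm_y.max():
            raise SeparationError(
                "complete separation: one arm has all-identical outcomes; "
                "the maximum-likelihood odds ratio is infinite or zero"
            )

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SeparationError(f"information matrix singular: {exc}")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise SeparationError("IRLS failed to converge")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = math.sqrt(cov[1, 1])
    z = beta[1] / se
    return {
        "coef": float(beta[1]),
        "intercept": float(beta[0]),
        "or": math.exp(beta[1]),
        "ci_low": math.exp(beta[1] - Z_95 * se),
        "ci_high": math.exp(beta[1] + Z_95 * se),
        "pvalue": float(2.0 * sps.norm.sf(abs(z))),
        "se": se,
    }


def welch_t_test(x: Sequence[float], y: Sequence[float]):
    """Welch unequal-variance t-test (two-sided).

    Degenerate zero-variance-in-both samples are resolved by
    convention: p = 1 when the means agree, p = 0 otherwise, with a
    ``degenerate`` flag in the result.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if xa.var(ddof=1) == 0.0 and ya.var(ddof=1) == 0.0:
        equal = xa.mean() == ya.mean()
        return {
            "t": 0.0 if equal else math.inf * np.sign(xa.mean() - ya.mean()),
            "df": float(len(xa) + len(ya) - 2),
            "pvalue": 1.0 if equal else 0.0,
            "degenerate": True,
        }
    res = sps.ttest_ind(xa, ya, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "pvalue": float(res.pvalue),
        "degenerate": False,
    }


def proportion_ratio(x_yes: int, x_n: int, y_yes: int, y_n: int):
    """Ratio of two proportions with the Katz log-ratio 95% CI.

    A zero numerator proportion gives ratio 0 with an undefined CI; a
    zero denominator proportion leaves the ratio undefined.
    """
    if x_n <= 0 or y_n <= 0:
        raise ValueError("denominators must be positive")
    px = x_yes / x_n
    py = y_yes / y_n
    if y_yes == 0:
        return {"ratio": None, "ci_low": None, "ci_high": None}
    ratio = px / py
    if x_yes == 0:
        return {"ratio": 0.0, "ci_low": None, "ci_high": None}
    se = math.sqrt(1.0 / x_yes - 1.0 / x_n + 1.0 / y_yes - 1.0 / y_n)
    log_r = math.log(ratio)
    return {
        "ratio": ratio,
        "ci_low": math.exp(log_r - Z_95 * se),
        "ci_high": math.exp(log_r + Z_95 * se),
    }


def _classify_frame(df: pd.DataFrame, spec: FailureRateSpec):
    constants = compute_constants(spec)
    series = series_from_frame(df)
    results = [classify(s, constants) for s in series]
    groups = {s.trainee_id: s.group for s in series}
    return series, results, groups


def compare_cohorts(
    df: pd.DataFrame,
    spec: FailureRateSpec,
    *,
    study_label: str = "study",
    control_label: str = "control",
) -> CohortComparison:
    """Classify every trainee and compare the two arms at one setting."""
    _, results, groups = _classify_frame(df, spec)
    by_arm = {study_label: [], control_label: []}
    for r in results:
        arm = groups[r.trainee_id]
        if arm not in by_arm:
            raise ValueError(f"unexpected group label {arm!r}")
        by_arm[arm].append(r)

    s_res, c_res = by_arm[study_label], by_arm[control_label]
    table = ContingencyTable2x2(
        study_yes=sum(r.competent for r in s_res),
        study_no=sum(not r.competent for r in s_res),
        control_yes=sum(r.competent for r in c_res),
        control_no=sum(not r.competent for r in c_res),
    )
    or_res = odds_ratio(table)
    att_s = attempts_to_competence(s_res)
    att_c = attempts_to_competence(c_res)

    notes = []
    if or_res["corrected"]:
        notes.append("odds ratio used Haldane-Anscombe 0.5 correction")
    t_stat = p_att = None
    if att_s["n"] >= 2 and att_c["n"] >= 2:
        xs = [r.crossing_attempt for r in s_res if r.competent]
        ys = [r.crossing_attempt for r in c_res if r.competent]
        welch = welch_t_test(xs, ys)
        t_stat, p_att = welch["t"], welch["pvalue"]
        if welch["degenerate"]:
            notes.append("attempts t-test degenerate (zero variance)")
    else:
        notes.append("too few achievers for attempts t-test")

    return CohortComparison(
        table=table,
        odds_ratio=or_res["or"],
        or_ci_low=or_res["ci_low"],
        or_ci_high=or_res["ci_high"],
        or_pvalue=or_res["pvalue"],
        attempts_study=att_s,
        attempts_control=att_c,
        attempts_t=t_stat,
        attempts_pvalue=p_att,
        continuity_corrected=or_res["corrected"],
        notes=notes,
    )


def sensitivity_grid(
    df: pd.DataFrame,
    settings: Sequence[tuple[float, float]],
    alpha: float,
    beta: float,
    **kwargs,
) -> list[SensitivityRow]:
    """Re-run the full cohort comparison at each (p0, p1) setting."""
    if not settings:
        raise ValueError("settings must be non-empty")
    rows = []
    for p0, p1 in settings:
        spec = FailureRateSpec(p0=p0, p1=p1, alpha=alpha, beta=beta)
        rows.append(
            SensitivityRow(
                p0=p0, p1=p1, comparison=compare_cohorts(df, spec, **kwargs)
            )
        )
    return rows
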