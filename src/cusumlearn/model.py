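"""Model/Results interface for the CUSUM learning-curve analysis.

``CusumLearningCurve`` is built from per-attempt data plus a boundary
design and behaves like a statistical model object: ``fit()``
classifies every trainee against the SPRT control lines and, when two
cohorts are present, compares them, returning a ``CusumResults``
carrying per-trainee verdicts, the cohort comparison, a ``summary()``
table, the sensitivity grid and chart exports.

Examples
--------
>>> from cusumlearn import CusumLearningCurve, FailureRateSpec, default_design
>>> from cusumlearn.synthetic import simulate_cohort_frame
>>> data = simulate_cohort_frame(default_design(seed=1))
>>> res = CusumLearningCurve(data, FailureRateSpec(0.10, 0.30, 0.10, 0.10)).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .boundaries import FailureRateSpec, SprtConstants, compute_constants
from .cohort_stats import (
    CohortComparison,
    SensitivityRow,
    compare_cohorts,
    sensitivity_grid,
)
from .io import read_attempts, validate_attempts
from .learning_curve import (
    CompetenceResult,
    TraineeSeries,
    chart_table,
    classify,
    series_from_frame,
)

__all__ = ["CusumLearningCurve", "CusumResults"]


class CusumLearningCurve:
    """CUSUM/SPRT competency model for per-attempt binary outcomes.

    Parameters
    ----------
    data : pandas.DataFrame
        Attempt table with columns trainee_id, group, attempt_no,
        score (0 = success, 1 = failure).
    spec : FailureRateSpec
        Boundary design (p0, p1, alpha, beta).
    study_label, control_label : str
        Which group label is the intervention arm and which the
        reference arm (defaults "study" / "control").
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: FailureRateSpec,
        *,
        study_label: str = "study",
        control_label: str = "control",
    ):
        self.data = validate_attempts(data)
        self.spec = spec
        self.study_label = study_label
        self.control_label = control_label
        self.constants: SprtConstants = compute_constants(spec)

    @classmethod
    def from_csv(cls, path, spec: FailureRateSpec, **kwargs) -> "CusumLearningCurve":
        """Build the model from an attempt CSV on disk."""
        return cls(read_attempts(path), spec, **kwargs)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def fit(self) -> "CusumResults":
        """Classify all trainees and (if two arms) compare the cohorts."""
        series = series_from_frame(self.data)
        results = [classify(s, self.constants) for s in series]
        comparison = None
        if len(self.groups) == 2:
            comparison = compare_cohorts(
                self.data,
                self.spec,
                study_label=self.study_label,
                control_label=self.control_label,
            )
        return CusumResults(self, series, results, comparison)


@dataclass
class CusumResults:
    """Fitted results: per-trainee verdicts plus the cohort comparison."""

    model: CusumLearningCurve
    series: list[TraineeSeries]
    trainee_results: list[CompetenceResult]
    comparison: Optional[CohortComparison]

    @property
    def trainee_table(self) -> pd.DataFrame:
        """Per-trainee verdict table."""
        groups = {s.trainee_id: s.group for s in self.series}
        return pd.DataFrame(
            {
                "trainee_id": [r.trainee_id for r in self.trainee_results],
                "group": [groups[r.trainee_id] for r in self.trainee_results],
                "status": [r.status for r in self.trainee_results],
                "crossing_attempt": [
                    r.crossing_attempt for r in self.trainee_results
                ],
                "n_attempts": [r.n_attempts for r in self.trainee_results],
            }
        )

    def chart_table(self, trainee_id: str) -> pd.DataFrame:
        """Per-attempt chart data (n, cumsum, h0, h1) for one trainee."""
        for s in self.series:
            if s.trainee_id == trainee_id:
                return chart_table(s, self.model.constants)
        raise KeyError(f"unknown trainee {trainee_id!r}")

    def sensitivity(
        self, settings: Sequence[tuple[float, float]]
    ) -> list[SensitivityRow]:
        """Re-run the comparison across a grid of (p0, p1) settings."""
        if len(self.model.groups) != 2:
            raise ValueError("sensitivity analysis requires two cohorts")
        return sensitivity_grid(
            self.model.data,
            settings,
            self.model.spec.alpha,
            self.model.spec.beta,
            study_label=self.model.study_label,
            control_label=self.model.control_label,
        )

    def sensitivity_frame(
        self, settings: Sequence[tuple[float, float]]
    ) -> pd.DataFrame:
        """Sensitivity grid flattened to one row per setting."""
        rows = []
        for row in self.sensitivity(settings):
            d = row.comparison.to_dict()
            att_s, att_c = d.pop("attempts_study"), d.pop("attempts_control")
            d.pop("notes")
            rows.append(
                {
                    "p0": row.p0,
                    "p1": row.p1,
                    **d,
                    "attempts_study_mean": att_s["mean"],
                    "attempts_study_sd": att_s["sd"],
                    "attempts_control_mean": att_c["mean"],
                    "attempts_control_sd": att_c["sd"],
                }
            )
        return pd.DataFrame(rows)

    def plot_trainee(self, trainee_id: str, ax=None):
        """Cumulative-failure chart with control lines for one trainee."""
        from .plotting import plot_cusum_chart

        return plot_cusum_chart(self.chart_table(trainee_id), trainee_id, ax=ax)

    def to_dict(self) -> dict:
        """Machine-readable report structure."""
        spec = self.model.spec
        out = {
            "design": {
                "p0": spec.p0,
                "p1": spec.p1,
                "alpha": spec.alpha,
                "beta": spec.beta,
            },
            "constants": self.model.constants.to_config(),
            "trainees": self.trainee_table.to_dict(orient="records"),
            "comparison": (
                self.comparison.to_dict() if self.comparison is not None
                else "not estimable (fewer than two cohorts)"
            ),
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        """Aligned text summary of the fitted analysis."""
        spec = self.model.spec
        c = self.model.constants
        lines = [
            "CUSUM learning-curve analysis",
            "=" * 60,
            f"Boundary design: p0={spec.p0:g}  p1={spec.p1:g}  "
            f"alpha={spec.alpha:g}  beta={spec.beta:g}",
            f"Control lines:   h0(n) = {c.s:.5f} n - {c.h0_intercept:.5f}",
            f"                 h1(n) = {c.s:.5f} n + {c.h1_intercept:.5f}",
            "-" * 60,
        ]
        tab = self.trainee_table
        counts = tab.groupby(["group", "status"]).size()
        for group in self.model.groups:
            n = (tab["group"] == group).sum()
            comp = counts.get((group, "competent"), 0)
            unac = counts.get((group, "unacceptable"), 0)
            lines.append(
                f"{group:>10}: n={n:<3d} competent={comp:<3d} "
                f"unacceptable={unac:<3d} indeterminate={n - comp - unac}"
            )
        if self.comparison is not None:
            cmp_ = self.comparison
            lines.append("-" * 60)
            if cmp_.odds_ratio is None:
                lines.append("Odds ratio: not estimable (empty margin)")
            else:
                lines.append(
                    f"Achievement OR (study vs control): {cmp_.odds_ratio:.3g} "
                    f"(95% CI {cmp_.or_ci_low:.3g}-{cmp_.or_ci_high:.3g}, "
                    f"p={cmp_.or_pvalue:.3g})"
                )
            for name, att in (
                ("study", cmp_.attempts_study),
                ("control", cmp_.attempts_control),
            ):
                if att["n"]:
                    lines.append(
                        f"Attempts to competence, {name}: "
                        f"{att['mean']:.1f} (±{att['sd']:.1f}), n={att['n']}"
                    )
            if cmp_.attempts_pvalue is not None:
                lines.append(
                    f"Attempts Welch t-test: t={cmp_.attempts_t:.3f}, "
                    f"p={cmp_.attempts_pvalue:.3g}"
                )
            for note in cmp_.notes:
                lines.append(f"note: {note}")
        else:
            lines.append("Cohort comparison: not estimable (single group)")
        lines.append("=" * 60)
        return "\n".join(lines)
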