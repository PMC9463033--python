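"""End-to-end analysis pipeline: config in, report files out.

``run_analysis`` ties the pieces together: read and validate the
attempt CSV, fit the model at the primary boundary setting, run the
sensitivity grid, and write a JSON report, an aligned-text report, and
(optionally) per-trainee chart tables and images into the output
directory.  Reports are reproducible bit-for-bit given fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .boundaries import FailureRateSpec
from .model import CusumLearningCurve, CusumResults

logger = logging.getLogger("cusumlearn")

DEFAULT_SENSITIVITY = [
    (0.10, 0.30),
    (0.10, 0.40),
    (0.20, 0.30),
    (0.20, 0.35),
    (0.20, 0.40),
]

__all__ = ["AnalysisConfig", "run_analysis", "DEFAULT_SENSITIVITY"]


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs."""

    spec: FailureRateSpec
    input_path: Path
    output_dir: Path
    sensitivity_settings: Sequence[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_SENSITIVITY)
    )
    chart_export: bool = False
    study_label: str = "study"
    control_label: str = "control"

    def __post_init__(self) -> None:
        self.input_path = Path(self.input_path)
        self.output_dir = Path(self.output_dir)
        for p0, p1 in self.sensitivity_settings:
            if not p0 < p1:
                raise ValueError(f"sensitivity setting needs p0 < p1; got ({p0}, {p1})")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        """Load a flat YAML config (keys mirror the dataclass fields)."""
        raw = yaml.safe_load(Path(path).read_text())
        spec = FailureRateSpec(
            p0=float(raw["p0"]),
            p1=float(raw["p1"]),
            alpha=float(raw.get("alpha", 0.10)),
            beta=float(raw.get("beta", 0.10)),
        )
        settings = [
            (float(a), float(b))
            for a, b in raw.get("sensitivity_settings", DEFAULT_SENSITIVITY)
        ]
        return cls(
            spec=spec,
            input_path=raw["input_path"],
            output_dir=raw["output_dir"],
            sensitivity_settings=settings,
            chart_export=bool(raw.get("chart_export", False)),
            study_label=str(raw.get("study_label", "study")),
            control_label=str(raw.get("control_label", "control")),
        )


def _sensitivity_text(results: CusumResults, settings) -> str:
    df = results.sensitivity_frame(settings)
    lines = [
        "Sensitivity to boundary settings",
        f"{'p0':>5} {'p1':>5} {'study':>12} {'control':>12} "
        f"{'OR (95% CI)':>22} {'p':>8} {'att study':>12} {'att control':>12}",
    ]
    for _, r in df.iterrows():
        or_txt = (
            f"{r['odds_ratio']:.3g} ({r['or_ci_low']:.3g}-{r['or_ci_high']:.3g})"
            if r["odds_ratio"] is not None
            else "n/e"
        )
        att_s = (
            f"{r['attempts_study_mean']:.0f} (±{r['attempts_study_sd']:.0f})"
            if r["attempts_study_mean"] is not None
            else "-"
        )
        att_c = (
            f"{r['attempts_control_mean']:.0f} (±{r['attempts_control_sd']:.0f})"
            if r["attempts_control_mean"] is not None
            else "-"
        )
        p_txt = f"{r['or_pvalue']:.3g}" if r["or_pvalue"] is not None else "n/e"
        lines.append(
            f"{r['p0']:>5.2f} {r['p1']:>5.2f} "
            f"{r['study_yes']:>3d} ({r['study_pct']:>3d}%) "
            f"{r['control_yes']:>3d} ({r['control_pct']:>3d}%) "
            f"{or_txt:>22} {p_txt:>8} {att_s:>12} {att_c:>12}"
        )
    return "\n".join(lines)


def run_analysis(config: AnalysisConfig) -> CusumResults:
    """Run the full pipeline and write reports under ``output_dir``."""
    model = CusumLearningCurve.from_csv(
        config.input_path,
        config.spec,
        study_label=config.study_label,
        control_label=config.control_label,
    )
    results = model.fit()

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    report = results.to_dict()
    two_arms = len(model.groups) == 2
    if two_arms:
        sens = results.sensitivity_frame(config.sensitivity_settings)
        report["sensitivity"] = sens.to_dict(orient="records")

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    text = results.summary()
    if two_arms:
        text += "\n\n" + _sensitivity_text(results, config.sensitivity_settings)
    (out / "report.txt").write_text(text + "\n")
    results.trainee_table.to_csv(out / "trainees.csv", index=False)

    if config.chart_export:
        chart_dir = out / "charts"
        chart_dir.mkdir(exist_ok=True)
        import matplotlib.pyplot as plt

        for s in results.series:
            results.chart_table(s.trainee_id).to_csv(
                chart_dir / f"{s.trainee_id}.csv", index=False
            )
            ax = results.plot_trainee(s.trainee_id)
            ax.figure.savefig(chart_dir / f"{s.trainee_id}.png", dpi=100)
            plt.close(ax.figure)
    logger.info("analysis written to %s", out)
    return results
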