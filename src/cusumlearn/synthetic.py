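"""Synthetic per-attempt outcome generator for two trainee cohorts.

The latent learning process is an exponential decay of the per-attempt
failure probability,

    p(i) = p_floor + (p_start - p_floor) * exp(-(i - 1) / tau_t),

with trainee-specific time constant ``tau_t = tau * exp(eps)``,
``eps ~ Normal(0, heterogeneity_sd)``.  The score of attempt ``i`` is a
Bernoulli draw at ``p(i)``.  This is the simplest monotone learning
model consistent with the analysis' assumptions: failure probability
declines with experience towards an asymptote, cohorts differ in
learning speed, and trainees within a cohort are heterogeneous.

Default cohort: two arms of 21 trainees over a 60-attempt rotation,
with the study arm learning faster (tau = 3 vs 7 attempts), calibrated
so that at the (p0=0.10, p1=0.30, alpha=beta=0.10) boundary the arms
achieve competence at roughly 2/3 vs 2/5 — the regime the analysis is
designed for.

Seeding: one integer seed expands to per-trainee substreams through
``numpy.random.SeedSequence(seed, spawn_key=(arm, index))``, so adding
trainees or arms never perturbs earlier trainees' outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .boundaries import FailureRateSpec, compute_constants
from .learning_curve import AttemptRecord, classify_paths

__all__ = [
    "LearnerModel",
    "CohortDesign",
    "default_design",
    "simulate_trainee",
    "simulate_cohort",
    "simulate_cohort_frame",
    "simulate_arm_scores",
    "achievement_counts",
    "effect_replicates",
    "operating_characteristics",
]


@dataclass(frozen=True)
class LearnerModel:
    """Latent learning-curve parameters for one cohort.

    Parameters
    ----------
    p_start : float
        Failure probability at the first attempt.
    p_floor : float
        Asymptotic failure probability, ``0 <= p_floor <= p_start <= 1``.
    tau : float
        Learning time constant, in attempts; smaller is faster.
    n_attempts : int
        Attempts available in the rotation.
    heterogeneity_sd : float
        SD of the per-trainee log-tau perturbation (0 disables it).
    """

    p_start: float
    p_floor: float
    tau: float
    n_attempts: int = 60
    heterogeneity_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_floor <= self.p_start <= 1.0):
            raise ValueError(
                f"need 0 <= p_floor <= p_start <= 1; "
                f"got p_floor={self.p_floor}, p_start={self.p_start}"
            )
        if self.tau <= 0:
            raise ValueError(f"tau must be positive; got {self.tau}")
        if self.n_attempts < 1:
            raise ValueError(f"n_attempts must be >= 1; got {self.n_attempts}")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")

    def failure_curve(self, tau_t: float) -> np.ndarray:
        """Per-attempt failure probabilities for time constant tau_t."""
        i = np.arange(1, self.n_attempts + 1)
        return self.p_floor + (self.p_start - self.p_floor) * np.exp(
            -(i - 1) / tau_t
        )


@dataclass(frozen=True)
class CohortDesign:
    """Two-arm simulation design."""

    n_per_group: int
    study_model: LearnerModel
    control_model: LearnerModel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def default_design(seed: int = 0, n_per_group: int = 21) -> CohortDesign:
    """The calibrated study-scale design (see module docstring)."""
    shared = dict(p_start=0.5, p_floor=0.04, n_attempts=60, heterogeneity_sd=0.3)
    return CohortDesign(
        n_per_group=n_per_group,
        study_model=LearnerModel(tau=3.0, **shared),
        control_model=LearnerModel(tau=7.0, **shared),
        seed=seed,
    )


def _trainee_rng(seed: int, arm_index: int, trainee_index: int):
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(arm_index, trainee_index))
    )


def _draw_scores(model: LearnerModel, rng) -> np.ndarray:
    eps = rng.normal(0.0, model.heterogeneity_sd) if model.heterogeneity_sd else 0.0
    tau_t = model.tau * np.exp(eps)
    p = model.failure_curve(tau_t)
    return (rng.random(model.n_attempts) < p).astype(np.int64)


def simulate_trainee(
    model: LearnerModel,
    trainee_id: str,
    group: str,
    rng,
) -> list[AttemptRecord]:
    """Draw one trainee's attempt records from the learning model."""
    scores = _draw_scores(model, rng)
    return [
        AttemptRecord(
            trainee_id=trainee_id,
            group=group,
            attempt_no=i + 1,
            score=int(s),
        )
        for i, s in enumerate(scores)
    ]


def simulate_cohort(design: CohortDesign) -> list[AttemptRecord]:
    """Draw the full two-arm cohort; deterministic under a fixed seed."""
    records: list[AttemptRecord] = []
    arms = [("study", design.study_model, 0), ("control", design.control_model, 1)]
    for group, model, arm_idx in arms:
        for t in range(design.n_per_group):
            rng = _trainee_rng(design.seed, arm_idx, t)
            tid = f"{group[0].upper()}{t + 1:02d}"
            records.extend(simulate_trainee(model, tid, group, rng))
    return records


def simulate_cohort_frame(design: CohortDesign) -> pd.DataFrame:
    """Cohort as the canonical attempt table (one row per attempt)."""
    recs = simulate_cohort(design)
    return pd.DataFrame(
        {
            "trainee_id": [r.trainee_id for r in recs],
            "group": [r.group for r in recs],
            "attempt_no": [r.attempt_no for r in recs],
            "score": [r.score for r in recs],
        }
    )


def simulate_arm_scores(
    model: LearnerModel, seed: int, arm_index: int, n_trainees: int
) -> np.ndarray:
    """Score matrix (trainees x attempts) for one arm.

    Bit-for-bit identical to the per-record path: row ``t`` uses the
    same substream as trainee ``t`` of ``simulate_cohort``.
    """
    return np.vstack(
        [
            _draw_scores(model, _trainee_rng(seed, arm_index, t))
            for t in range(n_trainees)
        ]
    )


def achievement_counts(design: CohortDesign, spec: FailureRateSpec) -> dict:
    """Competent-trainee counts per arm for one simulated cohort.

    Fast path for replicate studies; agrees exactly with classifying
    the output of ``simulate_cohort`` trainee by trainee.
    """
    constants = compute_constants(spec)
    counts = {}
    for group, model, arm_idx in (
        ("study", design.study_model, 0),
        ("control", design.control_model, 1),
    ):
        scores = simulate_arm_scores(model, design.seed, arm_idx, design.n_per_group)
        status, _ = classify_paths(np.cumsum(scores, axis=1), constants)
        counts[group] = int(np.sum(status == "competent"))
    return counts


def effect_replicates(
    spec: FailureRateSpec,
    n_per_group: int,
    n_reps: int,
    seed: int,
    design_factory=None,
) -> pd.DataFrame:
    """Achievement counts over repeated simulated cohorts.

    Each replicate draws a fresh cohort (seeds ``seed .. seed+n_reps-1``
    passed to ``design_factory``, default :func:`default_design`) and
    records the per-arm competent counts at the ``spec`` boundary.

    Returns
    -------
    DataFrame with columns seed, study_yes, control_yes, n_per_group.
    """
    if design_factory is None:
        design_factory = default_design
    rows = []
    for r in range(n_reps):
        design = design_factory(seed=seed + r, n_per_group=n_per_group)
        counts = achievement_counts(design, spec)
        rows.append(
            {
                "seed": seed + r,
                "study_yes": counts["study"],
                "control_yes": counts["control"],
                "n_per_group": n_per_group,
            }
        )
    return pd.DataFrame(rows)


def operating_characteristics(
    failure_rate: float,
    spec: FailureRateSpec,
    n_attempts: int,
    n_reps: int,
    seed: int = 0,
):
    """Empirical classification probabilities at a constant failure rate.

    Simulates ``n_reps`` trainees whose every attempt fails with the
    same probability, classifies each against the boundaries for
    ``spec``, and returns the observed proportion of each verdict —
    the Monte-Carlo analogue of the designed error rates: at
    ``failure_rate = p0`` the unacceptable proportion estimates the
    realised type-I error, at ``p1`` the competent proportion estimates
    the realised type-II error.

    Returns
    -------
    dict with keys ``prop_competent``, ``prop_unacceptable``,
    ``prop_indeterminate``.
    """
    if not (0.0 <= failure_rate <= 1.0):
        raise ValueError("failure_rate must lie in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    constants = compute_constants(spec)
    rng = np.random.default_rng(seed)
    scores = (rng.random((n_reps, n_attempts)) < failure_rate).astype(np.int64)
    status, _ = classify_paths(np.cumsum(scores, axis=1), constants)
    return {
        "prop_competent": float(np.mean(status == "competent")),
        "prop_unacceptable": float(np.mean(status == "unacceptable")),
        "prop_indeterminate": float(np.mean(status == "indeterminate")),
    }
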