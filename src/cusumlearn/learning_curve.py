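"""Per-trainee cumulative-failure series and competence classification.

Each attempt is a binary score (0 = success, 1 = failure).  The running
sum of scores is charted against the attempt number and compared with
the two SPRT control lines: the first attempt at which the cumulative
failure count falls on or below the lower line declares the trainee
competent; the first at which it rises on or above the upper line
declares performance unacceptable; a series that meets neither boundary
is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .boundaries import SprtConstants, boundary_values

__all__ = [
    "AttemptRecord",
    "TraineeSeries",
    "CompetenceResult",
    "build_series",
    "classify",
    "classify_paths",
    "attempts_to_competence",
    "chart_table",
]

# Integer-valued paths meet real-valued lines; an analytically exact
# touch (e.g. all failures at p0=0.1, p1=0.3, alpha=beta=0.1, where
# a = 2P makes the path meet the upper line exactly at n = 2) must not
# be lost to rounding, so comparisons carry a tiny absolute slack.
BOUNDARY_ATOL = 1e-12

COMPETENT = "competent"
UNACCEPTABLE = "unacceptable"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class AttemptRecord:
    """One procedural attempt: trainee, cohort, attempt index, outcome."""

    trainee_id: str
    group: str
    attempt_no: int
    score: int

    def __post_init__(self) -> None:
        if self.score not in (0, 1):
            raise ValueError(
                f"score must be 0 (success) or 1 (failure); got {self.score!r}"
            )
        if self.attempt_no < 1:
            raise ValueError(f"attempt_no must be >= 1; got {self.attempt_no}")


@dataclass(frozen=True)
class TraineeSeries:
    """Ordered outcomes and their running failure count for one trainee."""

    trainee_id: str
    group: str
    scores: np.ndarray
    cumsum: np.ndarray

    @property
    def n_attempts(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class CompetenceResult:
    """Boundary-crossing verdict for one trainee's series."""

    trainee_id: str
    status: str
    crossing_attempt: Optional[int]
    n_attempts: int

    @property
    def competent(self) -> bool:
        return self.status == COMPETENT


def build_series(records: Iterable[AttemptRecord]) -> TraineeSeries:
    """Order one trainee's attempts and accumulate failures.

    Raises
    ------
    ValueError
        If the record set is empty, mixes trainees, or the attempt
        numbers are not consecutive from 1.
    """
    recs = sorted(records, key=lambda r: r.attempt_no)
    if not recs:
        raise ValueError("cannot build a series from an empty record set")
    ids = {r.trainee_id for r in recs}
    if len(ids) > 1:
        raise ValueError(f"records mix multiple trainees: {sorted(ids)}")
    for expected, rec in enumerate(recs, start=1):
        if rec.attempt_no != expected:
            raise ValueError(
                f"trainee {rec.trainee_id!r}: attempt numbers must run 1..N "
                f"without gaps or duplicates; expected {expected}, "
                f"found {rec.attempt_no}"
            )
    scores = np.array([r.score for r in recs], dtype=np.int64)
    return TraineeSeries(
        trainee_id=recs[0].trainee_id,
        group=recs[0].group,
        scores=scores,
        cumsum=np.cumsum(scores),
    )


def classify_paths(cumsum: np.ndarray, constants: SprtConstants):
    """Vectorised first-crossing scan for one or many failure paths.

    Parameters
    ----------
    cumsum : ndarray, shape (n,) or (m, n)
        Cumulative failure counts at attempts 1..n (rows are paths).
    constants : SprtConstants

    Returns
    -------
    status : ndarray of str, shape (m,)
    crossing : ndarray of int, shape (m,)
        First crossing attempt (1-based); -1 where indeterminate.

    Notes
    -----
    At an attempt where both boundaries are met the lower (acceptable)
    line wins: the favourable-to-trainee tie-break.
    """
    cs = np.atleast_2d(np.asarray(cumsum))
    n = cs.shape[1]
    attempts = np.arange(1, n + 1)
    h0, h1 = boundary_values(constants, attempts)
    below = cs <= h0 + BOUNDARY_ATOL
    above = cs >= h1 - BOUNDARY_ATOL
    big = n + 1  # sentinel beyond any valid attempt
    first_lo = np.where(below.any(axis=1), below.argmax(axis=1) + 1, big)
    first_hi = np.where(above.any(axis=1), above.argmax(axis=1) + 1, big)
    status = np.full(cs.shape[0], INDETERMINATE, dtype=object)
    status[first_lo <= first_hi] = COMPETENT
    status[first_hi < first_lo] = UNACCEPTABLE
    status[(first_lo == big) & (first_hi == big)] = INDETERMINATE
    crossing = np.where(first_lo <= first_hi, first_lo, first_hi)
    crossing[crossing == big] = -1
    return status, crossing


def classify(series: TraineeSeries, constants: SprtConstants) -> CompetenceResult:
    """Classify one trainee by first boundary crossing.

    Scans attempts in order; the verdict is terminal at the first
    crossing and later recrossings are ignored.
    """
    status, crossing = classify_paths(series.cumsum, constants)
    cross = int(crossing[0])
    return CompetenceResult(
        trainee_id=series.trainee_id,
        status=str(status[0]),
        crossing_attempt=None if cross < 0 else cross,
        n_attempts=series.n_attempts,
    )


def attempts_to_competence(results: Iterable[CompetenceResult]) -> dict:
    """Mean and SD of the competence crossing attempt over achievers.

    Returns a dict with keys ``mean``, ``sd``, ``n`` and a
    ``degenerate`` flag.  With no competent trainee the summary is
    empty (``n=0``, mean/sd None); with a single one, ``sd`` is
    reported as 0.0 and flagged degenerate.
    """
    crossings = [
        r.crossing_attempt for r in results if r.status == COMPETENT
    ]
    if not crossings:
        return {"mean": None, "sd": None, "n": 0, "degenerate": True}
    arr = np.asarray(crossings, dtype=float)
    if len(arr) == 1:
        return {"mean": float(arr[0]), "sd": 0.0, "n": 1, "degenerate": True}
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)),
        "n": len(arr),
        "degenerate": False,
    }


def chart_table(series: TraineeSeries, constants: SprtConstants) -> pd.DataFrame:
    """Per-attempt chart data: n, cumulative failures, h0(n), h1(n)."""
    n = np.arange(1, series.n_attempts + 1)
    h0, h1 = boundary_values(constants, n)
    return pd.DataFrame(
        {
            "attempt_no": n,
            "cum_failures": series.cumsum,
            "h0": h0,
            "h1": h1,
        }
    )


def series_from_frame(df: pd.DataFrame) -> list[TraineeSeries]:
    """Split a validated attempt table into per-trainee series.

    ``df`` must carry columns trainee_id, group, attempt_no, score;
    grouping preserves first-appearance order of trainees.
    """
    out: list[TraineeSeries] = []
    for tid, sub in df.groupby("trainee_id", sort=False):
        records = [
            AttemptRecord(
                trainee_id=str(tid),
                group=str(row.group),
                attempt_no=int(row.attempt_no),
                score=int(row.score),
            )
            for row in sub.itertuples(index=False)
        ]
        out.append(build_series(records))
    return out
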