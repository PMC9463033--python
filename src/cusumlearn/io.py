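"""Readers, writers and validation for the attempt-record table.

The on-disk format is a UTF-8 CSV with a header and the four columns
``trainee_id, group, attempt_no, score``; scores are 0 (success) or
1 (failure), exactly two group labels are allowed, and each trainee's
attempt numbers must run 1..N without gaps.  Validation errors cite
the offending data row (1-based, excluding the header).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("cusumlearn")

REQUIRED_COLUMNS = ["trainee_id", "group", "attempt_no", "score"]

__all__ = ["read_attempts", "write_attempts", "validate_attempts"]


def validate_attempts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory attempt table; returns a typed copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError("attempt table is empty")
    out = df[REQUIRED_COLUMNS].copy()
    out["trainee_id"] = out["trainee_id"].astype(str)
    out["group"] = out["group"].astype(str)

    for col in ("attempt_no", "score"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"row {row}: non-integer {col} {out[col].iloc[row - 1]!r}")
        out[col] = vals.astype(int)

    bad_score = ~out["score"].isin([0, 1])
    if bad_score.any():
        row = int(bad_score.idxmax()) + 1
        raise ValueError(
            f"row {row}: score must be 0 or 1, got {out['score'].iloc[row - 1]}"
        )

    labels = sorted(out["group"].unique())
    if len(labels) > 2:
        raise ValueError(f"more than two group labels: {labels}")

    for tid, sub in out.groupby("trainee_id", sort=False):
        attempts = sub.sort_values("attempt_no")["attempt_no"].to_numpy()
        expected = range(1, len(attempts) + 1)
        for got, want, idx in zip(attempts, expected, sub.index):
            if got != want:
                raise ValueError(
                    f"row {int(idx) + 1}: trainee {tid!r} attempt numbers must "
                    f"run 1..N; expected {want}, found {got}"
                )
        if len(sub["group"].unique()) > 1:
            raise ValueError(f"trainee {tid!r} appears in multiple groups")
    return out


def read_attempts(path) -> pd.DataFrame:
    """Load and validate an attempt CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    logger.info("read %d rows from %s", len(df), path)
    return validate_attempts(df)


def write_attempts(df: pd.DataFrame, path) -> None:
    """Write an attempt table as the canonical CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[REQUIRED_COLUMNS].to_csv(path, index=False)
    logger.info("wrote %d rows to %s", len(df), path)
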