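import numpy as np
import pandas as pd
import pytest

from cusumlearn import FailureRateSpec, compute_constants, default_design
from cusumlearn.synthetic import simulate_cohort_frame


@pytest.fixture(scope="session")
def primary_spec():
    """The study's primary boundary design."""
    return FailureRateSpec(p0=0.10, p1=0.30, alpha=0.10, beta=0.10)


@pytest.fixture(scope="session")
def primary_constants(primary_spec):
    return compute_constants(primary_spec)


@pytest.fixture(scope="session")
def cohort_frame():
    """One simulated two-arm cohort at the calibrated defaults."""
    return simulate_cohort_frame(default_design(seed=7))


def make_frame(trainee_scores: dict, groups: dict | None = None) -> pd.DataFrame:
    """Attempt table from {trainee_id: score sequence}."""
    rows = []
    for tid, scores in trainee_scores.items():
        grp = (groups or {}).get(tid, "study")
        for i, s in enumerate(scores, start=1):
            rows.append(
                {"trainee_id": tid, "group": grp, "attempt_no": i, "score": s}
            )
    return pd.DataFrame(rows)


def engineered_cohort(study_yes, study_n, control_yes, control_n, n_attempts=60):
    """Cohort in which achievement counts are known by construction.

    Achievers are all-success trainees (cross the lower line as early
    as possible); non-achievers alternate failure-heavy blocks that
    keep the path between the lines when possible.
    """
    rng = np.random.default_rng(123)
    trainee_scores, groups = {}, {}
    for grp, yes, n in (("study", study_yes, study_n),
                        ("control", control_yes, control_n)):
        for t in range(n):
            tid = f"{grp[0]}{t:02d}"
            groups[tid] = grp
            if t < yes:
                scores = [0] * n_attempts
            else:
                # ~30% failures keeps the path above h0 yet usually
                # below h1 only briefly; any non-competent status counts
                # as non-achievement, which is all the tables need.
                scores = list((rng.random(n_attempts) < 0.5).astype(int))
            trainee_scores[tid] = scores
    return make_frame(trainee_scores, groups)
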