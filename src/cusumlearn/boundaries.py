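"""SPRT-derived control boundaries for the cumulative-failure chart.

The chart monitors a trainee's running count of failed attempts ``S_n``
against the attempt number ``n``.  Competence is framed as a sequential
test between two Bernoulli failure rates: an *acceptable* rate ``p0``
(the competent-performer hypothesis) and an *unacceptable* rate ``p1``.
Wald's sequential probability ratio test (SPRT) with error rates
``alpha`` (falsely declaring an acceptable performer unacceptable) and
``beta`` (falsely declaring an unacceptable performer acceptable)
yields two parallel straight lines in the ``(n, S_n)`` plane:

    lower (acceptable)   h0(n) = s*n - b/(P+Q)
    upper (unacceptable) h1(n) = s*n + a/(P+Q)

with ``a = ln((1-beta)/alpha)``, ``b = ln((1-alpha)/beta)``,
``P = ln(p1/p0)``, ``Q = ln((1-p0)/(1-p1))`` and slope
``s = Q/(P+Q)``, which always lies strictly between ``p0`` and ``p1``.
A cumulative-failure path that reaches the lower line signals
acceptable performance; one that reaches the upper line signals
unacceptable performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FailureRateSpec",
    "SprtConstants",
    "compute_constants",
    "boundary_values",
]


@dataclass(frozen=True)
class FailureRateSpec:
    """The four design parameters of the sequential test.

    Parameters
    ----------
    p0 : float
        Acceptable failure rate, ``0 < p0 < p1``.
    p1 : float
        Unacceptable failure rate, ``p0 < p1 < 1``.
    alpha : float
        Type-I error rate (probability of flagging a competent
        performer as unacceptable), in ``(0, 1)``.
    beta : float
        Type-II error rate (probability of declaring an unacceptable
        performer competent), in ``(0, 1)``.
    """

    p0: float
    p1: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise ValueError(f"p0 must lie in (0, 1); got {self.p0}")
        if not (0.0 < self.p1 < 1.0):
            raise ValueError(f"p1 must lie in (0, 1); got {self.p1}")
        if not self.p0 < self.p1:
            raise ValueError(
                f"acceptable rate p0 must be below unacceptable rate p1; "
                f"got p0={self.p0}, p1={self.p1}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha}")
        if not (0.0 < self.beta < 1.0):
            raise ValueError(f"beta must lie in (0, 1); got {self.beta}")


@dataclass(frozen=True)
class SprtConstants:
    """Derived SPRT quantities and boundary geometry.

    ``a`` and ``b`` are the upper and lower log-likelihood-ratio
    thresholds, ``P`` and ``Q`` the log rate ratio and log survival
    ratio, ``s`` the common slope of the two control lines, and
    ``h0_intercept``/``h1_intercept`` the magnitudes of the lower and
    upper intercepts (the lines are ``s*n - h0_intercept`` and
    ``s*n + h1_intercept``).
    """

    a: float
    b: float
    P: float
    Q: float
    s: float
    h0_intercept: float
    h1_intercept: float

    def to_config(self) -> dict[str, float]:
        """Flat key/value block for inclusion in analysis reports."""
        return {
            "a": self.a,
            "b": self.b,
            "P": self.P,
            "Q": self.Q,
            "s": self.s,
            "h0_intercept": self.h0_intercept,
            "h1_intercept": self.h1_intercept,
        }


def compute_constants(spec: FailureRateSpec) -> SprtConstants:
    """Evaluate the SPRT constants for a boundary design.

    Parameters
    ----------
    spec : FailureRateSpec
        Validated design parameters.

    Returns
    -------
    SprtConstants

    Examples
    --------
    >>> c = compute_constants(FailureRateSpec(0.10, 0.30, 0.10, 0.10))
    >>> round(c.s, 5)
    0.18617
    """
    a = math.log((1.0 - spec.beta) / spec.alpha)
    b = math.log((1.0 - spec.alpha) / spec.beta)
    P = math.log(spec.p1 / spec.p0)
    Q = math.log((1.0 - spec.p0) / (1.0 - spec.p1))
    s = Q / (P + Q)
    return SprtConstants(
        a=a,
        b=b,
        P=P,
        Q=Q,
        s=s,
        h0_intercept=b / (P + Q),
        h1_intercept=a / (P + Q),
    )


def boundary_values(constants: SprtConstants, n):
    """Control-line ordinates at attempt number(s) ``n``.

    Parameters
    ----------
    constants : SprtConstants
    n : int or array-like of int
        Attempt number(s), each >= 1.

    Returns
    -------
    (h0, h1) : pair of floats or ndarrays
        Lower (acceptable) and upper (unacceptable) line values.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("attempt number n must be >= 1")
    h0 = constants.s * n_arr - constants.h0_intercept
    h1 = constants.s * n_arr + constants.h1_intercept
    if np.isscalar(n) or n_arr.ndim == 0:
        return float(h0), float(h1)
    return h0, h1
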