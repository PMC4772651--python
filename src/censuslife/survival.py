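"""Actuarial estimation of age-specific mortality and survivorship.

The estimator is the classical actuarial (life-table) method for interval
data with right censoring: within each one-year age class the censored
individuals are assumed on average to be at risk for half the interval, so
the at-risk count is adjusted to ``N_q.x = N_x - c_x / 2`` and mortality is
``q_x = dp_x / N_q.x``, with ``dp_x = d_x + p_x`` pooling permanent
disappearances into the deaths. Survivorship follows as the cumulative
product

    l_0 = 1,   l_x = prod_{i<x} (1 - q_i).

When the oldest individuals are still alive (right-censored), the table is
truncated at the last age class with an observed death: beyond it there is
no information about mortality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .census import AgeClassCounts, at_risk
from .errors import ComputationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "actuarial_mortality",
    "survivorship",
    "truncate_at_last_death",
    "apply_disappearance_policy",
]


@dataclass
class LifeTable:
    """A (possibly truncated) life table for one sex.

    All vectors cover ages ``0..omega`` inclusive. ``m`` (daughters per
    female per year) and its sample sizes ``N_m`` are present for female
    tables once the fertility stage has run; ``N_q`` is the
    censoring-adjusted at-risk vector. ``sex`` may be None for ground-truth
    tables.
    """

    sex: str | None
    q: np.ndarray
    l: np.ndarray
    m: np.ndarray | None
    N_q: np.ndarray | None
    N_m: np.ndarray | None
    omega: int

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.l = np.asarray(self.l, dtype=float)
        if self.m is not None:
            self.m = np.asarray(self.m, dtype=float)
        if self.N_q is not None:
            self.N_q = np.asarray(self.N_q, dtype=float)
        if self.N_m is not None:
            self.N_m = np.asarray(self.N_m, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.omega + 1
        if len(self.q) != n or len(self.l) != n:
            raise ValidationError(
                f"q and l must have length omega+1 = {n}; got "
                f"{len(self.q)} and {len(self.l)}"
            )
        finite = ~np.isnan(self.q)
        if np.any((self.q[finite] < 0) | (self.q[finite] > 1)):
            raise ValidationError("q entries must lie in [0, 1]")
        if not math.isclose(self.l[0], 1.0):
            raise ValidationError("l[0] must equal 1")
        if np.any(np.diff(self.l) > 1e-12):
            raise ValidationError("survivorship must be non-increasing")
        for x in range(self.omega):
            if not np.isnan(self.q[x]) and not math.isclose(
                self.l[x + 1], self.l[x] * (1.0 - self.q[x]), abs_tol=1e-9
            ):
                raise ValidationError(
                    f"l[{x + 1}] does not equal l[{x}] * (1 - q[{x}])"
                )
        if self.m is not None:
            if len(self.m) != n:
                raise ValidationError(f"m must have length {n}")
            if np.any(self.m < 0):
                raise ValidationError("m entries must be >= 0")


def actuarial_mortality(counts: AgeClassCounts) -> tuple[np.ndarray, np.ndarray]:
    """Censoring-adjusted mortality ``q_x`` with its sample sizes ``N_q.x``.

    Returns ``(q, N_q)`` over all tabulated classes. Classes with
    ``N_q = 0`` get ``q = NaN`` (no information); a ratio above 1 —
    possible under heavy within-class censoring — is clamped to 1 with a
    warning; deaths in a class with non-positive adjusted risk are a hard
    error.
    """
    N = at_risk(counts)
    dp = counts.dp
    N_q = N - counts.c / 2.0
    q = np.full(counts.n_classes, np.nan)
    for x in range(counts.n_classes):
        if dp[x] > 0 and N_q[x] <= 0:
            raise ComputationError(
                f"age {x}: {dp[x]} deaths/disappearances but adjusted "
                f"at-risk N_q = {N_q[x]} <= 0"
            )
        if N_q[x] > 0:
            q[x] = dp[x] / N_q[x]
            if q[x] > 1.0:
                logger.warning(
                    "q_%d = %.4f > 1 after censoring adjustment; clamped to 1",
                    x,
                    q[x],
                )
                q[x] = 1.0
        elif dp[x] == 0 and N[x] == 0:
            pass  # empty class: q stays undefined
    return q, N_q


def survivorship(q) -> np.ndarray:
    """Cumulative-product survivorship; ``l`` has length ``len(q) + 1``.

    The product stops at the first undefined (NaN) mortality: subsequent
    entries are NaN, since the table is not estimable past that age.
    """
    q = np.asarray(q, dtype=float)
    finite = ~np.isnan(q)
    if np.any((q[finite] < 0) | (q[finite] > 1)):
        raise ValidationError("q entries must lie in [0, 1]")
    l = np.empty(len(q) + 1)
    l[0] = 1.0
    stopped = False
    for x, qx in enumerate(q):
        if stopped or np.isnan(qx):
            stopped = True
            l[x + 1] = np.nan
        else:
            l[x + 1] = l[x] * (1.0 - qx)
    return l


def truncate_at_last_death(
    counts: AgeClassCounts, q: np.ndarray, l: np.ndarray
) -> LifeTable:
    """Truncate estimates at the last age class with an observed death.

    ``omega`` is the last class with ``dp > 0``; if survivorship reaches 0
    earlier, or the estimable table ends earlier (a class with no one at
    risk), ``omega`` is that age instead. Raises when there are no deaths
    at all (no mortality information).
    """
    q = np.asarray(q, dtype=float)
    l = np.asarray(l, dtype=float)
    dp = counts.dp
    if not np.any(dp > 0):
        raise ValidationError("no deaths or disappearances: empty life table")
    omega = int(np.max(np.flatnonzero(dp > 0)))
    nan_ix = np.flatnonzero(np.isnan(q))
    if nan_ix.size and nan_ix[0] <= omega:
        omega = int(nan_ix[0]) - 1
        if omega < 0:
            raise ValidationError("mortality undefined at age 0")
    zero_ix = np.flatnonzero(l[: omega + 1] == 0.0)
    if zero_ix.size:
        omega = int(zero_ix[0])
    N = at_risk(counts)
    N_q = (N - counts.c / 2.0)[: omega + 1]
    return LifeTable(
        sex=counts.sex,
        q=q[: omega + 1],
        l=l[: omega + 1],
        m=None,
        N_q=N_q,
        N_m=None,
        omega=omega,
    )


def apply_disappearance_policy(counts: AgeClassCounts, policy: str) -> AgeClassCounts:
    """Route permanent disappearances into the mortality numerator
    (``"deaths"``, the default, which avoids underestimating mortality) or
    into the censored column (``"censored"``, which can grossly
    underestimate it for a heavily-dispersing sex; logged as a caution)."""
    if policy == "deaths":
        return counts
    if policy == "censored":
        logger.warning(
            "treating %d permanent disappearances as censored: mortality of "
            "a dispersing sex may be greatly underestimated",
            int(counts.p.sum()),
        )
        return AgeClassCounts(
            sex=counts.sex,
            t=counts.t,
            d=counts.d,
            p=np.zeros_like(counts.p),
            c=counts.c + counts.p,
        )
    raise ValidationError(f"unknown disappearance policy {policy!r}")
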