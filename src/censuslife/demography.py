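"""Leslie-matrix and closed-form population statistics from a female life table.

Given survivorship ``l_x`` and daughter fertility ``m_x`` up to the
truncation age ``omega``, this module computes:

* the net reproductive rate ``R0 = sum_x l_x m_x`` (lifetime daughters per
  newborn female) and the generation time ``G = sum_x x l_x m_x / R0``;
* the Leslie projection matrix (fertilities ``m_x`` in the first row,
  survival ratios ``l_{x+1}/l_x`` on the subdiagonal, zeros elsewhere);
* its dominant eigen-structure — asymptotic growth rate ``lambda``, stable
  age distribution ``w`` (right eigenvector, normalised to sum 1) and
  reproductive values ``v`` (left eigenvector, scaled to ``v_0 = 1``);
* age-specific life expectancy ``e_x`` as the column sums of the
  fundamental matrix ``(I - U)^{-1}``, where ``U`` is the Leslie matrix
  with its fertility row zeroed;
* the fraction of newborns surviving to the median age at first
  reproduction.

The discrete life-expectancy convention counts the current interval, so
``e_x >= 1`` for every living class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, ValidationError
from .fertility import AFRDistribution
from .survival import LifeTable

__all__ = [
    "DemographicSummary",
    "net_reproductive_rate",
    "generation_time",
    "build_leslie",
    "leslie_from_rates",
    "eigen_analysis",
    "power_iteration_lambda",
    "life_expectancy",
    "survival_to_median_afr",
    "summarize",
]

_EIG_IMAG_TOL = 1e-9


@dataclass
class DemographicSummary:
    """Scalar and per-age population statistics from one female life table."""

    R0: float
    G: float | None
    lam: float
    w: np.ndarray
    v: np.ndarray
    e: np.ndarray
    surv_to_median_afr: float | None = None


def _aligned_lm(lt: LifeTable) -> tuple[np.ndarray, np.ndarray]:
    if lt.m is None:
        raise ValidationError("life table has no fertility vector")
    l = np.asarray(lt.l, dtype=float)
    m = np.asarray(lt.m, dtype=float)
    if len(l) != len(m) or len(l) != lt.omega + 1:
        raise ValidationError(
            f"l and m must both have length omega+1 = {lt.omega + 1}"
        )
    return l, m


def net_reproductive_rate(lt: LifeTable) -> float:
    """Lifetime daughters per newborn female, ``sum_{x=0}^{omega} l_x m_x``."""
    l, m = _aligned_lm(lt)
    return float(np.sum(l * m))


def generation_time(lt: LifeTable) -> float:
    """Mean maternal age at daughter production,
    ``sum_x x l_x m_x / R0``; undefined when ``R0 = 0``."""
    l, m = _aligned_lm(lt)
    r0 = float(np.sum(l * m))
    if r0 <= 0:
        raise ComputationError("R0 = 0: generation time undefined")
    x = np.arange(len(l))
    return float(np.sum(x * l * m) / r0)


def build_leslie(lt: LifeTable) -> np.ndarray:
    """Leslie matrix of dimension ``omega + 1`` from the life table.

    Fertilities ``m_x`` fill the first row; the survival ratio
    ``l_{x+1} / l_x`` sits on the subdiagonal in column ``x``; every other
    entry is zero. Requires ``l_x > 0`` for ``x < omega``.
    """
    l, m = _aligned_lm(lt)
    for x in range(lt.omega):
        if l[x] <= 0:
            raise ComputationError(
                f"survivorship reaches 0 at age {x} < omega: cannot form "
                f"the survival ratio l_{x + 1}/l_{x}"
            )
    surv = l[1:] / l[:-1]
    return leslie_from_rates(surv, m)


def leslie_from_rates(surv: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Assemble a Leslie matrix from per-class survival probabilities
    (length ``n-1``) and fertilities (length ``n``)."""
    surv = np.asarray(surv, dtype=float)
    m = np.asarray(m, dtype=float)
    n = len(m)
    if len(surv) != n - 1:
        raise ValidationError("need len(surv) == len(m) - 1")
    if np.any(surv < 0) or np.any(surv > 1) or np.any(m < 0):
        raise ValidationError("survival must lie in [0,1] and m must be >= 0")
    A = np.zeros((n, n))
    A[0, :] = m
    A[np.arange(1, n), np.arange(n - 1)] = surv
    return A


def eigen_analysis(A: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Dominant eigen-structure of a Leslie matrix.

    Returns ``(lam, w, v)``: the dominant eigenvalue (real and positive
    for a matrix with at least one positive fertility reachable from age
    0), the stable age distribution (right eigenvector, non-negative,
    summing to 1) and the reproductive values (left eigenvector, scaled so
    ``v[0] = 1``). Raises if the dominant eigenvalue carries a
    non-negligible imaginary part (a periodic schedule whose dominant
    modulus is tied) rather than silently returning a complex root.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("Leslie matrix must be square")
    if not np.any(A[0] > 0):
        raise ValidationError("matrix has no positive fertility")
    vals, vecs = np.linalg.eig(A)
    order = np.argsort(-np.abs(vals))
    top = order[0]
    # among modulus ties prefer the real positive root (the Perron root)
    ties = [k for k in order if np.isclose(np.abs(vals[k]), np.abs(vals[top]), rtol=1e-12, atol=1e-15)]
    real_ties = [k for k in ties if abs(vals[k].imag) <= _EIG_IMAG_TOL * max(1.0, abs(vals[k]))]
    if not real_ties:
        raise ComputationError(
            "dominant eigenvalue is complex: the fertility schedule appears "
            "periodic (no primitive age structure)"
        )
    top = real_ties[0]
    lam = float(vals[top].real)
    if lam <= 0:
        raise ComputationError(f"dominant eigenvalue {lam} is not positive")

    w = vecs[:, top]
    if np.max(np.abs(w.imag)) > _EIG_IMAG_TOL * np.max(np.abs(w)):
        raise ComputationError("stable age distribution has imaginary residue")
    w = w.real
    w = w * np.sign(w[np.argmax(np.abs(w))])
    if np.any(w < -1e-9 * np.max(np.abs(w))):
        raise ComputationError("dominant right eigenvector changes sign")
    w = np.clip(w, 0.0, None)
    w = w / w.sum()

    lvals, lvecs = np.linalg.eig(A.T)
    lk = int(np.argmin(np.abs(lvals - lam)))
    v = lvecs[:, lk]
    if np.max(np.abs(v.imag)) > _EIG_IMAG_TOL * np.max(np.abs(v)):
        raise ComputationError("reproductive-value vector has imaginary residue")
    v = v.real
    if abs(v[0]) < 1e-300:
        raise ComputationError("v[0] = 0: cannot scale reproductive values")
    v = v / v[0]
    return lam, w, v


def power_iteration_lambda(
    A: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000
) -> float:
    """Dominant eigenvalue by power iteration — an independent cross-check
    of :func:`eigen_analysis`, not the primary route."""
    A = np.asarray(A, dtype=float)
    x = np.ones(A.shape[0]) / A.shape[0]
    lam = 0.0
    for _ in range(max_iter):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return 0.0
        y /= norm
        lam_new = float(y @ A @ y) / float(y @ y)
        if abs(lam_new - lam) < tol * max(1.0, abs(lam_new)):
            return lam_new
        lam, x = lam_new, y
    raise ComputationError("power iteration did not converge")


def life_expectancy(A: np.ndarray) -> np.ndarray:
    """Life expectancy at each age from the fundamental matrix.

    ``U`` is the Leslie matrix with the fertility row replaced by zeros;
    the column sums of ``N = (I - U)^{-1}`` give the expected number of
    one-year intervals an age-x individual has yet to live, counting the
    current one (so ``e_x >= 1``).
    """
    A = np.asarray(A, dtype=float)
    U = A.copy()
    U[0, :] = 0.0
    n = U.shape[0]
    eye = np.eye(n)
    try:
        fundamental = np.linalg.inv(eye - U)
    except np.linalg.LinAlgError as err:  # pragma: no cover - bidiagonal U is regular
        raise ComputationError(
            "I - U is singular (terminal survival equals 1)"
        ) from err
    return fundamental.sum(axis=0)


def survival_to_median_afr(
    lt: LifeTable, afr: AFRDistribution, interpolate: bool = False
) -> float:
    """Fraction of newborns surviving to the median age at first
    reproduction: a lookup of ``l`` at the (rounded) median age, or linear
    interpolation between the flanking integer ages when requested."""
    med = afr.median
    if med > lt.omega:
        raise ValidationError(
            f"median AFR {med} lies beyond the table's omega = {lt.omega}"
        )
    if interpolate:
        return float(np.interp(med, np.arange(lt.omega + 1), lt.l))
    return float(lt.l[int(np.floor(med + 0.5))])


def summarize(
    lt: LifeTable,
    afr: AFRDistribution | None = None,
    interpolate_afr: bool = False,
) -> DemographicSummary:
    """All population statistics from one completed female life table."""
    r0 = net_reproductive_rate(lt)
    g = generation_time(lt) if r0 > 0 else None
    A = build_leslie(lt)
    lam, w, v = eigen_analysis(A)
    e = life_expectancy(A)
    surv = (
        survival_to_median_afr(lt, afr, interpolate=interpolate_afr)
        if afr is not None
        else None
    )
    return DemographicSummary(
        R0=r0, G=g, lam=lam, w=w, v=v, e=e, surv_to_median_afr=surv
    )
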