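"""Parametric bootstrap confidence limits for life-history statistics.

Each replicate resamples the life table from the sampling distributions of
its own estimates:

* mortality — for each age class, the number dying is Binomial with the
  adjusted at-risk count rounded *up* to the next integer and success
  probability ``q_hat_x``; dividing by that count gives one plausible
  ``q*_x``, and Eq.-style cumulative products give ``l*``;
* fertility — each of ``ceil(N_m.x)`` females contributes a Poisson number
  of daughters with mean ``m_hat_x``; the total over females divided by
  their number gives one plausible ``m*_x`` (drawn here as a single
  Poisson(``n * m_hat``) variate — identical in distribution by Poisson
  additivity). The Poisson accommodates the occasional two births within a
  one-year interval (infant death, twinning).

From every sampled ``(l*, m*)`` pair all downstream statistics (R0, G,
lambda, stable age distribution, reproductive values, life expectancies)
are recomputed; after ``n_reps`` replicates (4999 by default) the 2.5th
and 97.5th percentiles of each bootstrap distribution give the 95%
confidence limits. The truncation age is held fixed at the point
estimate's omega. One seeded generator drives the whole run — draws
ordered replicate-by-replicate, mortality before fertility, ages ascending
— so results are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .demography import eigen_analysis, leslie_from_rates, life_expectancy
from .errors import ValidationError
from .survival import LifeTable, survivorship

logger = logging.getLogger(__name__)

__all__ = ["BootstrapEnvelope", "sample_mortality", "sample_fertility", "bootstrap_ci"]

PERCENTILES = (2.5, 97.5)


@dataclass
class BootstrapEnvelope:
    """Percentile confidence envelopes from one bootstrap run.

    ``scalars`` maps a statistic name (``"R0"``, ``"G"``, ``"lam"``) to
    ``(point, lower, upper)``; ``per_age`` maps a vector statistic
    (``"l"``, ``"m"``, ``"w"``, ``"v"``, ``"e"``) to a dict with
    ``point`` / ``lower`` / ``upper`` arrays over ages ``0..omega``.
    ``replicates`` retains the raw bootstrap distributions (one row per
    replicate). ``n_undefined_G`` counts replicates with ``R0* = 0``,
    excluded from G's percentile set; ``n_zero_fertility`` counts
    replicates whose sampled fertility was identically zero (their
    ``w*``/``v*`` are undefined).
    """

    scalars: dict[str, tuple[float, float, float]]
    per_age: dict[str, dict[str, np.ndarray]]
    n_reps: int
    seed: int
    n_undefined_G: int = 0
    n_zero_fertility: int = 0
    replicates: dict[str, np.ndarray] = field(default_factory=dict)


def sample_mortality(
    q_hat: np.ndarray, N_q: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One bootstrap draw of the mortality vector.

    ``n_x = ceil(N_q.x)`` individuals at risk; ``D_x ~ Binomial(n_x,
    q_hat_x)``; ``q*_x = D_x / n_x``. Classes with ``n_x = 0`` stay NaN.
    """
    q_hat = np.asarray(q_hat, dtype=float)
    N_q = np.asarray(N_q, dtype=float)
    if len(q_hat) != len(N_q):
        raise ValidationError("q_hat and N_q must have equal length")
    finite = ~np.isnan(q_hat)
    if np.any((q_hat[finite] < 0) | (q_hat[finite] > 1)):
        raise ValidationError("q_hat entries must lie in [0, 1]")
    if np.any(N_q < 0):
        raise ValidationError("N_q entries must be >= 0")
    n = np.array([math.ceil(v) for v in N_q], dtype=int)
    out = np.full(len(q_hat), np.nan)
    ok = (n > 0) & finite
    if np.any(ok):
        draws = rng.binomial(n[ok], q_hat[ok])
        out[ok] = draws / n[ok]
    return out


def sample_fertility(
    m_hat: np.ndarray, N_m: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One bootstrap draw of the fertility vector.

    ``n_x = ceil(N_m.x)`` females each contribute Poisson(``m_hat_x``)
    daughters; ``m*_x`` is their total divided by ``n_x`` (drawn as a
    single Poisson(``n_x * m_hat_x``) variate). Classes with ``n_x = 0``
    keep ``m* = 0``.
    """
    m_hat = np.asarray(m_hat, dtype=float)
    N_m = np.asarray(N_m, dtype=float)
    if len(m_hat) != len(N_m):
        raise ValidationError("m_hat and N_m must have equal length")
    if np.any(m_hat < 0):
        raise ValidationError("m_hat entries must be >= 0")
    if np.any(N_m < 0):
        raise ValidationError("N_m entries must be >= 0")
    n = np.array([math.ceil(v) for v in N_m], dtype=int)
    out = np.zeros(len(m_hat))
    ok = (n > 0) & (m_hat > 0)
    if np.any(ok):
        out[ok] = rng.poisson(n[ok] * m_hat[ok]) / n[ok]
    return out


def bootstrap_ci(lt: LifeTable, n_reps: int = 4999, seed: int = 0) -> BootstrapEnvelope:
    """Percentile bootstrap envelopes for all statistics of a female table.

    Requires a completed table (``m``, ``N_q`` and ``N_m`` present).
    Percentiles use the linear-interpolation order-statistic convention.
    """
    if lt.m is None or lt.N_q is None or lt.N_m is None:
        raise ValidationError(
            "bootstrap needs a completed female life table with N_q and N_m"
        )
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if np.any(np.isnan(lt.q)):
        raise ValidationError("bootstrap needs q defined at every age <= omega")

    from .demography import generation_time, net_reproductive_rate  # point estimates

    rng = np.random.default_rng(seed)
    n_ages = lt.omega + 1
    reps = {
        "R0": np.empty(n_reps),
        "G": np.full(n_reps, np.nan),
        "lam": np.empty(n_reps),
        "l": np.empty((n_reps, n_ages)),
        "m": np.empty((n_reps, n_ages)),
        "w": np.full((n_reps, n_ages), np.nan),
        "v": np.full((n_reps, n_ages), np.nan),
        "e": np.empty((n_reps, n_ages)),
    }
    ages = np.arange(n_ages)
    n_zero_fert = 0
    for r in range(n_reps):
        q_star = sample_mortality(lt.q, lt.N_q, rng)
        l_star = survivorship(q_star)[:n_ages]
        m_star = sample_fertility(lt.m, lt.N_m, rng)
        reps["l"][r] = l_star
        reps["m"][r] = m_star
        r0 = float(np.sum(l_star * m_star))
        reps["R0"][r] = r0
        if r0 > 0:
            reps["G"][r] = float(np.sum(ages * l_star * m_star) / r0)
        if np.any(m_star > 0):
            A = leslie_from_rates(1.0 - q_star[:-1], m_star)
            lam, w, v = eigen_analysis(A)
            reps["lam"][r] = lam
            reps["w"][r] = w
            reps["v"][r] = v
            reps["e"][r] = life_expectancy(A)
        else:
            n_zero_fert += 1
            reps["lam"][r] = 0.0
            U = leslie_from_rates(1.0 - q_star[:-1], np.zeros(n_ages))
            reps["e"][r] = life_expectancy(U)

    n_bad_g = int(np.isnan(reps["G"]).sum())
    if n_bad_g:
        logger.info(
            "excluded %d replicate(s) with R0* = 0 from the G percentiles",
            n_bad_g,
        )

    point_r0 = net_reproductive_rate(lt)
    point_g = generation_time(lt) if point_r0 > 0 else np.nan
    from .demography import build_leslie

    if np.any(lt.m > 0):
        A0 = build_leslie(lt)
        point_lam, point_w, point_v = eigen_analysis(A0)
        point_e = life_expectancy(A0)
    else:  # sterile point estimate: growth 0, age structure undefined
        point_lam = 0.0
        point_w = np.full(n_ages, np.nan)
        point_v = np.full(n_ages, np.nan)
        point_e = life_expectancy(leslie_from_rates(1.0 - lt.q[:-1], np.zeros(n_ages)))

    def _pct(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            lo, hi = np.nanpercentile(a, PERCENTILES, axis=0)
        return lo, hi

    scalars = {}
    for name, point in (("R0", point_r0), ("G", point_g), ("lam", point_lam)):
        lo, hi = _pct(reps[name])
        scalars[name] = (float(point), float(lo), float(hi))
    per_age = {}
    for name, point in (
        ("l", lt.l),
        ("m", lt.m),
        ("w", point_w),
        ("v", point_v),
        ("e", point_e),
    ):
        lo, hi = _pct(reps[name])
        per_age[name] = {"point": np.asarray(point, dtype=float), "lower": lo, "upper": hi}

    return BootstrapEnvelope(
        scalars=scalars,
        per_age=per_age,
        n_reps=n_reps,
        seed=seed,
        n_undefined_G=n_bad_g,
        n_zero_fertility=n_zero_fert,
        replicates=reps,
    )
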