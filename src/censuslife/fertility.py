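"""Age-specific fertility, offspring sex ratio, and age at first reproduction.

Fertility ``m_x`` is the expected number of daughters per female per year.
Because females are not watched continuously, each female's observed births
in an age interval are weighted by the fraction of that interval she spent
under intensive observation, and the weighted births are divided by the sum
of the weights (``N_m.x``). To damp demographic stochasticity in the sexed
counts — and to keep newborns that died before they could be sexed — the
estimate uses *all* newborns and halves the result under a 50:50 birth sex
ratio, an assumption checked by :func:`sex_ratio`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .census import FertilityCounts
from .errors import ValidationError
from .records import FEMALE, MALE

__all__ = [
    "SexRatioSummary",
    "AFRDistribution",
    "age_specific_fertility",
    "sex_ratio",
    "offspring_sex_by_mother_age",
    "age_first_reproduction",
]


@dataclass
class SexRatioSummary:
    """Proportion female among sexed newborns, with an exact
    (Clopper–Pearson) 95% binomial confidence interval."""

    n_sexed: int
    prop_female: float
    ci_low: float
    ci_high: float


@dataclass
class AFRDistribution:
    """Per-female ages at first reproduction with median and quartiles
    (inclusive linear-interpolation convention)."""

    ages: np.ndarray
    median: float
    q1: float
    q3: float


def age_specific_fertility(fc: FertilityCounts) -> tuple[np.ndarray, np.ndarray]:
    """Daughter fertility ``m_x`` and its sample sizes ``N_m.x``.

    ``m_x = (weighted_births_x / weight_sum_x) / 2`` where the weight sum
    is positive, 0 elsewhere within the observed age range.
    """
    ws = fc.weight_sum
    m = np.zeros(fc.n_classes)
    pos = ws > 0
    m[pos] = (fc.weighted_births[pos] / ws[pos]) / 2.0
    return m, ws.copy()


def sex_ratio(records, alpha: float = 0.05) -> SexRatioSummary:
    """Proportion female among individuals born into the study whose sex
    was determined (entry age 0, recorded sex F or M)."""
    daughters = sum(
        1 for r in records if r.entry_age == 0 and r.sex == FEMALE
    )
    sons = sum(1 for r in records if r.entry_age == 0 and r.sex == MALE)
    n = daughters + sons
    if n == 0:
        raise ValidationError("no sexed newborns: sex ratio undefined")
    prop = daughters / n
    lo, hi = proportion_confint(daughters, n, alpha=alpha, method="beta")
    return SexRatioSummary(
        n_sexed=n, prop_female=prop, ci_low=float(lo), ci_high=float(hi)
    )


def offspring_sex_by_mother_age(fc: FertilityCounts) -> tuple[np.ndarray, np.ndarray]:
    """Weighted probability of producing a son / a daughter at each
    maternal age: weighted sexed offspring over the weighted number of
    mothers. Unsexed newborns are necessarily ignored here (they are not
    ignored in ``m_x``). Ages with no observed mothers yield NaN."""
    ws = fc.weight_sum
    p_son = np.full(fc.n_classes, np.nan)
    p_dau = np.full(fc.n_classes, np.nan)
    pos = ws > 0
    p_son[pos] = fc.weighted_sons[pos] / ws[pos]
    p_dau[pos] = fc.weighted_daughters[pos] / ws[pos]
    return p_son, p_dau


def age_first_reproduction(records, known_age_only: bool = False) -> AFRDistribution:
    """Distribution of female age at first reproduction.

    Each female with at least one recorded birth contributes the age class
    of her earliest birth. ``known_age_only`` restricts to females born
    into the study (entry age 0), excluding immigrants and
    present-at-start females whose ages were estimated.
    """
    ages = []
    for rec in records:
        if rec.sex != FEMALE or not rec.births:
            continue
        if known_age_only and rec.entry_age != 0:
            continue
        ages.append(min(a for a, _ in rec.births))
    if not ages:
        raise ValidationError("no reproducing females: AFR distribution empty")
    arr = np.sort(np.asarray(ages, dtype=int))
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return AFRDistribution(ages=arr, median=float(med), q1=float(q1), q3=float(q3))
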