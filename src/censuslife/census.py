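"""Reduction of individual records to per-sex, per-age-class count vectors.

This is the bookkeeping layer of the life-table pipeline: every individual
contributes one entry (``t_x``, with ``t_0`` = births) and exactly one exit
— death (``d_x``), permanent disappearance (``p_x``) or right censoring
(``c_x``) — in one-year age classes. The at-risk series ``N_x`` (number
alive at the start of class x) follows by recurrence. For females, a second
pass accumulates the observation-weighted birth tallies that feed the
fertility estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .records import CENSORED, DEATH, DISAPPEARANCE, FEMALE, MALE, UNKNOWN, IndividualRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AgeClassCounts",
    "FertilityCounts",
    "tabulate_counts",
    "at_risk",
    "tabulate_fertility",
]


@dataclass
class AgeClassCounts:
    """Per-age-class counts for one sex.

    ``t`` entries (``t[0]`` = births), ``d`` deaths, ``p`` permanent
    disappearances, ``c`` censored. ``dp = d + p`` is the pooled mortality
    numerator (pooling disappearances with deaths avoids underestimating
    mortality, at the cost of possibly overestimating it for the
    dispersing sex).
    """

    sex: str
    t: np.ndarray
    d: np.ndarray
    p: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        vecs = [np.asarray(v, dtype=int) for v in (self.t, self.d, self.p, self.c)]
        lengths = {len(v) for v in vecs}
        if len(lengths) != 1:
            raise ValidationError(f"count vectors have mixed lengths {lengths}")
        for name, v in zip("tdpc", vecs):
            if np.any(v < 0):
                raise ValidationError(f"negative entries in count vector {name}")
        self.t, self.d, self.p, self.c = vecs

    @property
    def dp(self) -> np.ndarray:
        return self.d + self.p

    @property
    def n_classes(self) -> int:
        return len(self.t)

    @property
    def N(self) -> np.ndarray:
        return at_risk(self)


@dataclass
class FertilityCounts:
    """Observation-weighted birth tallies per maternal age class.

    ``weight_sum`` is the fertility sample size ``N_m.x`` (the sum of the
    mothers' observation fractions); ``weighted_births`` counts all
    newborns of both sexes, including those whose sex was never determined;
    ``weighted_sons`` / ``weighted_daughters`` count sexed offspring only.
    ``n_mothers`` is the plain head count of females observed at each age.
    """

    weighted_births: np.ndarray
    weight_sum: np.ndarray
    n_mothers: np.ndarray
    weighted_sons: np.ndarray
    weighted_daughters: np.ndarray

    def __post_init__(self):
        arrays = [
            np.asarray(v, dtype=float)
            for v in (
                self.weighted_births,
                self.weight_sum,
                self.weighted_sons,
                self.weighted_daughters,
            )
        ]
        nm = np.asarray(self.n_mothers, dtype=int)
        if len({len(a) for a in arrays} | {len(nm)}) != 1:
            raise ValidationError("fertility count vectors have mixed lengths")
        if any(np.any(a < 0) for a in arrays) or np.any(nm < 0):
            raise ValidationError("fertility counts must be non-negative")
        sexed = arrays[2] + arrays[3]
        if np.any(sexed > arrays[0] + 1e-9):
            raise ValidationError(
                "sexed offspring exceed total weighted births in some class"
            )
        (
            self.weighted_births,
            self.weight_sum,
            self.weighted_sons,
            self.weighted_daughters,
        ) = arrays
        self.n_mothers = nm

    @property
    def n_classes(self) -> int:
        return len(self.weight_sum)


def tabulate_counts(
    records,
    sex: str,
    truncate_age: int | None = None,
    n_classes: int | None = None,
) -> AgeClassCounts:
    """Tabulate entry/exit counts for one sex.

    Individuals whose exit lies beyond ``truncate_age`` are converted to
    censored at ``truncate_age`` (the convention used for the dispersing
    sex when older fates are unreliable); individuals entering beyond it
    are dropped with a warning. Records of unknown sex are excluded with a
    warning.
    """
    if sex not in (FEMALE, MALE):
        raise ValidationError(f"sex must be F or M, got {sex!r}")
    if truncate_age is not None and truncate_age < 0:
        raise ValidationError("truncate_age must be >= 0")

    kept: list[IndividualRecord] = []
    n_unknown = 0
    n_beyond = 0
    for rec in records:
        if rec.exit_age < rec.entry_age:
            raise ValidationError(
                f"record {rec.id}: exit_age {rec.exit_age} < entry_age {rec.entry_age}"
            )
        if rec.sex == UNKNOWN:
            n_unknown += 1
            continue
        if rec.sex != sex:
            continue
        if truncate_age is not None and rec.entry_age > truncate_age:
            n_beyond += 1
            continue
        kept.append(rec)
    if n_unknown:
        logger.warning("excluded %d record(s) of unknown sex", n_unknown)
    if n_beyond:
        logger.warning(
            "excluded %d record(s) entering beyond truncate_age=%s",
            n_beyond,
            truncate_age,
        )

    if n_classes is None:
        if truncate_age is not None:
            top = truncate_age
        elif kept:
            top = max(r.exit_age for r in kept)
        else:
            top = 0
        n_classes = top + 1
    t = np.zeros(n_classes, dtype=int)
    d = np.zeros(n_classes, dtype=int)
    p = np.zeros(n_classes, dtype=int)
    c = np.zeros(n_classes, dtype=int)
    for rec in kept:
        t[rec.entry_age] += 1
        if truncate_age is not None and rec.exit_age > truncate_age:
            c[truncate_age] += 1
            continue
        if rec.fate == DEATH:
            d[rec.exit_age] += 1
        elif rec.fate == DISAPPEARANCE:
            p[rec.exit_age] += 1
        elif rec.fate == CENSORED:
            c[rec.exit_age] += 1
        else:  # pragma: no cover - guarded by record validation
            raise ValidationError(f"record {rec.id}: unknown fate {rec.fate!r}")
    return AgeClassCounts(sex=sex, t=t, d=d, p=p, c=c)


def at_risk(counts: AgeClassCounts) -> np.ndarray:
    """Number alive at the start of each age class.

    ``N_0 = t_0``; ``N_x = N_{x-1} - dp_{x-1} - c_{x-1} + t_x``. A negative
    value means the counts are internally inconsistent (more exits than
    individuals present) and raises naming the offending class.
    """
    t, dp, c = counts.t, counts.dp, counts.c
    N = np.zeros(counts.n_classes, dtype=int)
    for x in range(counts.n_classes):
        N[x] = t[0] if x == 0 else N[x - 1] - dp[x - 1] - c[x - 1] + t[x]
        if N[x] < 0:
            raise ValidationError(
                f"inconsistent counts: at-risk N_{x} = {N[x]} < 0"
            )
        if N[x] < dp[x] + c[x]:
            raise ValidationError(
                f"inconsistent counts at age {x}: {dp[x] + c[x]} exits but "
                f"only {N[x]} at risk"
            )
    return N


def tabulate_fertility(records, n_classes: int | None = None) -> FertilityCounts:
    """Accumulate observation-weighted birth tallies over female records.

    For each female alive during class ``x`` with observation fraction
    ``w``: the denominator ``weight_sum[x]`` gains ``w`` and the numerator
    ``weighted_births[x]`` gains ``w`` times her newborns at ``x`` (the
    same weighting the fertility estimator divides through by).
    """
    females = [r for r in records if r.sex == FEMALE]
    for rec in females:
        for age, _ in rec.births:
            if not (rec.entry_age <= age <= rec.exit_age):
                raise ValidationError(
                    f"record {rec.id}: birth event at age {age} outside "
                    f"[{rec.entry_age}, {rec.exit_age}]"
                )
    if n_classes is None:
        n_classes = (max(r.exit_age for r in females) + 1) if females else 0

    wb = np.zeros(n_classes)
    ws = np.zeros(n_classes)
    wson = np.zeros(n_classes)
    wdau = np.zeros(n_classes)
    nm = np.zeros(n_classes, dtype=int)
    for rec in females:
        by_age: dict[int, list[str]] = {}
        for age, osex in rec.births:
            by_age.setdefault(age, []).append(osex)
        for x in range(rec.entry_age, min(rec.exit_age, n_classes - 1) + 1):
            w = rec.observed_fraction(x)
            ws[x] += w
            nm[x] += 1
            kids = by_age.get(x, [])
            wb[x] += w * len(kids)
            wson[x] += w * sum(1 for s in kids if s == MALE)
            wdau[x] += w * sum(1 for s in kids if s == FEMALE)
    return FertilityCounts(
        weighted_births=wb,
        weight_sum=ws,
        n_mothers=nm,
        weighted_sons=wson,
        weighted_daughters=wdau,
    )
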