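"""The individual-based census record.

One :class:`IndividualRecord` summarises the complete monitoring history of a
single animal in a long-term field study: the age class at which it entered
observation (0 for animals born into the study population, >0 for immigrants
or animals present when monitoring began), the age class at which observation
ended and how (death, permanent disappearance of ambiguous fate, or right
censoring), any birth events attributed to it (females only), and the
fraction of each age interval during which it was under intensive
observation.

Ages are integer one-year age-class indices: class ``x`` is the half-open
interval ``[x, x+1)`` years, class 0 the first year of life.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

FEMALE = "F"
MALE = "M"
UNKNOWN = "U"
SEXES = (FEMALE, MALE, UNKNOWN)

DEATH = "death"
DISAPPEARANCE = "permanent_disappearance"
CENSORED = "censored"
FATES = (DEATH, DISAPPEARANCE, CENSORED)


@dataclass
class IndividualRecord:
    """Monitoring history of one animal.

    Parameters
    ----------
    id
        Opaque identifier, unique within a dataset.
    sex
        ``"F"``, ``"M"``, or ``"U"`` for animals whose sex was never
        determined (typically newborns that died before sexing).
    entry_age
        Age class at first contact. 0 means born into the study.
    exit_age
        Age class at last contact; ``exit_age >= entry_age``.
    fate
        How observation ended: ``"death"``, ``"permanent_disappearance"``
        (vanished, death vs. emigration unresolvable), or ``"censored"``
        (alive at end of study or known successful emigration).
    births
        Birth events as ``(mother_age_class, offspring_sex)`` pairs.
        Non-empty only for females.
    obs_fraction
        Map from age class to the fraction of that interval spent under
        intensive observation. Missing classes default to 1.0 (fully
        observed).
    """

    id: str
    sex: str
    entry_age: int
    exit_age: int
    fate: str
    births: list[tuple[int, str]] = field(default_factory=list)
    obs_fraction: dict[int, float] = field(default_factory=dict)

    def observed_fraction(self, age: int) -> float:
        return self.obs_fraction.get(age, 1.0)

    def births_at(self, age: int) -> int:
        return sum(1 for a, _ in self.births if a == age)

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"record {self.id}: unknown sex {self.sex!r}")
        if self.fate not in FATES:
            raise ValidationError(f"record {self.id}: unknown fate {self.fate!r}")
        if not (0 <= int(self.entry_age) <= int(self.exit_age)):
            raise ValidationError(
                f"record {self.id}: need 0 <= entry_age <= exit_age, got "
                f"entry={self.entry_age}, exit={self.exit_age}"
            )
        if self.births and self.sex != FEMALE:
            raise ValidationError(
                f"record {self.id}: birth events on a non-female record"
            )
        for age, osex in self.births:
            if not (self.entry_age <= age <= self.exit_age):
                raise ValidationError(
                    f"record {self.id}: birth event at age {age} outside "
                    f"[{self.entry_age}, {self.exit_age}]"
                )
            if osex not in SEXES:
                raise ValidationError(
                    f"record {self.id}: unknown offspring sex {osex!r}"
                )
        for age, frac in self.obs_fraction.items():
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(
                    f"record {self.id}: observation fraction {frac} at age "
                    f"{age} outside [0, 1]"
                )


def validate_records(records) -> None:
    """Validate a collection, aggregating all per-record failures."""
    problems = []
    for rec in records:
        try:
            rec.validate()
        except ValidationError as err:
            problems.append(str(err))
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid record(s):\n" + "\n".join(problems)
        )
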