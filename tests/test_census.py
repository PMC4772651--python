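"""Count tabulation: bookkeeping, conservation, at-risk recurrence, weighting."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from censuslife import (
    AgeClassCounts,
    IndividualRecord,
    ValidationError,
    at_risk,
    tabulate_counts,
    tabulate_fertility,
)
from censuslife.records import CENSORED, DEATH, DISAPPEARANCE, FEMALE, MALE


def rec(id, sex, entry, exit, fate, births=(), obs=None):
    return IndividualRecord(
        id=id,
        sex=sex,
        entry_age=entry,
        exit_age=exit,
        fate=fate,
        births=list(births),
        obs_fraction=dict(obs or {}),
    )


def test_single_death_bookkeeping():
    counts = tabulate_counts([rec("a", FEMALE, 0, 3, DEATH)], FEMALE)
    assert counts.t.tolist() == [1, 0, 0, 0]
    assert counts.d.tolist() == [0, 0, 0, 1]
    assert counts.p.tolist() == [0, 0, 0, 0]
    assert counts.c.tolist() == [0, 0, 0, 0]


def test_truncation_converts_late_exits_to_censors():
    counts = tabulate_counts(
        [rec("b", MALE, 2, 5, CENSORED)], MALE, truncate_age=4
    )
    assert counts.n_classes == 5
    assert counts.t.tolist() == [0, 0, 1, 0, 0]
    assert counts.c.tolist() == [0, 0, 0, 0, 1]
    assert counts.d.sum() == 0 and counts.p.sum() == 0


def test_each_fate_lands_in_its_own_column():
    records = [
        rec("a", FEMALE, 0, 1, DEATH),
        rec("b", FEMALE, 0, 1, DISAPPEARANCE),
        rec("c", FEMALE, 0, 1, CENSORED),
    ]
    counts = tabulate_counts(records, FEMALE)
    assert counts.d.tolist() == [0, 1]
    assert counts.p.tolist() == [0, 1]
    assert counts.c.tolist() == [0, 1]
    assert counts.dp.tolist() == [0, 2]


def test_exit_before_entry_rejected():
    bad = IndividualRecord("x", FEMALE, entry_age=3, exit_age=1, fate=DEATH)
    with pytest.raises(ValidationError):
        tabulate_counts([bad], FEMALE)


def test_conservation_on_simulated_population(rich_population):
    _, records = rich_population
    for sex in (FEMALE, MALE):
        counts = tabulate_counts(records, sex)
        n_sex = sum(1 for r in records if r.sex == sex)
        assert counts.t.sum() == n_sex
        assert (counts.d + counts.p + counts.c).sum() == n_sex


def test_at_risk_recurrence_examples():
    counts = AgeClassCounts(
        sex=FEMALE, t=[10, 0, 0], d=[2, 3, 0], p=[0, 0, 0], c=[1, 0, 0]
    )
    assert at_risk(counts).tolist() == [10, 7, 4]
    late = AgeClassCounts(
        sex=FEMALE, t=[0, 5, 0], d=[0, 1, 0], p=[0, 0, 0], c=[0, 0, 0]
    )
    assert at_risk(late).tolist() == [0, 5, 4]


def test_inconsistent_counts_raise_with_age_class():
    counts = AgeClassCounts(sex=FEMALE, t=[1, 0], d=[0, 2], p=[0, 0], c=[0, 0])
    with pytest.raises(ValidationError, match="age 1"):
        at_risk(counts)


def test_at_risk_equals_direct_count_on_simulated_data(rich_population):
    _, records = rich_population
    for sex in (FEMALE, MALE):
        counts = tabulate_counts(records, sex)
        N = at_risk(counts)
        for x in range(counts.n_classes):
            direct = sum(
                1 for r in records if r.sex == sex and r.entry_age <= x <= r.exit_age
            )
            assert N[x] == direct, f"sex {sex}, age {x}"


def test_fertility_weighting_arithmetic():
    records = [
        rec("a", FEMALE, 2, 2, DEATH, births=[(2, MALE)], obs={2: 1.0}),
        rec("b", FEMALE, 2, 2, DEATH, births=[(2, FEMALE)], obs={2: 0.5}),
    ]
    fc = tabulate_fertility(records)
    assert fc.weighted_births[2] == pytest.approx(1.5)
    assert fc.weight_sum[2] == pytest.approx(1.5)
    assert fc.weighted_sons[2] == pytest.approx(1.0)
    assert fc.weighted_daughters[2] == pytest.approx(0.5)
    assert fc.n_mothers[2] == 2


def test_zero_weight_female_contributes_nothing():
    records = [rec("a", FEMALE, 1, 1, DEATH, births=[(1, MALE)], obs={1: 0.0})]
    fc = tabulate_fertility(records)
    assert fc.weighted_births[1] == 0.0
    assert fc.weight_sum[1] == 0.0
    assert fc.n_mothers[1] == 1


def test_full_observation_equals_unweighted_tally(recovery_population):
    fc = tabulate_fertility(recovery_population)
    for x in range(fc.n_classes):
        raw_births = sum(r.births_at(x) for r in recovery_population if r.sex == FEMALE)
        raw_mothers = sum(
            1
            for r in recovery_population
            if r.sex == FEMALE and r.entry_age <= x <= r.exit_age
        )
        assert fc.weighted_births[x] == pytest.approx(raw_births)
        assert fc.weight_sum[x] == pytest.approx(raw_mothers)


def test_birth_outside_lifespan_rejected():
    bad = rec("a", FEMALE, 2, 4, DEATH)
    bad.births = [(1, MALE)]  # bypass constructor-time checks
    with pytest.raises(ValidationError):
        tabulate_fertility([bad])


@st.composite
def record_sets(draw):
    n = draw(st.integers(1, 25))
    out = []
    for i in range(n):
        entry = draw(st.integers(0, 5))
        exit_ = draw(st.integers(entry, 6))
        fate = draw(st.sampled_from([DEATH, DISAPPEARANCE, CENSORED]))
        sex = draw(st.sampled_from([FEMALE, MALE]))
        out.append(rec(f"r{i}", sex, entry, exit_, fate))
    return out


@given(record_sets())
def test_conservation_and_at_risk_oracle_property(records):
    for sex in (FEMALE, MALE):
        n_sex = sum(1 for r in records if r.sex == sex)
        if n_sex == 0:
            continue
        counts = tabulate_counts(records, sex)
        assert counts.t.sum() == n_sex
        assert (counts.d + counts.p + counts.c).sum() == n_sex
        N = at_risk(counts)
        for x in range(counts.n_classes):
            direct = sum(
                1 for r in records if r.sex == sex and r.entry_age <= x <= r.exit_age
            )
            assert N[x] == direct
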