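"""Fertility estimation, sex-ratio summaries, age at first reproduction."""

import numpy as np
import pytest
from scipy import stats

from censuslife import (
    FertilityCounts,
    IndividualRecord,
    ValidationError,
    age_first_reproduction,
    age_specific_fertility,
    offspring_sex_by_mother_age,
    sex_ratio,
    tabulate_fertility,
)
from censuslife.records import CENSORED, DEATH, FEMALE, MALE


def female(id, entry, exit, births=(), obs=None, fate=DEATH):
    return IndividualRecord(
        id=id,
        sex=FEMALE,
        entry_age=entry,
        exit_age=exit,
        fate=fate,
        births=list(births),
        obs_fraction=dict(obs or {}),
    )


def newborn(id, sex):
    return IndividualRecord(id=id, sex=sex, entry_age=0, exit_age=0, fate=DEATH)


def fc_of(wb, ws, sons=None, daughters=None, mothers=None):
    n = len(wb)
    return FertilityCounts(
        weighted_births=wb,
        weight_sum=ws,
        n_mothers=mothers or [1] * n,
        weighted_sons=sons or [0.0] * n,
        weighted_daughters=daughters or [0.0] * n,
    )


def test_fertility_is_half_the_weighted_birth_rate():
    m, n_m = age_specific_fertility(fc_of(wb=[0.0, 1.5], ws=[2.0, 1.5]))
    np.testing.assert_allclose(m, [0.0, 0.5])
    np.testing.assert_allclose(n_m, [2.0, 1.5])


def test_zero_births_before_maturity_give_zero_fertility():
    m, _ = age_specific_fertility(fc_of(wb=[0.0, 0.0, 2.0], ws=[5.0, 5.0, 4.0]))
    assert m[0] == m[1] == 0.0
    assert m[2] == pytest.approx(0.25)


def test_halving_holds_for_any_counts():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(1, 8))
        ws = rng.uniform(0.5, 20, n)
        wb = rng.uniform(0, 2, n) * ws
        m, _ = age_specific_fertility(fc_of(wb=wb, ws=ws))
        np.testing.assert_allclose(m, (wb / ws) / 2.0)


def test_constant_weights_equal_unweighted_estimate():
    def records_with_weight(k):
        return [
            female("a", 3, 4, births=[(3, MALE)], obs={3: k, 4: k}),
            female("b", 3, 3, births=[(3, FEMALE), (3, MALE)], obs={3: k}),
            female("c", 3, 4, obs={3: k, 4: k}),
        ]

    m_full, _ = age_specific_fertility(tabulate_fertility(records_with_weight(1.0)))
    m_scaled, _ = age_specific_fertility(tabulate_fertility(records_with_weight(0.25)))
    np.testing.assert_allclose(m_scaled, m_full)
    assert m_full[3] == pytest.approx(3 / 3 / 2)


def test_sex_ratio_even_counts_symmetric_interval():
    records = [newborn(f"f{i}", FEMALE) for i in range(50)] + [
        newborn(f"m{i}", MALE) for i in range(50)
    ]
    sr = sex_ratio(records)
    assert sr.n_sexed == 100
    assert sr.prop_female == pytest.approx(0.5)
    assert sr.ci_low < 0.5 < sr.ci_high
    assert (0.5 - sr.ci_low) == pytest.approx(sr.ci_high - 0.5, abs=1e-9)


def test_sex_ratio_boundary_all_male():
    sr = sex_ratio([newborn(f"m{i}", MALE) for i in range(10)])
    assert sr.prop_female == 0.0
    assert sr.ci_low == 0.0
    assert sr.ci_high == pytest.approx(1 - 0.025 ** (1 / 10))


def test_sex_ratio_interval_is_clopper_pearson():
    records = [newborn(f"f{i}", FEMALE) for i in range(30)] + [
        newborn(f"m{i}", MALE) for i in range(70)
    ]
    sr = sex_ratio(records)
    assert sr.ci_low == pytest.approx(stats.beta.ppf(0.025, 30, 71))
    assert sr.ci_high == pytest.approx(stats.beta.ppf(0.975, 31, 70))


def test_sex_ratio_needs_sexed_newborns():
    with pytest.raises(ValidationError):
        sex_ratio([female("a", 3, 4)])


def test_sex_ratio_interval_covers_an_even_ratio(recovery_config):
    """Across seeded replicates the exact 95% binomial interval should
    cover the true 50:50 ratio in at least 90 of 100 populations."""
    import dataclasses

    from censuslife import simulate_population

    covered = 0
    for seed in range(100):
        cfg = dataclasses.replace(recovery_config, n_births=600, seed=1000 + seed)
        sr = sex_ratio(simulate_population(cfg))
        assert sr.n_sexed >= 500
        covered += sr.ci_low <= 0.5 <= sr.ci_high
    assert covered >= 90


def test_offspring_sex_probabilities_by_mother_age():
    fc = fc_of(
        wb=[0.0, 2.0],
        ws=[2.0, 2.0],
        sons=[0.0, 1.0],
        daughters=[0.0, 1.0],
    )
    p_son, p_dau = offspring_sex_by_mother_age(fc)
    assert p_son[1] == pytest.approx(0.5)
    np.testing.assert_allclose(p_son, p_dau)


def test_sexed_offspring_rates_bounded_by_total_birth_rate(rich_population):
    _, records = rich_population
    fc = tabulate_fertility(records)
    p_son, p_dau = offspring_sex_by_mother_age(fc)
    pos = fc.weight_sum > 0
    total = fc.weighted_births[pos] / fc.weight_sum[pos]
    assert np.all(p_son[pos] + p_dau[pos] <= total + 1e-12)


def test_afr_is_age_of_earliest_birth():
    afr = age_first_reproduction(
        [female("a", 0, 8, births=[(7, MALE), (5, FEMALE)], fate=CENSORED)]
    )
    assert afr.ages.tolist() == [5]
    assert afr.median == 5


def test_afr_median_interpolates_between_females():
    records = [
        female("a", 0, 8, births=[(4, MALE)], fate=CENSORED),
        female("b", 0, 8, births=[(6, MALE)], fate=CENSORED),
    ]
    assert age_first_reproduction(records).median == pytest.approx(5.0)


def test_afr_ignores_births_after_the_first():
    base = [female("a", 0, 9, births=[(4, MALE)], fate=CENSORED)]
    more = [female("a", 0, 9, births=[(4, MALE), (6, FEMALE), (8, MALE)], fate=CENSORED)]
    assert age_first_reproduction(base).median == age_first_reproduction(more).median


def test_afr_respects_maturity_and_known_age_filter(recovery_population):
    afr = age_first_reproduction(recovery_population)
    assert afr.ages.min() >= 3  # reference schedule is infertile below age 3
    known = age_first_reproduction(recovery_population, known_age_only=True)
    assert known.ages.size <= afr.ages.size


def test_afr_requires_a_reproducing_female():
    with pytest.raises(ValidationError):
        age_first_reproduction([female("a", 0, 4, fate=CENSORED)])
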