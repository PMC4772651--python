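"""Leslie-matrix statistics against closed forms and independent oracles."""

import numpy as np
import pytest

from censuslife import (
    ComputationError,
    LifeTable,
    ValidationError,
    build_leslie,
    eigen_analysis,
    generation_time,
    leslie_from_rates,
    life_expectancy,
    net_reproductive_rate,
    summarize,
    survival_to_median_afr,
    true_life_table,
)
from censuslife.demography import power_iteration_lambda
from censuslife.fertility import AFRDistribution
from censuslife.synthetic import default_config


def afr_of(median):
    return AFRDistribution(
        ages=np.array([int(median)]), median=median, q1=median, q3=median
    )


def test_two_class_closed_forms(micro_table):
    assert net_reproductive_rate(micro_table) == pytest.approx(1.0)
    assert generation_time(micro_table) == pytest.approx(1.0)
    A = build_leslie(micro_table)
    np.testing.assert_allclose(A, [[0.0, 2.0], [0.5, 0.0]])
    lam, w, v = eigen_analysis(A)
    assert lam == pytest.approx(1.0)
    np.testing.assert_allclose(w, [2 / 3, 1 / 3])
    np.testing.assert_allclose(v, [1.0, 2.0])
    np.testing.assert_allclose(life_expectancy(A), [1.5, 1.0])


def test_reproduction_at_birth_only_is_a_one_class_problem():
    lt = LifeTable(
        sex="F",
        q=np.array([1.0]),
        l=np.array([1.0]),
        m=np.array([1.5]),
        N_q=np.array([10.0]),
        N_m=np.array([10.0]),
        omega=0,
    )
    lam, w, v = eigen_analysis(build_leslie(lt))
    assert lam == pytest.approx(1.5)
    np.testing.assert_allclose(w, [1.0])
    np.testing.assert_allclose(v, [1.0])


def test_zero_fertility_has_no_dominant_structure(micro_table):
    A = build_leslie(micro_table)
    A[0, :] = 0.0
    with pytest.raises(ValidationError):
        eigen_analysis(A)


def test_r0_equals_next_generation_matrix_root(table_factory):
    rng = np.random.default_rng(42)
    for _ in range(50):
        lt = table_factory(rng)
        A = build_leslie(lt)
        F = np.zeros_like(A)
        F[0, :] = A[0, :]
        U = A.copy()
        U[0, :] = 0.0
        ngm = F @ np.linalg.inv(np.eye(len(A)) - U)
        r0_oracle = np.max(np.abs(np.linalg.eigvals(ngm)))
        assert net_reproductive_rate(lt) == pytest.approx(r0_oracle, rel=1e-10)


def test_generation_time_is_the_lxmx_weighted_mean_age(table_factory):
    rng = np.random.default_rng(43)
    for _ in range(50):
        lt = table_factory(rng)
        weights = lt.l * lt.m
        oracle = sum(x * wx for x, wx in enumerate(weights)) / weights.sum()
        assert generation_time(lt) == pytest.approx(oracle, rel=1e-12)


def test_point_mass_reproduction_gives_generation_time_at_that_age():
    q = np.array([0.1, 0.1, 0.1, 0.1])
    m = np.array([0.0, 0.0, 0.0, 0.8])
    from censuslife import survivorship

    lt = LifeTable(
        sex="F", q=q, l=survivorship(q)[:4], m=m, N_q=None, N_m=None, omega=3
    )
    assert generation_time(lt) == pytest.approx(3.0)


def test_leslie_subdiagonal_reconstructs_survivorship(table_factory):
    rng = np.random.default_rng(44)
    for _ in range(50):
        lt = table_factory(rng)
        A = build_leslie(lt)
        n = len(A)
        assert np.allclose(A[0, :], lt.m)
        off_pattern = A.copy()
        off_pattern[0, :] = 0.0
        off_pattern[np.arange(1, n), np.arange(n - 1)] = 0.0
        assert np.all(off_pattern == 0.0)
        l_rebuilt = np.concatenate(
            [[1.0], np.cumprod(A[np.arange(1, n), np.arange(n - 1)])]
        )
        np.testing.assert_allclose(l_rebuilt, lt.l, atol=1e-12)


def test_leslie_needs_positive_survivorship_before_omega():
    lt = LifeTable(
        sex="F",
        q=np.array([1.0, 0.5, 0.5]),
        l=np.array([1.0, 0.0, 0.0]),
        m=np.array([0.0, 0.0, 0.5]),
        N_q=None,
        N_m=None,
        omega=2,
    )
    with pytest.raises(ComputationError):
        build_leslie(lt)


def test_eigen_pair_identities(table_factory):
    rng = np.random.default_rng(45)
    for _ in range(50):
        A = build_leslie(table_factory(rng))
        lam, w, v = eigen_analysis(A)
        assert np.max(np.abs(A @ w - lam * w)) < 1e-9
        assert np.max(np.abs(v @ A - lam * v)) < 1e-9
        assert w.sum() == pytest.approx(1.0)
        assert v[0] == pytest.approx(1.0)
        assert np.all(w >= 0)


def test_power_iteration_agrees_with_full_decomposition(table_factory):
    rng = np.random.default_rng(46)
    for _ in range(10):
        A = build_leslie(table_factory(rng))
        lam, _, _ = eigen_analysis(A)
        assert power_iteration_lambda(A) == pytest.approx(lam, rel=1e-9)


def test_periodic_schedule_still_returns_the_real_root():
    # single reproductive age -> eigenvalue modulus is three-fold tied;
    # the real positive (Perron) root must be selected
    A = leslie_from_rates([0.5, 0.5], [0.0, 0.0, 8.0])
    lam, _, _ = eigen_analysis(A)
    assert lam == pytest.approx(2.0 ** (1 / 3))


def test_growth_rate_sides_with_net_reproduction(table_factory):
    rng = np.random.default_rng(47)
    for _ in range(30):
        lt = table_factory(rng)
        r0 = net_reproductive_rate(lt)
        lam, _, _ = eigen_analysis(build_leslie(lt))
        if r0 > 1:
            assert lam > 1
        elif r0 < 1:
            assert lam < 1
    # exact boundary: the two-class table with R0 = 1
    boundary = LifeTable(
        sex="F",
        q=np.array([0.5, 1.0]),
        l=np.array([1.0, 0.5]),
        m=np.array([0.0, 2.0]),
        N_q=None,
        N_m=None,
        omega=1,
    )
    lam, _, _ = eigen_analysis(build_leslie(boundary))
    assert lam == pytest.approx(1.0, abs=1e-12)


def test_life_expectancy_trivial_chains():
    np.testing.assert_allclose(
        life_expectancy(leslie_from_rates([0.5], [0.0, 0.0])), [1.5, 1.0]
    )
    np.testing.assert_allclose(
        life_expectancy(leslie_from_rates([0.0, 0.0], [0.0, 0.0, 0.0])), [1.0, 1.0, 1.0]
    )


def test_reproductive_value_peaks_near_first_reproduction():
    lt = true_life_table(default_config(n_births=10, seed=0))
    _, _, v = eigen_analysis(build_leslie(lt))
    peak = int(np.argmax(v))
    assert peak == 3  # first reproductive age of the reference schedule
    assert np.all(np.diff(v[: peak + 1]) > 0)
    assert np.all(np.diff(v[peak:]) < 0)


def test_survival_to_median_afr_lookup_and_interpolation():
    lt = LifeTable(
        sex="F",
        q=np.array([0.2, 0.25, 1.0]),
        l=np.array([1.0, 0.8, 0.6]),
        m=np.array([0.0, 0.0, 1.0]),
        N_q=None,
        N_m=None,
        omega=2,
    )
    assert survival_to_median_afr(lt, afr_of(2.0)) == pytest.approx(0.6)
    assert survival_to_median_afr(lt, afr_of(0.0)) == pytest.approx(1.0)
    assert survival_to_median_afr(lt, afr_of(1.5), interpolate=True) == pytest.approx(0.7)
    with pytest.raises(ValidationError):
        survival_to_median_afr(lt, afr_of(5.0))


def test_summary_bundles_every_statistic(micro_table):
    s = summarize(micro_table, afr=afr_of(1.0))
    assert s.R0 == pytest.approx(1.0)
    assert s.lam == pytest.approx(1.0)
    assert s.surv_to_median_afr == pytest.approx(0.5)
    assert s.e.shape == s.w.shape == s.v.shape == (2,)


def test_generation_time_undefined_without_reproduction():
    lt = LifeTable(
        sex="F",
        q=np.array([0.5]),
        l=np.array([1.0]),
        m=np.array([0.0]),
        N_q=None,
        N_m=None,
        omega=0,
    )
    with pytest.raises(ComputationError):
        generation_time(lt)
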