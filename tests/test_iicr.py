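import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from islandiicr import (
    IslandDemography,
    StepwiseIICR,
    T2Sample,
    build_rate_matrix,
    empirical_iicr,
    exact_iicr,
    log_grid,
    scale_iicr,
    simulate_t2,
    survival_and_density,
    unscale_iicr,
)
from islandiicr.iicr import _expm2, _transient_block

from conftest import stationary_closed_form

component_params = st.tuples(
    st.integers(2, 30),
    st.floats(0.05, 50.0),
    st.floats(0.2, 5.0),
)


class TestRateMatrix:
    def test_symmetric_two_island_matrix(self):
        Q = build_rate_matrix(2, 1.0, 1.0)
        assert np.allclose(Q, [[-2, 1, 1], [1, -1, 0], [0, 0, 0]])

    def test_rates_scale_with_size_and_islands(self):
        Q = build_rate_matrix(10, 5.0, 2.0)
        assert np.allclose(Q[0], [-5.5, 5.0, 0.5])
        assert np.allclose(Q[1], [5 / 9, -5 / 9, 0.0])

    @given(component_params)
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_generator_rows_sum_to_zero(self, params):
        n, M, s = params
        Q = build_rate_matrix(n, M, s)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        off = Q[~np.eye(3, dtype=bool)]
        assert np.all(off >= 0)

    def test_too_few_islands_rejected(self):
        with pytest.raises(ValueError):
            build_rate_matrix(1, 1.0)

    @given(component_params, st.floats(0.01, 20.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_analytic_expm_matches_scipy(self, params, dt):
        # the spectral 2x2 exponential against the general-purpose one
        A = _transient_block(*params)
        assert np.allclose(_expm2(A, dt), expm(dt * A), atol=1e-12)


class TestSurvivalAndDensity:
    def test_time_zero_values(self, two_component):
        surv, dens = survival_and_density(two_component, 0.0)
        assert surv == pytest.approx(1.0)
        assert dens == pytest.approx(1.0)  # 1 / s_0

    def test_time_zero_density_is_initial_coalescence_rate(self):
        d = IslandDemography(n=3, event_times=(), migration_rates=(1.0,), deme_sizes=(2.0,))
        _, dens = survival_and_density(d, 0.0)
        assert dens == pytest.approx(0.5)

    def test_stationary_matches_spectral_oracle(self):
        surv, dens = survival_and_density(
            IslandDemography(n=2, event_times=(), migration_rates=(1.0,)), 1.0
        )
        o_surv, o_dens, _ = stationary_closed_form(2, 1.0, 1.0, 1.0)
        assert surv == pytest.approx(o_surv[0], abs=1e-12)
        assert dens == pytest.approx(o_dens[0], abs=1e-12)

    def test_merging_spurious_event_changes_nothing(self, grid32):
        plain = IslandDemography(n=5, event_times=(), migration_rates=(2.0,))
        split = IslandDemography(n=5, event_times=(0.7,), migration_rates=(2.0, 2.0))
        a = exact_iicr(plain, grid32).values
        b = exact_iicr(split, grid32).values
        assert np.max(np.abs(a - b)) < 1e-12

    @given(st.floats(0.01, 30.0), st.floats(0.01, 30.0))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_survival_decreasing_and_conserved(self, t1, t2):
        d = IslandDemography(n=4, event_times=(1.0,), migration_rates=(3.0, 0.5))
        lo, hi = sorted((t1, t2))
        s_lo, _ = survival_and_density(d, lo)
        s_hi, _ = survival_and_density(d, hi)
        assert 0 <= s_hi <= s_lo <= 1
        if hi > lo:
            assert s_hi < s_lo

    def test_negative_time_rejected(self, stationary):
        with pytest.raises(ValueError):
            survival_and_density(stationary, -0.1)


class TestExactIICR:
    def test_recent_limit_is_first_deme_size(self, grid32):
        d = IslandDemography(n=6, event_times=(), migration_rates=(1.0,))
        tiny = log_grid(1e-8, 1e-6, 4)
        assert exact_iicr(d, tiny).values == pytest.approx(1.0, rel=1e-4)

    def test_two_island_plateau(self):
        # slowest decay rate of [[-2, 1], [1, -1]] gives plateau (3+sqrt 5)/2
        d = IslandDemography(n=2, event_times=(), migration_rates=(1.0,))
        curve = exact_iicr(d, log_grid(10.0, 50.0, 8))
        assert curve.values[-1] == pytest.approx((3 + np.sqrt(5)) / 2, rel=1e-10)

    def test_strong_migration_approaches_panmixia(self):
        d = IslandDemography(n=5, event_times=(), migration_rates=(1000.0,))
        curve = exact_iicr(d, log_grid(0.1, 10.0, 16))
        assert np.all(np.abs(curve.values - 5.0) / 5.0 < 0.01)

    def test_weak_migration_early_curve_is_single_deme(self):
        d = IslandDemography(n=5, event_times=(), migration_rates=(1e-6,))
        curve = exact_iicr(d, log_grid(1e-3, 0.1, 8))
        assert curve.values == pytest.approx(1.0, rel=1e-3)

    def test_stationary_lattice_matches_spectral_oracle(self, grid32):
        for n in (2, 5, 10, 20):
            for M in (0.1, 1.0, 10.0, 50.0):
                d = IslandDemography(n=n, event_times=(), migration_rates=(M,))
                got = exact_iicr(d, grid32).values
                _, _, want = stationary_closed_form(n, M, 1.0, grid32[1:])
                assert np.max(np.abs(got - want)) < 1e-10

    def test_underflow_far_beyond_horizon_raises(self, stationary):
        with pytest.raises(FloatingPointError, match="t_max"):
            exact_iicr(stationary, log_grid(1.0, 1e6, 16))


class TestScaling:
    def test_scale_by_reference_size(self):
        curve = StepwiseIICR(grid=[0.0, 1.0], values=[1.0])
        scaled = scale_iicr(curve, 1000.0)
        assert scaled.scaled
        assert np.allclose(scaled.grid, [0.0, 2000.0])
        assert np.allclose(scaled.values, [1000.0])

    def test_round_trip_is_identity(self, grid32, two_component):
        curve = exact_iicr(two_component, grid32)
        # powers of two rescale exactly; general N to double precision
        back = unscale_iicr(scale_iicr(curve, 512.0), 512.0)
        assert np.array_equal(back.grid, curve.grid)
        assert np.array_equal(back.values, curve.values)
        back = unscale_iicr(scale_iicr(curve, 350.0), 350.0)
        assert np.allclose(back.grid, curve.grid, rtol=1e-15)
        assert np.allclose(back.values, curve.values, rtol=1e-15)

    def test_fractional_reference_size(self):
        curve = StepwiseIICR(grid=[0.0, 1.0], values=[2.0])
        scaled = scale_iicr(curve, 0.5)
        assert np.allclose(scaled.grid, [0.0, 1.0])
        assert np.allclose(scaled.values, [1.0])

    def test_invalid_N_rejected(self, grid32, stationary):
        with pytest.raises(ValueError):
            scale_iicr(exact_iicr(stationary, grid32), -1.0)


class TestLogGrid:
    def test_geometric_spacing(self):
        g = log_grid(0.01, 100.0, 5)
        assert g[0] == 0.0
        ratios = g[2:] / g[1:-1]
        assert np.allclose(ratios, 10.0)

    def test_endpoints_included(self):
        assert np.allclose(log_grid(0.3, 7.0, 2), [0.0, 0.3, 7.0])

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            log_grid(1.0, 1.0, 8)


class TestT2Simulation:
    def test_isolated_deme_mean_is_one(self):
        d = IslandDemography(n=2, event_times=(), migration_rates=(1e-6,))
        sample = simulate_t2(d, 10_000, seed=1)
        se = sample.draws.std() / np.sqrt(sample.size)
        assert abs(sample.draws.mean() - 1.0) < 3 * se

    def test_survival_matches_spectral_oracle(self):
        d = IslandDemography(n=2, event_times=(), migration_rates=(1.0,))
        sample = simulate_t2(d, 20_000, seed=2)
        surv_true, _, _ = stationary_closed_form(2, 1.0, 1.0, [0.5, 1.0, 2.0])
        for t, p in zip([0.5, 1.0, 2.0], surv_true):
            phat = np.mean(sample.draws > t)
            ci = 2.576 * np.sqrt(p * (1 - p) / sample.size)
            assert abs(phat - p) < ci + 1e-9

    def test_same_seed_reproduces_draws(self, two_component):
        a = simulate_t2(two_component, 100, seed=3)
        b = simulate_t2(two_component, 100, seed=3)
        assert np.array_equal(a.draws, b.draws)


class TestEmpiricalIICR:
    def test_point_mass_hand_arithmetic(self):
        sample = T2Sample(draws=np.ones(50))
        curve = empirical_iicr(sample, np.array([0.0, 0.5, 1.5]))
        assert np.allclose(curve.grid, [0.0, 1.5])
        assert curve.values == pytest.approx([1.0])

    def test_converges_to_exact_iicr(self):
        d = IslandDemography(n=2, event_times=(), migration_rates=(1.0,))
        grid = log_grid(1e-2, 1e2, 32)
        sample = simulate_t2(d, 100_000, seed=4)
        emp = empirical_iicr(sample, grid)
        exact = exact_iicr(d, emp.grid)
        # only score bins holding enough coalescences
        surv = np.array([np.mean(sample.draws > t) for t in emp.grid])
        counts = -np.diff(surv) * sample.size
        rel = np.abs(emp.values - exact.values) / exact.values
        assert np.max(rel[counts >= 100]) < 0.10

    def test_grid_beyond_sample_drops_trailing_intervals(self):
        sample = T2Sample(draws=np.array([0.2, 0.3, 0.4]))
        curve = empirical_iicr(sample, np.array([0.0, 0.25, 0.5, 10.0, 100.0]))
        assert curve.grid[-1] == 0.5
        assert np.all(curve.values > 0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            T2Sample(draws=np.array([]))
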