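import numpy as np
import pytest

from islandiicr import (
    Bounds,
    DistanceSpec,
    IICRInference,
    InferenceSettings,
    IslandDemography,
    ScaledDemography,
    decode,
    encode,
    exact_iicr,
    infer,
    log_grid,
    objective,
    scale_iicr,
)


class TestEncoding:
    def test_round_trip_on_valid_demography(self, wide_bounds):
        d = IslandDemography(n=7, event_times=(0.3, 4.0), migration_rates=(1.0, 9.0, 0.2))
        back = decode(encode(d), 3, wide_bounds(2))
        assert back.n == d.n
        assert back.event_times == pytest.approx(d.event_times, rel=1e-12)
        assert back.migration_rates == pytest.approx(d.migration_rates, rel=1e-12)

    def test_unsorted_time_coordinates_decode_sorted(self, wide_bounds):
        vec = np.array([5.0, np.log10(4.0), np.log10(0.3), 1.0, 2.0, 3.0])
        d = decode(vec, 3, wide_bounds(2))
        assert d.event_times == pytest.approx((0.3, 4.0), rel=1e-12)

    def test_n_coordinate_rounding(self, wide_bounds):
        vec = np.array([9.6, 1.0])
        assert decode(vec, 1, wide_bounds(0)).n == 10

    def test_out_of_bounds_vector_is_clamped(self, wide_bounds):
        vec = np.array([500.0, 10.0, 1e6, 1e6])
        d = decode(vec, 2, wide_bounds(1))
        assert d.n == 50
        assert d.event_times[0] == 100.0
        assert d.migration_rates == (100.0, 100.0)

    def test_scaled_round_trip(self, wide_bounds):
        b = Bounds.uniform(0, n=(2, 50), t=(0.05, 100), M=(0.05, 100), N=(100, 10000))
        d = ScaledDemography(
            N=1234.0, base=IslandDemography(n=5, event_times=(), migration_rates=(2.0,))
        )
        back = decode(encode(d, scaled=True), 1, b, scaled=True)
        assert back.base.n == 5
        assert back.N == pytest.approx(1234.0, rel=1e-12)
        assert back.base.migration_rates == pytest.approx((2.0,), rel=1e-12)


class TestObjective:
    def test_self_distance_is_zero(self, grid32, wide_bounds):
        d = IslandDemography(n=6, event_times=(1.0,), migration_rates=(3.0, 0.4))
        target = exact_iicr(d, grid32)
        s = InferenceSettings(n_components=2, bounds=wide_bounds(1))
        assert objective(encode(d), target, s) < 1e-12

    def test_nonnegative_and_well_defined(self, grid32, wide_bounds):
        d = IslandDemography(n=6, event_times=(1.0,), migration_rates=(3.0, 0.4))
        target = exact_iicr(d, grid32)
        s = InferenceSettings(n_components=2, bounds=wide_bounds(1))
        rng = np.random.default_rng(0)
        for _ in range(10):
            vec = np.array([rng.uniform(2, 50), rng.uniform(-1, 2), *rng.uniform(0.1, 50, 2)])
            assert objective(vec, target, s) >= 0
        # two vectors decoding to the same demography score equally
        v1 = np.array([6.4, 0.0, 3.0, 0.4])
        v2 = np.array([5.6, 0.0, 3.0, 0.4])
        assert objective(v1, target, s) == pytest.approx(objective(v2, target, s))


class TestObjectiveRoutes:
    def test_vectorized_and_compiled_paths_agree(self, grid32, wide_bounds):
        # the population-vectorized numpy evaluator and the compiled
        # single-vector evaluator must implement the same objective
        from islandiicr.inference import _TargetContext

        d = IslandDemography(n=9, event_times=(0.5, 4.0), migration_rates=(8.0, 1.0, 20.0))
        target = exact_iicr(d, grid32)
        ctx = _TargetContext(target, InferenceSettings(n_components=3, bounds=wide_bounds(2)))
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = np.array(
                [rng.uniform(2, 50), rng.uniform(-1.3, 2), rng.uniform(-1.3, 2),
                 *rng.uniform(0.05, 100, 3)]
            )
            a = float(ctx.evaluate(x[:, None])[0])
            assert ctx.scalar(x) == pytest.approx(a, rel=1e-12)


class TestInference:
    def test_vacuous_tolerance_converges_after_min_rounds(self, grid32, wide_bounds):
        d = IslandDemography(n=4, event_times=(), migration_rates=(1.0,))
        target = exact_iicr(d, grid32)
        s = InferenceSettings(
            n_components=1, bounds=wide_bounds(0), tolerance_eps=1e6, max_rounds=10
        )
        res = infer(target, s)
        assert res.converged and res.rounds_used == 1

    def test_seeded_determinism(self, grid32, wide_bounds):
        d = IslandDemography(n=4, event_times=(), migration_rates=(1.0,))
        target = exact_iicr(d, grid32)
        s = InferenceSettings(n_components=1, bounds=wide_bounds(0), max_rounds=3, seed=5)
        a, b = infer(target, s), infer(target, s)
        assert a.best == b.best
        assert a.trace == b.trace

    def test_trace_is_nonincreasing(self, grid32, wide_bounds):
        d = IslandDemography(n=12, event_times=(0.5,), migration_rates=(10.0, 1.0))
        target = exact_iicr(d, grid32)
        s = InferenceSettings(n_components=2, bounds=wide_bounds(1), max_rounds=5,
                              tolerance_eps=1e-30, seed=2)
        res = infer(target, s)
        assert all(b <= a + 1e-18 for a, b in zip(res.trace, res.trace[1:]))
        assert res.distance_achieved == res.trace[-1]

    def test_two_component_self_recovery(self, wide_bounds):
        # known scenario, exact target: n exact, M within 10%, t within 50%
        grid = log_grid(1e-2, 2e2, 64)
        true = IslandDemography(n=9, event_times=(1.2,), migration_rates=(8.0, 0.9))
        target = exact_iicr(true, grid)
        s = InferenceSettings(n_components=2, bounds=wide_bounds(1), max_rounds=50, seed=11)
        res = infer(target, s)
        assert res.best.n == true.n
        for got, want in zip(res.best.migration_rates, true.migration_rates):
            assert abs(got - want) / want < 0.10
        for got, want in zip(res.best.event_times, true.event_times):
            assert abs(got - want) / want < 0.50


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = IICRInference(n_components=3, max_rounds=7)
        params = est.get_params()
        assert params["n_components"] == 3
        clone = IICRInference(**params)
        assert clone.get_params() == params
        est.set_params(max_rounds=9)
        assert est.max_rounds == 9

    def test_fitted_attributes_and_predict(self, grid32, wide_bounds):
        d = IslandDemography(n=4, event_times=(), migration_rates=(1.0,))
        target = exact_iicr(d, grid32)
        est = IICRInference(
            n_components=1, bounds=wide_bounds(0), max_rounds=20, random_state=0
        )
        est.fit(target)
        assert est.demography_.n == 4
        assert est.converged_
        pred = est.predict(grid32[1:])
        assert np.allclose(pred, target.values, rtol=1e-6)
        assert est.score(target) == pytest.approx(0.0, abs=1e-9)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            IICRInference().predict([1.0])

    def test_scale_flag_mismatch_rejected(self, grid32, stationary):
        target = scale_iicr(exact_iicr(stationary, grid32), 1000.0)
        with pytest.raises(ValueError, match="scale"):
            IICRInference(n_components=1).fit(target)


class TestScaledInference:
    def test_recovers_reference_size(self):
        # scaled two-component history at N=1000, human-magnitude grid
        true_base = IslandDemography(n=10, event_times=(1.0,), migration_rates=(5.0, 0.8))
        N = 1000.0
        grid = log_grid(1e-2, 2e2, 64) * 2 * N
        grid[0] = 0.0
        target = scale_iicr(exact_iicr(true_base, log_grid(1e-2, 2e2, 64)), N)
        b = Bounds.uniform(1, n=(2, 50), t=(20.0, 4e5), M=(0.05, 100), N=(1e2, 1e4))
        s = InferenceSettings(
            n_components=2, bounds=b, scaled=True, max_rounds=40, seed=21
        )
        res = infer(target, s)
        assert isinstance(res.best, ScaledDemography)
        assert res.best.base.n == 10
        assert res.best.N == pytest.approx(N, rel=0.10)
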