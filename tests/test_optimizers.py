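"""WOA/GA/PSO: update-rule oracles, convergence, clipping, benchmark table."""

import numpy as np
import pytest

from anklestage import optimizers as opt


# independent straight-line transcription of the update equations
def _oracle_encircle(X, Xs, a, r1, r2):
    return np.array([Xs[k] - (2 * a * r1 - a) * abs(2 * r2 * Xs[k] - X[k])
                     for k in range(len(X))])


def _oracle_spiral(X, Xs, b, l):
    return np.array([Xs[k] + abs(Xs[k] - X[k]) * np.exp(b * l) * np.cos(2 * np.pi * l)
                     for k in range(len(X))])


def _oracle_search(X, Xr, a, r1, r2):
    return np.array([Xr[k] - (2 * a * r1 - a) * abs(2 * r2 * Xr[k] - X[k])
                     for k in range(len(X))])


class TestConvergenceParameter:
    def test_endpoints_and_midpoint(self):
        assert opt.convergence_a(0, 10) == 2.0
        assert opt.convergence_a(10, 10) == 0.0
        assert opt.convergence_a(5, 10) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            opt.convergence_a(11, 10)


class TestUpdateRules:
    def test_encircle_hand_example(self):
        # X*=5, X=3, a=1, r1=1, r2=0.5 -> A1=1, C1=1, D=2, result 3
        out = opt.encircle_update(np.array([3.0]), np.array([5.0]), 1.0, 1.0, 0.5)
        assert out[0] == pytest.approx(3.0)

    def test_encircle_zero_a1_returns_best(self, rng):
        X, Xs = rng.normal(size=5), rng.normal(size=5)
        np.testing.assert_allclose(opt.encircle_update(X, Xs, 1.3, 0.5, 0.8), Xs)

    def test_spiral_hand_example(self):
        # X*=5, X=3, b=1, l=0 -> 5 + 2*e^0*cos(0) = 7
        out = opt.spiral_update(np.array([3.0]), np.array([5.0]), 1.0, 0.0)
        assert out[0] == pytest.approx(7.0)

    def test_spiral_fixed_point_and_cosine_zero(self, rng):
        Xs = rng.normal(size=4)
        np.testing.assert_allclose(opt.spiral_update(Xs.copy(), Xs, 1.0, 0.37), Xs)
        X = rng.normal(size=4)
        np.testing.assert_allclose(opt.spiral_update(X, Xs, 1.0, 0.25), Xs, atol=1e-12)

    def test_search_hand_example(self):
        # Xrand=2, X=6, a=2, r1=1, r2=1 -> A1=2, C1=2, D=|4-6|=2, result -2
        out = opt.search_update(np.array([6.0]), np.array([2.0]), 2.0, 1.0, 1.0)
        assert out[0] == pytest.approx(-2.0)

    def test_updates_match_transcription_oracle(self, rng):
        """Oracle equivalence on 1000 random inputs at 1e-12."""
        for _ in range(1000):
            d = int(rng.integers(1, 6))
            X, Xs = rng.normal(size=d) * 10, rng.normal(size=d) * 10
            a, r1, r2 = rng.uniform(0, 2), rng.uniform(), rng.uniform()
            l = rng.uniform(-1, 1)
            np.testing.assert_allclose(opt.encircle_update(X, Xs, a, r1, r2),
                                       _oracle_encircle(X, Xs, a, r1, r2), atol=1e-12)
            np.testing.assert_allclose(opt.spiral_update(X, Xs, 1.0, l),
                                       _oracle_spiral(X, Xs, 1.0, l), atol=1e-12)
            np.testing.assert_allclose(opt.search_update(X, Xs, a, r1, r2),
                                       _oracle_search(X, Xs, a, r1, r2), atol=1e-12)


def _quad_config(optkw=None, **kw):
    base = dict(n_agents=30, max_iteration=200, dim=1, lb=(-10.0,), ub=(10.0,), seed=0)
    base.update(kw)
    return opt.WoaConfig(**base)


class TestOptimizerContracts:
    @pytest.mark.parametrize("optimizer,tol", [
        (opt.woa_optimize, 1e-3), (opt.ga_optimize, 1e-2), (opt.pso_optimize, 1e-2)])
    def test_converges_on_1d_quadratic(self, optimizer, tol):
        finals = [optimizer(lambda x: float(x[0] ** 2), _quad_config(seed=s)).best_cost
                  for s in range(5)]
        assert np.median(finals) < tol

    @pytest.mark.parametrize("optimizer", [opt.woa_optimize, opt.ga_optimize, opt.pso_optimize])
    def test_trace_non_increasing_and_ends_at_best(self, optimizer):
        run = optimizer(lambda x: float(np.sum(x**2)),
                        _quad_config(dim=3, lb=(-5.0,) * 3, ub=(5.0,) * 3,
                                     max_iteration=50, seed=2))
        assert np.all(np.diff(run.trace) <= 0)
        assert run.best_cost == run.trace[-1]

    @pytest.mark.parametrize("optimizer", [opt.woa_optimize, opt.ga_optimize, opt.pso_optimize])
    def test_same_seed_identical_runs(self, optimizer):
        cfg = _quad_config(max_iteration=30, seed=5)
        a = optimizer(lambda x: float(x[0] ** 2), cfg)
        b = optimizer(lambda x: float(x[0] ** 2), cfg)
        np.testing.assert_array_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.best_pos, b.best_pos)

    def test_zero_iterations_returns_initial_best(self):
        cfg = _quad_config(max_iteration=0, seed=3)
        run = opt.woa_optimize(lambda x: float(x[0] ** 2), cfg)
        rng = np.random.default_rng(3)
        init = rng.uniform(-10, 10, size=(30, 1))
        assert run.best_cost == pytest.approx(float((init**2).min()))

    def test_positions_stay_in_bounds(self):
        seen = []
        def obj(x):
            seen.append(x.copy())
            return float(np.sum(x**2))
        opt.woa_optimize(obj, _quad_config(dim=2, lb=(-1.0, -2.0), ub=(1.0, 2.0),
                                           max_iteration=50, seed=1))
        pts = np.array(seen)
        assert pts[:, 0].min() >= -1 and pts[:, 0].max() <= 1
        assert pts[:, 1].min() >= -2 and pts[:, 1].max() <= 2

    def test_nonfinite_objective_aborts_with_position(self):
        with pytest.raises(ValueError, match="non-finite"):
            opt.woa_optimize(lambda x: float("nan"), _quad_config(max_iteration=1))

    def test_woa_improves_with_larger_budget(self):
        """Median F1 cost in dim 30 decreases as the iteration budget grows."""
        meds = []
        for iters in (50, 200, 500):
            finals = [opt.woa_optimize(
                opt.make_objective("F1"),
                opt.WoaConfig(n_agents=30, max_iteration=iters, dim=30,
                              lb=(-100.0,) * 30, ub=(100.0,) * 30, seed=s)).best_cost
                for s in range(1, 6)]
            meds.append(np.median(finals))
        assert meds[0] > meds[1] > meds[2]


class TestTestFunctions:
    def test_known_minima(self):
        assert opt.test_function("F1", np.zeros(7)) == 0.0
        assert opt.test_function("F6", np.full(4, -0.5)) == 0.0

    def test_f2_hand_value(self):
        assert opt.test_function("F2", np.array([1.0, -2.0])) == pytest.approx(5.0)

    def test_f7_noise_is_seeded_and_bounded(self):
        rng = np.random.default_rng(0)
        vals = [opt.test_function("F7", np.zeros(3), rng) for _ in range(100)]
        assert all(0 <= v < 1 for v in vals)
        rng2 = np.random.default_rng(0)
        assert opt.test_function("F7", np.zeros(3), rng2) == vals[0]

    def test_f7_without_rng_rejected(self):
        with pytest.raises(ValueError):
            opt.test_function("F7", np.zeros(3))

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            opt.test_function("F3", np.zeros(3))


class TestBenchmark:
    def test_small_benchmark_table(self):
        res = opt.benchmark(["F1", "F6"], ["woa", "pso"], n_seeds=2, seed0=1,
                            n_agents=10, max_iteration=50)
        assert set(res["runs"]) == {"woa:F1", "woa:F6", "pso:F1", "pso:F6"}
        for run in res["runs"].values():
            assert len(run["final_costs"]) == 2
            assert all(c >= 0 for c in run["final_costs"])  # F1/F6 non-negative

    def test_benchmark_deterministic(self):
        a = opt.benchmark(["F1"], ["ga"], n_seeds=2, seed0=4, n_agents=10, max_iteration=30)
        b = opt.benchmark(["F1"], ["ga"], n_seeds=2, seed0=4, n_agents=10, max_iteration=30)
        assert a == b

    def test_woa_beats_pso_on_sphere(self):
        res = opt.benchmark(["F1"], ["woa", "pso"], n_seeds=3, seed0=1,
                            n_agents=20, max_iteration=200)
        assert res["runs"]["woa:F1"]["median"] < res["runs"]["pso:F1"]["median"]
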