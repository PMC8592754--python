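"""Unit and property tests for the thermal-exchange optimizer."""

from dataclasses import replace

import numpy as np
import pytest

from mammoteo.benchmarks import get_function
from mammoteo.optimize import (
    Candidate,
    EvaluationError,
    InvalidConfigError,
    TEOConfig,
    adapt_population_size,
    ateo_exchange,
    component_perturbation,
    cooling_factor,
    crossover_accept,
    env_temperature,
    init_population,
    pair_objects,
    run_ateo,
    run_teo,
    time_value,
    update_position,
)

sphere = lambda x: float(np.sum(np.asarray(x) ** 2))


def make_config(**kw):
    defaults = dict(lower=-5.0, upper=5.0, seed=0, max_fes=2000)
    defaults.update(kw)
    return TEOConfig(**defaults)


class TestInitPopulation:
    def test_population_is_ten_times_dimension(self, rng):
        state = init_population(make_config(), 20, rng, sphere)
        assert state.pop_size == 200
        assert state.fe_count == 200

    def test_pop_size_override(self, rng):
        state = init_population(make_config(pop_size=150), 20, rng, sphere)
        assert state.pop_size == 150

    def test_members_respect_bounds_and_theta_endpoints(self, rng):
        state = init_population(make_config(), 3, rng, sphere)
        assert np.all(state.positions >= -5) and np.all(state.positions <= 5)
        # theta = 0 / 1 endpoints of the affine draw
        lo, hi = make_config().bounds(1)
        assert lo[0] + 0.0 * (hi[0] - lo[0]) == -5
        assert lo[0] + 1.0 * (hi[0] - lo[0]) == 5

    def test_uniformity_monte_carlo(self):
        cfg = make_config(lower=0.0, upper=1.0, pop_size=10_000)
        state = init_population(cfg, 1, np.random.default_rng(7), sphere)
        assert abs(state.positions.mean() - 0.5) < 0.02

    def test_nonfinite_bounds_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            init_population(make_config(lower=-np.inf), 2, rng, sphere)

    def test_nonfinite_objective_reported(self, rng):
        with pytest.raises(EvaluationError):
            init_population(make_config(), 2, rng, lambda x: float("nan"))


@pytest.mark.parametrize(
    "cost,worst,expected",
    [(4.0, 4.0, 1.0), (0.0, 4.0, 0.0), (2.0, 4.0, 0.5), (1.0, 0.0, 0.0)],
)
def test_cooling_factor(cost, worst, expected):
    assert cooling_factor(cost, worst) == expected


@pytest.mark.parametrize("it,mx,expected", [(0, 100, 0.0), (100, 100, 1.0), (25, 100, 0.25)])
def test_time_value(it, mx, expected):
    assert time_value(it, mx) == expected


def test_time_value_zero_budget_rejected():
    with pytest.raises(InvalidConfigError):
        time_value(0, 0)


class TestPairing:
    def test_rank_pairing_of_four(self):
        partner = pair_objects(4)
        # best member (rank 0) pairs with rank 2, second with rank 3
        assert partner.tolist() == [2, 3, 0, 1]

    def test_two_members_single_pair(self):
        assert pair_objects(2).tolist() == [1, 0]

    @pytest.mark.parametrize("n", [2, 4, 6, 10, 30])
    def test_pairing_is_an_involution(self, n):
        partner = pair_objects(n)
        assert sorted(partner.tolist()) == list(range(n))
        assert np.array_equal(partner[partner], np.arange(n))

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(InvalidConfigError):
            pair_objects(1)


class TestEnvTemperature:
    def test_zero_delta_is_identity(self):
        prev = np.array([1.0, -2.0])
        assert np.array_equal(env_temperature(prev, 0.5, 0.5, 0.3, 0.0), prev)

    def test_full_decay_gives_zero(self):
        out = env_temperature(np.array([3.0]), 1.0, 0.0, 0.0, 1.0)
        assert np.allclose(out, 0.0)

    def test_hand_computed_value(self):
        out = env_temperature(np.array([1.0]), 0.3, 0.2, 0.5, 1.0)
        assert np.allclose(out, [0.6])


class TestUpdatePosition:
    def test_equal_old_and_env_is_fixed_point(self):
        v = np.array([1.0, 2.0])
        assert np.allclose(update_position(v, v, 0.7, 0.5), v)

    def test_zero_time_keeps_old_position(self):
        old, env = np.array([1.0]), np.array([9.0])
        assert np.allclose(update_position(old, env, 2.0, 0.0), old)

    def test_strong_cooling_relaxes_to_environment(self):
        old, env = np.array([1.0]), np.array([-1.0])
        out = update_position(old, env, 20.0, 1.0)
        assert np.allclose(out, env, atol=1e-6)


class TestPerturbation:
    def test_guard_failure_leaves_candidate_unchanged(self):
        cfg = make_config(pr=0.0)
        cand = Candidate(np.array([1.0, 2.0]), 5.0)
        out = component_perturbation(cand, cfg, 0.5, 0.5, np.random.default_rng(0))
        assert out is cand

    def test_delta_zero_resets_to_lower_bound(self):
        cfg = make_config(pr=1.0, perturbation_decay=False)

        class FakeRng:
            def __init__(self):
                self.calls = 0

            def random(self):
                self.calls += 1
                return 0.0  # triggers (R < pr) and delta = 0

            def integers(self, lo, hi):
                return 1

        cand = Candidate(np.array([1.0, 2.0, 3.0]), 5.0)
        out = component_perturbation(cand, cfg, 0.0, 0.0, FakeRng())
        assert out.position[1] == -5.0

    def test_dimension_choice_is_uniform(self):
        cfg = make_config(pr=1.0)
        rng = np.random.default_rng(3)
        counts = np.zeros(5)
        cand = Candidate(np.zeros(5), 1.0)
        for _ in range(10_000):
            out = component_perturbation(cand, cfg, 0.5, 0.5, rng)
            (j,) = np.nonzero(out.position != cand.position)[0:1]
            if j.size:
                counts[j[0]] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 0.2) < 0.02)


class TestExchange:
    def test_identical_donors_return_best(self):
        best = Candidate(np.array([0.5]), 0.0)
        pos = np.array([[1.0], [1.0], [1.0]])
        lo, hi = np.array([-5.0]), np.array([5.0])
        out = ateo_exchange(best, pos, 0.5, np.random.default_rng(0), lo, hi)
        assert np.allclose(out, best.position)

    def test_gamma_zero_returns_best(self):
        best = Candidate(np.array([0.5]), 0.0)
        pos = np.random.default_rng(0).normal(size=(5, 1))
        out = ateo_exchange(best, pos, 0.0, np.random.default_rng(1),
                            np.array([-5.0]), np.array([5.0]))
        assert np.allclose(out, best.position)

    def test_hand_computed_exchange_vector(self):
        best = Candidate(np.array([0.0]), 0.0)
        pos = np.array([[2.0], [1.0]])

        class FixedRng:
            def choice(self, n, size, replace):
                return np.array([0, 1])

        out = ateo_exchange(best, np.vstack([pos, [[0.0]]]), 0.5, FixedRng(),
                            np.array([-5.0]), np.array([5.0]))
        assert np.allclose(out, [0.5])

    def test_small_population_signals_skip(self):
        best = Candidate(np.array([0.0]), 0.0)
        out = ateo_exchange(best, np.zeros((2, 1)), 0.5, np.random.default_rng(0),
                            np.array([-5.0]), np.array([5.0]))
        assert out is None


class TestCrossover:
    def test_cg_one_trial_equals_exchange(self):
        worst = Candidate(np.zeros(4), 10.0)
        exch = np.ones(4)
        out, spent = crossover_accept(worst, exch, 1.0, sphere, np.random.default_rng(0))
        assert spent == 1
        assert np.array_equal(out.position, exch) or out is worst  # replaced only if better
        # sphere(1,1,1,1)=4 < 10 so the trial must win
        assert np.array_equal(out.position, exch)

    def test_cg_zero_spends_no_evaluation(self):
        worst = Candidate(np.zeros(4), 10.0)
        out, spent = crossover_accept(worst, np.ones(4), 0.0, sphere, np.random.default_rng(0))
        assert out is worst and spent == 0

    def test_worse_trial_is_rejected(self):
        worst = Candidate(np.zeros(2), 0.0)  # already optimal for sphere
        out, spent = crossover_accept(worst, np.ones(2), 1.0, sphere, np.random.default_rng(0))
        assert out is worst and spent == 1


class TestResize:
    def _arrays(self, ps, d=4, seed=0):
        r = np.random.default_rng(seed)
        X = r.normal(size=(ps, d))
        return X, np.array([sphere(x) for x in X])

    def test_no_change_branch(self):
        X, c = self._arrays(100)

        class ZeroRng:
            def uniform(self, a, b):
                return 0.0

        Xn, cn, spent = adapt_population_size(X, c, 4, ZeroRng(), np.full(4, -5.0),
                                              np.full(4, 5.0), sphere, False, 10_000)
        assert Xn is X and spent == 0

    def test_floor_at_dimension(self):
        X, c = self._arrays(10, d=20)

        class MinRng:
            def uniform(self, a, b):
                return -0.5

            def random(self, shape):
                return np.random.default_rng(0).random(shape)

        lo, hi = np.full(20, -5.0), np.full(20, 5.0)
        Xn, cn, _ = adapt_population_size(X, c, 20, MinRng(), lo, hi, sphere, False, 10_000)
        assert Xn.shape[0] == 20  # grown to the dimension floor

    def test_shrink_keeps_lowest_cost_members(self):
        X, c = self._arrays(100)

        class ShrinkRng:
            def uniform(self, a, b):
                return -0.3

        Xn, cn, _ = adapt_population_size(X, c, 4, ShrinkRng(), np.full(4, -5.0),
                                          np.full(4, 5.0), sphere, False, 10_000)
        assert Xn.shape[0] == 70
        assert np.allclose(np.sort(cn), np.sort(c)[:70])

    def test_population_never_below_dimension(self):
        d = 7
        lo, hi = np.full(d, -5.0), np.full(d, 5.0)
        rng = np.random.default_rng(11)
        X, c = self._arrays(20, d=d)
        for _ in range(1000):
            X, c, _ = adapt_population_size(X, c, d, rng, lo, hi, sphere, False, 10**9)
            assert X.shape[0] >= d


class TestRun:
    def test_constant_objective_stops_at_error_floor(self):
        cfg = make_config(max_fes=50_000)
        best, history = run_ateo(lambda x: 0.0, 3, cfg)
        assert best.cost == 0.0
        assert history["fe_count"].iloc[-1] <= 30 + 1  # initial population only

    def test_history_monotone_and_budget_respected(self):
        fn = get_function("rastrigin", 4, -5, 5)
        cfg = make_config(max_fes=4000, vectorized=True, seed=2)
        best, history = run_ateo(fn, 4, cfg)
        assert history["fe_count"].iloc[-1] <= 4000
        assert np.all(np.diff(history["best_cost"]) <= 0)

    def test_sphere_2d_median_final_cost(self):
        finals = []
        for seed in range(1, 21):
            cfg = make_config(max_fes=5000, seed=seed, vectorized=True)
            best, _ = run_ateo(lambda X: np.sum(X * X, axis=-1), 2, cfg)
            finals.append(best.cost)
        assert np.median(finals) < 1e-4

    def test_plain_teo_is_ateo_with_extensions_disabled(self):
        fn = get_function("rastrigin", 5, -5, 5)
        cfg = make_config(max_fes=3000, seed=9, vectorized=True,
                          exchange=False, adapt_population=False)
        b1, h1 = run_ateo(fn, 5, cfg)
        b2, h2 = run_teo(fn, 5, replace(cfg, exchange=True, adapt_population=True))
        assert np.array_equal(b1.position, b2.position)
        assert b1.cost == b2.cost
        assert h1.equals(h2)

    def test_emitted_best_is_within_bounds(self):
        fn = get_function("ackley", 3, -5, 5)
        cfg = make_config(max_fes=3000, seed=4, vectorized=True)
        best, _ = run_ateo(fn, 3, cfg)
        assert np.all(best.position >= -5) and np.all(best.position <= 5)
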