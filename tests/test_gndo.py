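"""GNDO metaheuristic: update equations, screening, reproducibility."""

import numpy as np
import pytest

from planefusion.gndo import (
    Bounds,
    GNDOConfig,
    Individual,
    Population,
    global_exploration,
    gndo_minimize,
    initialize_population,
    local_exploitation,
    screen,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def make_population(positions, fitnesses, bounds=None, seed=0):
    bounds = bounds or Bounds(np.full(positions.shape[1], -10.0), np.full(positions.shape[1], 10.0))
    inds = [Individual(p.astype(float), float(f)) for p, f in zip(positions, fitnesses)]
    return Population(inds, bounds, np.random.default_rng(seed))


class TestInitialization:
    def test_matches_affine_uniform_formula(self):
        bounds = Bounds(np.array([-2.0, 0.0]), np.array([3.0, 5.0]))
        config = GNDOConfig(population_size=6, max_iterations=1, seed=42)
        pop = initialize_population(bounds, config)
        oracle = np.random.default_rng(42)
        span = bounds.upper - bounds.lower
        for ind in pop.individuals:
            expected = bounds.lower + span * oracle.uniform(0.0, 1.0, size=2)
            np.testing.assert_array_equal(ind.position, expected)

    def test_positions_within_bounds(self):
        bounds = Bounds(np.zeros(5), np.ones(5))
        pop = initialize_population(bounds, GNDOConfig(seed=3))
        pos = pop.positions
        assert np.all(pos >= 0.0) and np.all(pos <= 1.0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            Bounds(np.array([1.0]), np.array([1.0]))


class TestLocalExploitation:
    def test_degenerate_population_returns_common_point(self):
        x = np.array([1.5, -0.5])
        pop = make_population(np.tile(x, (4, 1)), [1.0] * 4)
        trial = local_exploitation(pop, 0, np.random.default_rng(0))
        np.testing.assert_array_equal(trial, x)

    def test_mean_and_deviation_arithmetic(self):
        pop = make_population(
            np.array([[0.0], [3.0], [3.0], [6.0]]), [5.0, 0.0, 1.0, 9.0]
        )
        # y_i = 0, y_best = 3, M = 3 -> mu = 2, delta = sqrt(2)
        y, best, mean = pop.individuals[0].position, pop.best.position, pop.mean_position
        mu = (y + best + mean) / 3.0
        delta = np.sqrt(((y - mu) ** 2 + (best - mu) ** 2 + (mean - mu) ** 2) / 3.0)
        np.testing.assert_allclose(mu, [2.0])
        np.testing.assert_allclose(delta, [np.sqrt(2.0)])
        # the trial is mu + delta * eta for some scalar eta
        trial = local_exploitation(pop, 0, np.random.default_rng(1))
        eta = (trial - mu) / delta
        assert np.isfinite(eta).all()

    def test_penalty_factor_is_zero_mean(self):
        # recover eta from a degenerate-direction population and check the
        # Monte-Carlo mean of the heavy-tailed factor vanishes by symmetry
        pop = make_population(
            np.array([[0.0], [3.0], [3.0], [6.0]]), [5.0, 0.0, 1.0, 9.0]
        )
        mu, delta = np.array([2.0]), np.array([np.sqrt(2.0)])
        rng = np.random.default_rng(123)
        etas = np.array(
            [(local_exploitation(pop, 0, rng) - mu)[0] / delta[0] for _ in range(100_000)]
        )
        assert abs(etas.mean()) < 0.01
        assert np.mean(np.abs(etas) > 2.0) > 0.001  # heavy tails reach past 2 sd


class TestGlobalExploration:
    def test_v1_points_toward_fitter_of_self_and_p1(self):
        # individual 0 (fitter) at the origin, every peer at q: the pair
        # differences collapse to v1 = y_0 - y_p1 = -q and v2 = 0, so the
        # move is a non-negative multiple of -q
        rng = np.random.default_rng(0)
        q = np.array([2.0, -1.0])
        pos = np.vstack([np.zeros(2), np.tile(q, (3, 1))])
        pop = make_population(pos, [0.0, 1.0, 1.0, 1.0])
        for _ in range(20):
            trial = global_exploration(pop, 0, rng)
            coeff = trial / -q
            np.testing.assert_allclose(coeff[0], coeff[1], atol=1e-12)
            assert coeff[0] >= 0.0

    def test_all_points_coincident_returns_self(self):
        pos = np.tile(np.array([2.0, -1.0]), (5, 1))
        pop = make_population(pos, [1.0] * 5)
        trial = global_exploration(pop, 2, np.random.default_rng(9))
        np.testing.assert_array_equal(trial, pos[2])

    def test_peer_indices_distinct_from_each_other_and_i(self):
        from planefusion.gndo import _three_distinct

        rng = np.random.default_rng(5)
        for _ in range(10_000):
            p1, p2, p3 = _three_distinct(rng, 6, 2)
            assert len({p1, p2, p3, 2}) == 4

    def test_population_below_four_rejected(self):
        pos = np.zeros((3, 2))
        pop = make_population(pos, [0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            global_exploration(pop, 0, np.random.default_rng(0))


class TestScreening:
    def test_worse_trial_keeps_incumbent_better_trial_adopted(self):
        pos = np.array([[1.0], [2.0], [3.0], [4.0]])
        pop = make_population(pos, [sphere(p) for p in pos])
        trials = np.array([[5.0], [0.5], [3.0], [0.0]])
        screen(pop, trials, sphere)
        got = [ind.position[0] for ind in pop.individuals]
        assert got == [1.0, 0.5, 3.0, 0.0]  # strict improvement only

    def test_non_finite_trial_rejected(self):
        pos = np.array([[1.0], [2.0], [3.0], [4.0]])
        pop = make_population(pos, [sphere(p) for p in pos])
        bad = lambda x: float("nan") if x[0] == 0.5 else sphere(x)
        screen(pop, np.array([[5.0], [0.5], [3.0], [0.0]]), bad)
        assert pop.individuals[1].position[0] == 2.0

    def test_screening_never_increases_minimum_over_random_rounds(self):
        rng = np.random.default_rng(11)
        bounds = Bounds(np.full(5, -5.0), np.full(5, 5.0))
        for _ in range(100):
            pos = rng.uniform(-5, 5, size=(6, 5))
            pop = make_population(pos, [sphere(p) for p in pos], bounds=bounds)
            before = min(ind.fitness for ind in pop.individuals)
            trials = pos + rng.normal(size=pos.shape)
            screen(pop, trials, sphere)
            after = min(ind.fitness for ind in pop.individuals)
            assert after <= before


class TestMinimize:
    def test_mean_position_matches_brute_force(self):
        bounds = Bounds(np.full(3, -1.0), np.full(3, 1.0))
        pop = initialize_population(bounds, GNDOConfig(seed=2), sphere)
        np.testing.assert_allclose(
            pop.mean_position, np.mean([i.position for i in pop.individuals], axis=0)
        )

    def test_trace_length_monotonicity_and_bounds(self):
        bounds = Bounds(np.full(4, -5.0), np.full(4, 5.0))
        best, trace = gndo_minimize(sphere, bounds, GNDOConfig(10, 40, seed=1))
        assert len(trace) == 40
        assert (np.diff(trace["best_fitness"]) <= 1e-15).all()
        assert np.all(np.abs(best.position) <= 5.0)

    def test_fixed_seed_is_bitwise_reproducible(self):
        bounds = Bounds(np.full(4, -5.0), np.full(4, 5.0))
        cfg = GNDOConfig(8, 25, seed=7)
        best1, trace1 = gndo_minimize(sphere, bounds, cfg)
        best2, trace2 = gndo_minimize(sphere, bounds, cfg)
        np.testing.assert_array_equal(best1.position, best2.position)
        assert trace1.equals(trace2)

    def test_single_iteration_and_constant_objective(self):
        bounds = Bounds(np.full(2, 0.0), np.full(2, 1.0))
        _, trace = gndo_minimize(sphere, bounds, GNDOConfig(5, 1, seed=0))
        assert len(trace) == 1
        best, _ = gndo_minimize(lambda x: 3.5, bounds, GNDOConfig(5, 10, seed=0))
        assert best.fitness == 3.5
        assert np.all(best.position >= 0.0) and np.all(best.position <= 1.0)

    def test_population_size_minimum_enforced(self):
        with pytest.raises(ValueError):
            GNDOConfig(population_size=3)
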