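"""Genetic-algorithm operators and the attack loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actispoof import ga
from actispoof.ga import (
    GAConfig,
    attack_all_users,
    blend_crossover,
    evaluate,
    init_population,
    preset_config,
    rank_selection_probabilities,
    run_attack,
    select,
    step_generation,
    uniform_reset_mutation,
)


class StubOracle:
    """Oracle stand-in computing fitness from a plain function of x."""

    def __init__(self, fn, labels=("t",)):
        self.fn = fn
        self.query_count = 0
        self._labels = labels

    def query(self, X, t):
        X = np.atleast_2d(X)
        self.query_count += len(X)
        return np.apply_along_axis(self.fn, 1, X)


def bump_oracle(p, scale=0.18):
    """Smooth unimodal fitness with its maximum (value 1) at p."""
    return StubOracle(lambda x: float(np.exp(-np.sum((x - p) ** 2) / scale)))


class TestConfig:
    def test_presets_map_to_population_sizes(self):
        assert preset_config("weak").population_size == 10
        assert preset_config("medium").population_size == 20
        assert preset_config("strong").population_size == 50
        esc = preset_config("escalated")
        assert esc.population_size == 100 and esc.max_generations == 2000

    def test_elite_count_uses_half_up_rounding(self):
        assert GAConfig(population_size=50).n_elites == 3  # round(2.5) half-up
        assert GAConfig(population_size=10).n_elites == 1
        assert GAConfig(population_size=100).n_elites == 5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.5)
        with pytest.raises(ValueError):
            GAConfig(patience=2000, max_generations=1500)
        with pytest.raises(ValueError):
            preset_config("overwhelming")


class TestInitPopulation:
    def test_shape_and_range(self):
        pop = init_population(10, 24, np.random.default_rng(0))
        assert pop.shape == (10, 24)
        assert np.all((pop >= 0) & (pop <= 1))

    def test_same_seed_same_population(self):
        a = init_population(5, 24, np.random.default_rng(7))
        b = init_population(5, 24, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_genes_are_uniform_on_average(self):
        pop = init_population(5000, 20, np.random.default_rng(1))
        se = np.sqrt(1 / 12 / pop.size)
        assert abs(pop.mean() - 0.5) < 3 * se


class TestEvaluate:
    def test_constant_oracle_sets_constant_fitness(self):
        o = StubOracle(lambda x: 0.3)
        pop = init_population(8, 24, np.random.default_rng(0))
        np.testing.assert_allclose(evaluate(pop, o, "t"), 0.3)
        assert o.query_count == 8

    def test_fitness_matches_per_individual_queries(self, small_rf):
        from actispoof.oracle import make_oracle

        model, train, _ = small_rf
        pop = init_population(12, 24, np.random.default_rng(2))
        batch = evaluate(pop, make_oracle(model), train.y[0])
        singles = [make_oracle(model).query(ind, train.y[0]) for ind in pop]
        np.testing.assert_allclose(batch, singles)


class TestSelect:
    def test_equal_fitness_is_uniform(self):
        rng = np.random.default_rng(0)
        picks = select(np.full(4, 0.5), rng, size=20000)
        freq = np.bincount(picks, minlength=4) / 20000
        assert np.all(np.abs(freq - 0.25) < 0.02)

    def test_two_ranks_follow_one_third_two_thirds(self):
        rng = np.random.default_rng(1)
        picks = select(np.array([0.1, 0.9]), rng, size=30000)
        p_best = np.mean(picks == 1)
        se = np.sqrt(2 / 3 * 1 / 3 / 30000)
        assert abs(p_best - 2 / 3) < 3 * se

    def test_probabilities_are_the_documented_rank_formula(self):
        probs = rank_selection_probabilities(np.array([0.1, 0.2, 0.3, 0.4, 0.5]))
        np.testing.assert_allclose(probs, np.arange(1, 6) * 2 / 30)
        assert probs.sum() == pytest.approx(1.0)
        # ties share averaged rank weight
        np.testing.assert_allclose(
            rank_selection_probabilities(np.array([0.2, 0.2, 0.8])),
            [1.5 / 6, 1.5 / 6, 3 / 6],
        )

    def test_top_ranked_selected_more_than_average(self):
        rng = np.random.default_rng(2)
        fitness = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        picks = select(fitness, rng, size=10000)
        assert np.mean(picks == 4) > 1.2 / 5  # expected 2*5/30 = 1/3


class TestCrossover:
    def test_identical_parents_yield_identical_children(self):
        rng = np.random.default_rng(0)
        p = rng.random(24)
        ca, cb = blend_crossover(p, p.copy(), 1.0, rng)
        np.testing.assert_allclose(ca, p)
        np.testing.assert_allclose(cb, p)

    def test_zero_probability_copies_parents(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(24), rng.random(24)
        ca, cb = blend_crossover(a, b, 0.0, rng)
        np.testing.assert_array_equal(ca, a)
        np.testing.assert_array_equal(cb, b)

    def test_children_stay_within_parent_intervals(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = rng.random(24), rng.random(24)
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            for child in blend_crossover(a, b, 1.0, rng):
                assert np.all(child >= lo - 1e-12) and np.all(child <= hi + 1e-12)


class TestMutation:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        g = rng.random(24)
        np.testing.assert_array_equal(uniform_reset_mutation(g, 0.0, rng), g)

    def test_rate_one_changes_exactly_one_gene(self):
        rng = np.random.default_rng(1)
        g = rng.random(24)
        mutated = uniform_reset_mutation(g, 1.0, rng)
        assert np.sum(mutated != g) == 1

    def test_mutation_rate_is_per_individual(self):
        rng = np.random.default_rng(2)
        g = rng.random(24)
        n = 10000
        hits = sum(
            np.any(uniform_reset_mutation(g, 0.1, rng) != g) for _ in range(n)
        )
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(hits / n - 0.1) < 3 * se

    def test_per_gene_mode_mutates_many_genes(self):
        rng = np.random.default_rng(3)
        g = rng.random(1000)
        mutated = uniform_reset_mutation(g, 0.5, rng, per_gene=True)
        assert 350 < np.sum(mutated != g) < 650


class TestStepGeneration:
    def test_best_fitness_never_decreases_and_size_preserved(self):
        o = bump_oracle(np.full(24, 0.5))
        config = GAConfig(population_size=20, seed=0)
        rng = np.random.default_rng(0)
        pop = init_population(20, 24, rng)
        fit = evaluate(pop, o, "t")
        for _ in range(10):
            new_pop, new_fit = step_generation(pop, fit, o, "t", config, rng)
            assert new_pop.shape == pop.shape
            assert new_fit.max() >= fit.max()
            assert np.all((new_pop >= 0) & (new_pop <= 1))
            pop, fit = new_pop, new_fit


class TestRunAttack:
    def test_flat_zero_oracle_stops_after_patience(self):
        o = StubOracle(lambda x: 0.0)
        config = GAConfig(population_size=10, patience=40, max_generations=500, seed=0)
        result = run_attack(o, "t", config)
        assert result.generations_run == 40
        assert result.best_fitness == 0.0
        assert result.query_count == 10 * 40 == o.query_count

    def test_trace_is_all_time_best_and_queries_accounted(self):
        o = bump_oracle(np.full(24, 0.3))
        config = GAConfig(population_size=10, patience=30, max_generations=200, seed=1)
        result = run_attack(o, "t", config)
        assert np.all(np.diff(result.fitness_trace) >= 0)
        assert result.query_count == config.population_size * result.generations_run
        assert result.query_count == o.query_count
        assert result.best_fitness == result.fitness_trace[-1]

    def test_finds_smooth_bump_optimum_close_to_brute_force(self):
        # d=4 bump with known peak; brute force = best of 1e6 uniform samples
        rng = np.random.default_rng(99)
        p = rng.random(4)
        scale = 0.18

        def fn(X):
            return np.exp(-np.sum((np.atleast_2d(X) - p) ** 2, axis=1) / scale)

        class VecOracle:
            query_count = 0

            def query(self, X, t):
                X = np.atleast_2d(X)
                VecOracle.query_count += len(X)
                return fn(X)

        samples = np.random.default_rng(7).random((1_000_000, 4))
        brute = float(fn(samples).max())
        config = preset_config("strong", seed=5, dimension=4)
        result = run_attack(VecOracle(), "t", config)
        assert result.best_fitness >= brute - 0.05

    def test_max_generations_caps_the_run(self):
        o = bump_oracle(np.full(24, 0.5))
        config = GAConfig(population_size=10, patience=50, max_generations=60, seed=2)
        result = run_attack(o, "t", config)
        assert result.generations_run <= 60


class TestAttackAllUsers:
    def test_results_cover_all_targets_and_are_reproducible(self):
        def fn(x):
            return float(x.mean())

        config = GAConfig(population_size=8, patience=10, max_generations=30, seed=3)
        r1 = attack_all_users(StubOracle(fn), ["a", "b", "c"], config)
        r2 = attack_all_users(StubOracle(fn), ["a", "b", "c"], config)
        assert [r.target_user for r in r1] == ["a", "b", "c"]
        for x, y in zip(r1, r2):
            np.testing.assert_array_equal(x.best_genome, y.best_genome)
            np.testing.assert_array_equal(x.fitness_trace, y.fitness_trace)

    def test_lockstep_batching_equals_sequential_runs(self, small_rf):
        from actispoof.oracle import make_oracle

        model, train, _ = small_rf
        users = sorted(set(train.y))[:3]
        config = GAConfig(population_size=6, patience=8, max_generations=20, seed=4)
        batched = attack_all_users(make_oracle(model), users, config)
        seeds = ga.derive_user_seeds(config.seed, len(users))
        from dataclasses import replace

        for res, u, s in zip(batched, users, seeds):
            solo = run_attack(make_oracle(model), u, replace(config, seed=s))
            np.testing.assert_array_equal(res.best_genome, solo.best_genome)
            np.testing.assert_array_equal(res.fitness_trace, solo.fitness_trace)
            assert res.generations_run == solo.generations_run

    def test_oracle_counter_equals_sum_of_per_run_counts(self):
        o = StubOracle(lambda x: float(x[0]))
        config = GAConfig(population_size=5, patience=5, max_generations=15, seed=6)
        results = attack_all_users(o, ["a", "b"], config)
        assert o.query_count == sum(r.query_count for r in results)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(2, 12),
    patience=st.integers(1, 10),
)
def test_domain_closure_and_monotonicity_properties(seed, n, patience):
    """Any run keeps genomes in [0,1]^d, a non-decreasing trace, and exact
    query accounting."""
    rng = np.random.default_rng(seed)
    p = rng.random(6)
    o = StubOracle(lambda x: float(np.exp(-np.sum((x - p) ** 2))))
    config = GAConfig(
        population_size=n, patience=patience, max_generations=25,
        dimension=6, seed=seed,
    )
    result = run_attack(o, "t", config)
    assert np.all((result.best_genome >= 0) & (result.best_genome <= 1))
    assert np.all(np.diff(result.fitness_trace) >= 0)
    assert result.query_count == n * result.generations_run == o.query_count
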