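import math
from fractions import Fraction

import numpy as np
import pytest

from evobexpa import (
    FitnessFunction,
    GAParams,
    run_bexpa,
    seed_probability,
    seeds_for_solution,
)
from evobexpa.evolution import (
    _CachedEvaluator,
    crossover,
    decode,
    initialize_population,
    mutate,
    next_generation,
    repair,
    tournament_select,
)

FAST = GAParams(population_size=20, max_generations=40, stall_window=15,
                seed_oversampling=5, rng_seed=0)


class TestSeedProbability:
    def test_solution_equals_matrix(self):
        assert seed_probability(10, 8, 10, 8) == 1.0
        assert seed_probability(3, 3, 3, 3) == 1.0

    def test_exact_binomial_ratio(self):
        # independent oracle in exact rational arithmetic
        def comb3(n):
            return Fraction(n * (n - 1) * (n - 2), 6)

        expected = float(comb3(20) * comb3(10) / (comb3(2884) * comb3(17)))
        assert seed_probability(20, 10, 2884, 17) == pytest.approx(
            expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            seed_probability(2, 5, 10, 10)
        with pytest.raises(ValueError):
            seed_probability(20, 5, 10, 10)

    def test_seeds_for_solution_expectation(self):
        n = seeds_for_solution(20, 10, 300, 17, safety=3.0)
        p = seed_probability(20, 10, 300, 17)
        assert n * p >= 3.0
        assert (n - 1) * p < 3.0 + p


class TestGenotypeOps:
    def test_decode_splits_genes_and_conditions(self):
        bits = np.array([1, 0, 1, 0, 0, 1, 1], dtype=np.uint8)
        genes, conds = decode(bits, 4)
        np.testing.assert_array_equal(genes, [0, 2])
        np.testing.assert_array_equal(conds, [1, 2])

    def test_repair_guarantees_two_per_side(self, rng):
        bits = np.zeros(12, dtype=np.uint8)
        repair(bits, 8, rng)
        genes, conds = decode(bits, 8)
        assert genes.size >= 2 and conds.size >= 2

    def test_identical_parents_any_operator(self, rng):
        a = (rng.random(20) < 0.5).astype(np.uint8)
        for op in ("one_point", "two_point", "uniform"):
            c1, c2 = crossover(a, a.copy(), op, rng)
            np.testing.assert_array_equal(c1, a)
            np.testing.assert_array_equal(c2, a)

    def test_one_point_semantics(self):
        class ScriptedRng:
            def integers(self, lo, hi=None):
                return 4

        a = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.uint8)
        b = 1 - a
        c1, c2 = crossover(a, b, "one_point", ScriptedRng())
        np.testing.assert_array_equal(c1, np.zeros(8))
        np.testing.assert_array_equal(c2, np.ones(8))

    def test_positionwise_bit_conservation(self, rng):
        for _ in range(200):
            a = (rng.random(30) < 0.5).astype(np.uint8)
            b = (rng.random(30) < 0.5).astype(np.uint8)
            op = ("one_point", "two_point", "uniform")[int(rng.integers(3))]
            c1, c2 = crossover(a, b, op, rng)
            np.testing.assert_array_equal(c1 + c2, a + b)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            crossover(np.zeros(5, dtype=np.uint8),
                      np.zeros(6, dtype=np.uint8), "uniform", rng)

    def test_simple_mutation_flips_one_bit(self, rng):
        g = np.zeros(25, dtype=np.uint8)
        for _ in range(20):
            out = mutate(g, "simple", FAST, rng)
            assert int(np.abs(out.astype(int) - g.astype(int)).sum()) == 1

    def test_uniform_mutation_limits(self, rng):
        g = (rng.random(30) < 0.5).astype(np.uint8)
        same = mutate(g, "uniform",
                      GAParams(p_uniform_mutation_bit=0.0), rng)
        np.testing.assert_array_equal(same, g)
        flipped = mutate(g, "uniform",
                         GAParams(p_uniform_mutation_bit=1.0), rng)
        np.testing.assert_array_equal(flipped, 1 - g)


class TestTournament:
    def test_k_equals_population_returns_best(self, rng):
        pop = [np.zeros(3, dtype=np.uint8)] * 3
        fits = [3.0, 1.0, 2.0]
        # with k large, all individuals are almost surely sampled
        picks = {tournament_select(pop, fits, 50, rng) for _ in range(20)}
        assert picks == {1}

    def test_selection_pressure_matches_enumeration(self, rng):
        # closed form for k=3 over fitnesses (1,2,3): best chosen unless
        # all three draws miss it -> 1 - (2/3)^3 = 19/27
        pop = [np.zeros(3, dtype=np.uint8)] * 3
        fits = [1.0, 2.0, 3.0]
        draws = 10000
        hits = sum(tournament_select(pop, fits, 3, rng) == 0
                   for _ in range(draws))
        expected = 1 - (2 / 3) ** 3
        assert hits / draws == pytest.approx(expected, abs=0.02)


@pytest.fixture
def planted_fitness(planted_case):
    matrix, truth = planted_case
    return matrix, truth, FitnessFunction(matrix)


class TestInitializePopulation:
    def test_seed_shape_and_selection(self, planted_fitness, rng):
        matrix, _, fn = planted_fitness
        pop, fits = initialize_population(matrix, FAST, fn, rng)
        assert len(pop) == FAST.population_size
        M = matrix.n_genes
        for bits, fit in zip(pop, fits):
            genes, conds = decode(bits, M)
            assert genes.size == 3 and conds.size == 3
            assert fn(genes, conds) == pytest.approx(fit)
        # kept set = best of the oversample => sorted ascending
        assert fits == sorted(fits)

    def test_inflated_seeding_hits_planted_solution(self, planted_fitness):
        matrix, truth, fn = planted_fitness
        n_seeds = seeds_for_solution(20, 10, 100, 17, safety=5.0)
        rng = np.random.default_rng(42)
        pop, fits = initialize_population(matrix, FAST, fn, rng,
                                          n_seeds=n_seeds)
        rows = set(truth.row_positions.tolist())
        cols = set(truth.col_positions.tolist())
        inside = any(
            set(decode(b, matrix.n_genes)[0].tolist()) <= rows
            and set(decode(b, matrix.n_genes)[1].tolist()) <= cols
            for b in pop)
        assert inside


class TestNextGeneration:
    def test_elitism_and_size_preservation(self, planted_fitness):
        matrix, _, fn = planted_fitness
        rng = np.random.default_rng(5)
        evaluator = _CachedEvaluator(fn, matrix.n_genes)
        pop, fits = initialize_population(matrix, FAST, fn, rng)
        for _ in range(30):
            prev_best = min(fits)
            pop, fits = next_generation(pop, fits, evaluator, FAST, rng)
            assert len(pop) == FAST.population_size
            assert min(fits) <= prev_best + 1e-12

    def test_decoded_offspring_always_valid(self, planted_fitness):
        matrix, _, fn = planted_fitness
        rng = np.random.default_rng(6)
        evaluator = _CachedEvaluator(fn, matrix.n_genes)
        pop, fits = initialize_population(matrix, FAST, fn, rng)
        for _ in range(10):
            pop, fits = next_generation(pop, fits, evaluator, FAST, rng)
            for bits in pop:
                genes, conds = decode(bits, matrix.n_genes)
                assert genes.size >= 2 and conds.size >= 2


class TestRunBexpa:
    def test_stall_stops_after_window(self, planted_case):
        matrix, _ = planted_case
        constant = lambda genes, conds: 1.0
        params = GAParams(population_size=10, max_generations=500,
                          stall_window=25, seed_oversampling=2, rng_seed=0)
        _, history = run_bexpa(matrix, params=params, fitness_fn=constant,
                               return_history=True)
        assert len(history) - 1 == params.stall_window

    def test_determinism_same_seed_identical_result(self, planted_case):
        matrix, _ = planted_case
        params = GAParams(population_size=30, max_generations=60,
                          stall_window=20, seed_oversampling=3, rng_seed=77)
        r1, h1 = run_bexpa(matrix, params=params, return_history=True)
        r2, h2 = run_bexpa(matrix, params=params, return_history=True)
        assert r1.gene_ids == r2.gene_ids
        assert r1.condition_ids == r2.condition_ids
        assert r1.metrics == r2.metrics
        assert h1 == h2

    def test_best_fitness_trajectory_monotone(self, planted_case):
        matrix, _ = planted_case
        params = GAParams(population_size=30, max_generations=80,
                          stall_window=30, seed_oversampling=3, rng_seed=9)
        _, history = run_bexpa(matrix, params=params, return_history=True)
        assert all(a >= b - 1e-12 for a, b in zip(history, history[1:]))

    def test_recovers_planted_pattern(self, planted_case):
        matrix, truth = planted_case
        hits = 0
        for seed in range(1, 6):
            record = run_bexpa(matrix, params=GAParams(rng_seed=seed),
                               n_seeds=seeds_for_solution(20, 10, 100, 17))
            genes = set(matrix.gene_index(record.gene_ids).tolist())
            conds = set(matrix.condition_index(record.condition_ids).tolist())
            s_i = len(genes & set(truth.row_positions)) / len(
                genes | set(truth.row_positions))
            s_j = len(conds & set(truth.col_positions)) / len(
                conds | set(truth.col_positions))
            hits += s_i * s_j > 0.9
        assert hits >= 4

    def test_params_validation(self):
        with pytest.raises(ValueError):
            GAParams(max_generations=10, stall_window=20)
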