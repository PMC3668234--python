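"""The inner genetic algorithm (Bexpa): one bicluster per run.

An individual is a fixed-length binary string of length M+N — the first M
bits select genes, the last N bits select conditions.  The population is
seeded with randomly placed 3x3 submatrices (the smallest size at which
shifting-and-scaling coherence is informative: any 2x2 matrix already
follows a perfect pattern), heavily oversampled and filtered to the best.
Each generation keeps the best individual and a mutated copy of it
(elitism), fills 80% of the remaining slots by crossover of
tournament-selected parents and the rest by replication, mutating
offspring with a small probability.  The run stops at ``max_generations``
or when the best fitness has not improved appreciably for
``stall_window`` consecutive generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .fitness import FitnessFunction, ObjectiveWeights, OverlapWeightMatrix
from .matrixio import BiclusterRecord, ExpressionMatrix

__all__ = [
    "GAParams",
    "seed_probability",
    "seeds_for_solution",
    "decode",
    "repair",
    "crossover",
    "mutate",
    "tournament_select",
    "initialize_population",
    "next_generation",
    "run_bexpa",
]

SEED_SIZE = 3  # rows and columns of an initial-population seed

CROSSOVER_OPS = ("one_point", "two_point", "uniform")
MUTATION_OPS = ("simple", "uniform")


@dataclass(frozen=True)
class GAParams:
    """Tunable parameters of the genetic search.

    ``max_generations`` and ``stall_window`` follow the published setup
    (1500 and 150); the remaining operator probabilities are exposed
    because only their qualitative relationship (uniform mutation much
    rarer than simple) is prescribed.
    """

    population_size: int = 200
    max_generations: int = 1500
    stall_window: int = 150
    stall_tolerance: float = 1e-6
    crossover_fraction: float = 0.8
    tournament_size: int = 3
    p_mutate_offspring: float = 0.1
    p_simple_mutation: float = 0.9
    p_uniform_mutation_bit: float = 0.005
    seed_oversampling: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_generations < self.stall_window:
            raise ValueError("max_generations must be >= stall_window")
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValueError("crossover_fraction must be in [0, 1]")

    def with_seed(self, rng_seed: int) -> "GAParams":
        return replace(self, rng_seed=rng_seed)


def seed_probability(sol_I: int, sol_J: int, M: int, N: int) -> float:
    """Probability that a random 3x3 seed lies inside a known solution.

    Counts 3-subsets with binomial coefficients: C(|I|,3) C(|J|,3) /
    (C(M,3) C(N,3)).
    """
    if min(sol_I, sol_J, M, N) < SEED_SIZE:
        raise ValueError("all dimensions must be >= 3 to host a seed")
    if sol_I > M or sol_J > N:
        raise ValueError("solution cannot exceed the matrix")
    p = Fraction(math.comb(sol_I, 3) * math.comb(sol_J, 3),
                 math.comb(M, 3) * math.comb(N, 3))
    return float(p)


def seeds_for_solution(sol_I: int, sol_J: int, M: int, N: int,
                       safety: float = 3.0) -> int:
    """Seed count making the expected number of in-solution seeds >= safety."""
    p = seed_probability(sol_I, sol_J, M, N)
    return int(math.ceil(safety / p))


# ---------------------------------------------------------------------------
# genotype helpers

def decode(bits: np.ndarray, n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """Split an (M+N)-bit string into gene and condition index arrays."""
    on = np.flatnonzero(bits)
    split = np.searchsorted(on, n_genes)
    return on[:split], on[split:] - n_genes


def repair(bits: np.ndarray, n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Ensure at least 2 gene bits and 2 condition bits are set (in place).

    Below two rows or two columns both the pattern measure and the volume
    term degenerate, so the search space is closed over {|I|>=2, |J|>=2}.
    """
    for lo, hi in ((0, n_genes), (n_genes, bits.size)):
        seg = bits[lo:hi]
        while int(seg.sum()) < 2:
            zeros = np.flatnonzero(seg == 0)
            seg[zeros[rng.integers(zeros.size)]] = 1
    return bits


def crossover(a: np.ndarray, b: np.ndarray, op: str,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One-point, two-point or uniform crossover on the full bit string."""
    if a.size != b.size:
        raise ValueError("parent genotypes must have equal length")
    n = a.size
    c1, c2 = a.copy(), b.copy()
    if op == "one_point":
        cut = int(rng.integers(1, n))
        c1[cut:], c2[cut:] = b[cut:], a[cut:]
    elif op == "two_point":
        lo, hi = sorted(rng.choice(n + 1, size=2, replace=False).tolist())
        c1[lo:hi], c2[lo:hi] = b[lo:hi], a[lo:hi]
    elif op == "uniform":
        swap = rng.random(n) < 0.5
        c1[swap], c2[swap] = b[swap], a[swap]
    else:
        raise ValueError(f"unknown crossover operator {op!r}")
    return c1, c2


def mutate(g: np.ndarray, op: str, params: GAParams,
           rng: np.random.Generator) -> np.ndarray:
    """Simple (flip one random bit) or uniform (per-bit flip) mutation."""
    out = g.copy()
    if op == "simple":
        pos = int(rng.integers(out.size))
        out[pos] ^= 1
    elif op == "uniform":
        flips = rng.random(out.size) < params.p_uniform_mutation_bit
        out[flips] ^= 1
    else:
        raise ValueError(f"unknown mutation operator {op!r}")
    return out


def _choose_mutation_op(params: GAParams, rng: np.random.Generator) -> str:
    return "simple" if rng.random() < params.p_simple_mutation else "uniform"


def tournament_select(population: Sequence[np.ndarray],
                      fitnesses: Sequence[float], k: int,
                      rng: np.random.Generator) -> int:
    """Index of the best of k individuals sampled with replacement.

    Ties go to the earliest sampled individual.
    """
    idx = rng.integers(len(population), size=k)
    fits = np.asarray(fitnesses)[idx]
    return int(idx[int(np.argmin(fits))])


# ---------------------------------------------------------------------------
# population machinery

class _CachedEvaluator:
    """Memoises fitness per genotype so elites are never re-evaluated."""

    def __init__(self, fn: Callable[[np.ndarray, np.ndarray], float],
                 n_genes: int) -> None:
        self.fn = fn
        self.n_genes = n_genes
        self.cache: dict[bytes, float] = {}

    def __call__(self, bits: np.ndarray) -> float:
        key = bits.tobytes()
        val = self.cache.get(key)
        if val is None:
            genes, conditions = decode(bits, self.n_genes)
            val = float(self.fn(genes, conditions))
            self.cache[key] = val
        return val


def _distinct_tuples(count: int, universe: int, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(count, size) index rows with distinct entries, by rejection sampling."""
    rows = rng.integers(universe, size=(count, size))
    while True:
        sorted_rows = np.sort(rows, axis=1)
        bad = np.flatnonzero((np.diff(sorted_rows, axis=1) == 0).any(axis=1))
        if bad.size == 0:
            return rows
        rows[bad] = rng.integers(universe, size=(bad.size, size))


def initialize_population(
    m: ExpressionMatrix,
    params: GAParams,
    fitness_fn: Callable[[np.ndarray, np.ndarray], float],
    rng: np.random.Generator,
    n_seeds: int | None = None,
) -> tuple[list[np.ndarray], list[float]]:
    """Oversample random 3x3 seeds and keep the fittest population.

    ``n_seeds`` defaults to ``seed_oversampling * population_size``; for
    synthetic runs with a known planted solution it can be inflated (see
    :func:`seeds_for_solution`) so that at least one seed is expected to
    fall inside the solution.
    """
    M, N = m.shape
    if M < SEED_SIZE or N < SEED_SIZE:
        raise ValueError(f"matrix must be at least {SEED_SIZE}x{SEED_SIZE} "
                         "to host a seed")
    if n_seeds is None:
        n_seeds = params.seed_oversampling * params.population_size
    rows = _distinct_tuples(n_seeds, M, SEED_SIZE, rng)
    cols = _distinct_tuples(n_seeds, N, SEED_SIZE, rng)
    if isinstance(fitness_fn, FitnessFunction):
        fits = fitness_fn.evaluate_seed_batch(rows, cols)
    else:
        fits = np.array([
            fitness_fn(np.sort(rows[s]), np.sort(cols[s]))
            for s in range(n_seeds)
        ])
    keep = np.argsort(fits, kind="stable")[: params.population_size]
    population, fitnesses = [], []
    for s in keep:
        bits = np.zeros(M + N, dtype=np.uint8)
        bits[rows[s]] = 1
        bits[M + cols[s]] = 1
        population.append(bits)
        fitnesses.append(float(fits[s]))
    return population, fitnesses


def next_generation(
    population: list[np.ndarray],
    fitnesses: list[float],
    evaluator: _CachedEvaluator,
    params: GAParams,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[float]]:
    """Elitist generational change preserving population size."""
    n = len(population)
    n_genes = evaluator.n_genes
    best = int(np.argmin(fitnesses))

    new_pop: list[np.ndarray] = [population[best].copy()]
    new_fit: list[float] = [fitnesses[best]]

    mutated_best = mutate(population[best], _choose_mutation_op(params, rng),
                          params, rng)
    repair(mutated_best, n_genes, rng)
    new_pop.append(mutated_best)
    new_fit.append(evaluator(mutated_best))

    remaining = n - 2
    n_cross = round(params.crossover_fraction * remaining)
    offspring: list[np.ndarray] = []
    while len(offspring) < n_cross:
        p1 = tournament_select(population, fitnesses, params.tournament_size, rng)
        p2 = tournament_select(population, fitnesses, params.tournament_size, rng)
        op = CROSSOVER_OPS[int(rng.integers(3))]
        c1, c2 = crossover(population[p1], population[p2], op, rng)
        offspring.append(c1)
        if len(offspring) < n_cross:
            offspring.append(c2)
    for _ in range(remaining - n_cross):
        p = tournament_select(population, fitnesses, params.tournament_size, rng)
        offspring.append(population[p].copy())

    for child in offspring:
        if rng.random() < params.p_mutate_offspring:
            child = mutate(child, _choose_mutation_op(params, rng), params, rng)
        repair(child, n_genes, rng)
        new_pop.append(child)
        new_fit.append(evaluator(child))
    return new_pop, new_fit


def run_bexpa(
    m: ExpressionMatrix,
    overlap: OverlapWeightMatrix | None = None,
    weights: ObjectiveWeights | None = None,
    params: GAParams | None = None,
    n_seeds: int | None = None,
    fitness_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
    return_history: bool = False,
    log: Callable[[str], None] | None = None,
):
    """Search for one bicluster; returns its :class:`BiclusterRecord`.

    ``overlap`` carries both the cell-coverage counts and the order n_b of
    the bicluster being searched (n_b = 1, all-zero counts by default).
    A custom ``fitness_fn(genes, conditions) -> float`` may replace the
    aggregate objective (used for testing search mechanics in isolation).
    With ``return_history`` the best-fitness trajectory (one entry for the
    initial population plus one per generation) is returned alongside.
    """
    weights = weights or ObjectiveWeights()
    params = params or GAParams()
    if overlap is None:
        overlap = OverlapWeightMatrix.zeros(m.shape)
    if fitness_fn is None:
        fitness_fn = FitnessFunction(m, weights=weights, overlap=overlap)
    rng = np.random.default_rng(params.rng_seed)
    evaluator = _CachedEvaluator(fitness_fn, m.n_genes)

    population, fitnesses = initialize_population(m, params, fitness_fn, rng,
                                                  n_seeds=n_seeds)
    best_so_far = min(fitnesses)
    history = [best_so_far]
    stall = 0
    for gen in range(1, params.max_generations + 1):
        population, fitnesses = next_generation(population, fitnesses,
                                                evaluator, params, rng)
        best = min(fitnesses)
        if best_so_far - best >= params.stall_tolerance:
            stall = 0
        else:
            stall += 1
        best_so_far = min(best_so_far, best)
        history.append(best)
        if log is not None:
            gi, ci = decode(population[int(np.argmin(fitnesses))], m.n_genes)
            log(f"gen {gen}: best={best:.6f} mean={np.mean(fitnesses):.6f} "
                f"size={gi.size}x{ci.size}")
        if stall >= params.stall_window:
            break

    best_idx = int(np.argmin(fitnesses))
    genes, conditions = decode(population[best_idx], m.n_genes)
    if isinstance(fitness_fn, FitnessFunction):
        terms = fitness_fn.terms(genes, conditions)
        metrics = {**terms, "fitness": fitness_fn.combine(terms)}
    else:
        metrics = {"fitness": float(fitnesses[best_idx])}
    record = BiclusterRecord(
        gene_ids=[m.gene_ids[i] for i in genes],
        condition_ids=[m.condition_ids[j] for j in conditions],
        order_index=overlap.n_b,
        metrics=metrics,
    )
    if return_history:
        return record, history
    return record
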