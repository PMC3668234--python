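"""Planted-bicluster benchmark generator.

Backgrounds are i.i.d. uniform matrices shaped like a classic yeast cell
cycle compendium (2884 genes x 17 conditions).  Into each background a
perfect combined shifting-and-scaling bicluster is planted at uniformly
random (non-contiguous) row/column positions:

    b_ij = pi_i * alpha_j + beta_j,   alpha_j > 0,

which the transposed Virtual Error scores as exactly 0.  The full
benchmark is 5 planted sizes x 5 replicate backgrounds, each case with
and without additive Gaussian noise (sd 0.25) — 50 cases in total.  A
downscaled profile (300 x 17 background, two planted sizes) is provided
for quick runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrixio import ExpressionMatrix

__all__ = [
    "PlantedPattern",
    "BenchmarkCase",
    "generate_background",
    "plant_pattern",
    "add_noise",
    "build_benchmark_suite",
    "FULL_PROFILE",
    "CI_PROFILE",
]

#: Planted bicluster sizes (genes x conditions) of the full benchmark.
FULL_SIZES = ((20, 10), (60, 12), (100, 13), (150, 15), (200, 16))
NOISE_SD = 0.25
REPLICATES = 5


@dataclass(frozen=True)
class SuiteProfile:
    background_shape: tuple[int, int]
    sizes: tuple[tuple[int, int], ...]
    replicates: int = REPLICATES
    noise_sd: float = NOISE_SD


FULL_PROFILE = SuiteProfile((2884, 17), FULL_SIZES)
#: Reduced profile for fast runs: smaller background, two planted sizes.
CI_PROFILE = SuiteProfile((300, 17), ((20, 10), (60, 12)))


@dataclass
class PlantedPattern:
    """Ground truth of one planted bicluster.

    ``pi`` are per-gene bases, ``alpha`` (positive) and ``beta`` the
    per-condition scaling and shifting factors; positions are the matrix
    indices the pattern occupies.
    """

    pi: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    row_positions: np.ndarray
    col_positions: np.ndarray

    def values(self) -> np.ndarray:
        """The exact (pre-noise) planted submatrix pi_i*alpha_j + beta_j."""
        return np.outer(self.pi, self.alpha) + self.beta[None, :]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pi.size, self.alpha.size


@dataclass
class BenchmarkCase:
    matrix: ExpressionMatrix
    truth: list[PlantedPattern]
    noisy: bool = False
    noise_sd: float = 0.0
    case_id: str = ""


def generate_background(M: int = 2884, N: int = 17, low: float = 0.0,
                        high: float = 50.0,
                        rng: np.random.Generator | None = None) -> ExpressionMatrix:
    """Uniform(low, high) background matrix with generic identifiers."""
    if low >= high:
        raise ValueError("low must be < high")
    rng = rng if rng is not None else np.random.default_rng()
    values = rng.uniform(low, high, size=(M, N))
    return ExpressionMatrix(values,
                            [f"g{i}" for i in range(M)],
                            [f"c{j}" for j in range(N)])


def plant_pattern(m: ExpressionMatrix, size_I: int, size_J: int,
                  rng: np.random.Generator,
                  pi_range: tuple[float, float] = (0.0, 10.0),
                  alpha_range: tuple[float, float] = (0.5, 3.0),
                  beta_range: tuple[float, float] = (-5.0, 5.0),
                  exclude_rows: np.ndarray | None = None) -> PlantedPattern:
    """Overwrite a random size_I x size_J region with a perfect pattern.

    Row and column subsets are uniform random (not necessarily
    contiguous).  ``exclude_rows`` keeps a second pattern's cells disjoint
    from an earlier one by avoiding its rows.  alpha is drawn positive so
    the planted pattern is exactly recognisable by the measure.
    """
    M, N = m.shape
    candidates = np.arange(M)
    if exclude_rows is not None and len(exclude_rows):
        candidates = np.setdiff1d(candidates, np.asarray(exclude_rows))
    if size_I > candidates.size or size_J > N:
        raise ValueError("planted size exceeds available matrix area")
    rows = np.sort(rng.choice(candidates, size=size_I, replace=False))
    cols = np.sort(rng.choice(N, size=size_J, replace=False))
    pi = rng.uniform(*pi_range, size=size_I)
    alpha = rng.uniform(*alpha_range, size=size_J)
    beta = rng.uniform(*beta_range, size=size_J)
    pattern = PlantedPattern(pi=pi, alpha=alpha, beta=beta,
                             row_positions=rows, col_positions=cols)
    m.values[np.ix_(rows, cols)] = pattern.values()
    return pattern


def add_noise(case: BenchmarkCase, sd: float,
              rng: np.random.Generator) -> BenchmarkCase:
    """Return a copy of the case with Normal(0, sd) added to every cell."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    values = case.matrix.values + rng.normal(0.0, sd, size=case.matrix.shape)
    noisy_matrix = ExpressionMatrix(values, list(case.matrix.gene_ids),
                                    list(case.matrix.condition_ids))
    return BenchmarkCase(matrix=noisy_matrix,
                         truth=[replace(t) for t in case.truth],
                         noisy=True, noise_sd=sd,
                         case_id=case.case_id + "_noisy")


def build_benchmark_suite(rng_seed: int,
                          profile: SuiteProfile = FULL_PROFILE) -> list[BenchmarkCase]:
    """All cases of the planted-bicluster benchmark, deterministically.

    For each planted size, ``replicates`` independent backgrounds receive
    one pattern each (values redrawn per case); every noise-free case is
    paired with a noisy twin sharing the same underlying matrix.
    """
    rng = np.random.default_rng(rng_seed)
    M, N = profile.background_shape
    clean: list[BenchmarkCase] = []
    for size_I, size_J in profile.sizes:
        for rep in range(profile.replicates):
            matrix = generate_background(M, N, rng=rng)
            truth = plant_pattern(matrix, size_I, size_J, rng)
            clean.append(BenchmarkCase(
                matrix=matrix, truth=[truth], noisy=False, noise_sd=0.0,
                case_id=f"{size_I}x{size_J}_rep{rep}"))
    noisy = [add_noise(case, profile.noise_sd, rng) for case in clean]
    return clean + noisy
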