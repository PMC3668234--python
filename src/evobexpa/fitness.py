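"""The configurable aggregate objective function.

A candidate bicluster B is scored (lower is better) by

    Phi(B) = VE^t(B)/VE^t(M) + w_s * Vol(B) + w_ov * Overlap(B)
             + w_var * 1/(1 + GeneVar(B))

where M is the whole expression matrix treated as one bicluster, Vol is a
two-term logarithmic volume reward (negative, decreasing in each
dimension, shaped by w_g and w_c), Overlap penalises re-use of matrix
cells already covered by earlier solutions via an integer weight matrix W,
and the variance term prefers genes with fluctuating expression.  Setting
any weight to zero disables the corresponding objective, and additional
``(term_function, weight)`` pairs can be appended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .matrixio import ExpressionMatrix
from .metrics import BiclusterLike, as_submatrix, gene_variance, vet

__all__ = [
    "ObjectiveWeights",
    "OverlapWeightMatrix",
    "volume_term",
    "overlap_term",
    "aggregate_fitness",
    "FitnessFunction",
]


@dataclass(frozen=True)
class ObjectiveWeights:
    """The five tunable weights controlling the aggregate objective.

    Defaults are the experimentally derived values that favour biclusters
    with a low proportion of genes and a high proportion of samples:
    w_g=0.25, w_c=0.5, w_s=5.0, w_ov=5.0, w_var=0.1.
    """

    w_g: float = 0.25
    w_c: float = 0.5
    w_s: float = 5.0
    w_ov: float = 5.0
    w_var: float = 0.1

    def __post_init__(self) -> None:
        for name in ("w_g", "w_c", "w_s", "w_ov", "w_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {"w_g": self.w_g, "w_c": self.w_c, "w_s": self.w_s,
                "w_ov": self.w_ov, "w_var": self.w_var}


@dataclass
class OverlapWeightMatrix:
    """Counts, per matrix cell, how many prior biclusters contained it.

    ``n_b`` is the (1-based) order of the bicluster currently being
    searched; entries can therefore be at most ``n_b - 1``.
    """

    W: np.ndarray
    n_b: int = 1

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        if self.n_b < 1:
            raise ValueError("n_b is 1-based and positive")
        if self.W.min(initial=0) < 0:
            raise ValueError("overlap weights must be non-negative")
        if self.W.size and self.W.max() > self.n_b - 1:
            raise ValueError("overlap weight exceeds n_b - 1")

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "OverlapWeightMatrix":
        return cls(np.zeros(shape, dtype=np.int64), n_b=1)

    def record(self, genes: np.ndarray, conditions: np.ndarray) -> None:
        """Register a found bicluster: increment its cells and advance n_b."""
        self.W[np.ix_(genes, conditions)] += 1
        self.n_b += 1


def _volume_addend(size: int, weight: float) -> float:
    if size < 1:
        raise ValueError("bicluster dimension must be >= 1")
    ln = math.log(size)
    if ln == 0.0 and weight == 0.0:
        return 0.0  # 0/0 resolved by continuity
    return -ln / (ln + weight)


def volume_term(size_I: int, size_J: int, w: ObjectiveWeights) -> float:
    """Vol(B) = -ln|I|/(ln|I|+w_g) - ln|J|/(ln|J|+w_c), in (-2, 0].

    Strictly decreasing in each dimension, so minimisation rewards larger
    biclusters; the weights set how fast each addend saturates towards -1.
    """
    return _volume_addend(size_I, w.w_g) + _volume_addend(size_J, w.w_c)


def overlap_term(genes: np.ndarray, conditions: np.ndarray,
                 overlap: OverlapWeightMatrix) -> float:
    """Overlap(B) = sum of W over B's cells / (|I| |J| (n_b - 1)), in [0, 1].

    The first bicluster (n_b = 1) has no predecessors and scores 0.
    """
    if overlap.n_b == 1:
        return 0.0
    total = int(overlap.W[np.ix_(np.asarray(genes, dtype=np.intp),
                                 np.asarray(conditions, dtype=np.intp))].sum())
    denom = len(genes) * len(conditions) * (overlap.n_b - 1)
    return total / denom


def aggregate_fitness(b: BiclusterLike, vet_matrix: float,
                      overlap: OverlapWeightMatrix,
                      weights: ObjectiveWeights,
                      genes: np.ndarray | None = None,
                      conditions: np.ndarray | None = None) -> float:
    """Evaluate Phi for one bicluster (convenience wrapper; see FitnessFunction)."""
    from .metrics import Bicluster

    if isinstance(b, Bicluster):
        genes, conditions = b.genes, b.conditions
    x = as_submatrix(b)
    if genes is None or conditions is None:
        raise ValueError("gene/condition indices required for the overlap term")
    if vet_matrix <= 0:
        raise ValueError("VE^t of the whole matrix must be positive")
    return (
        vet(x) / vet_matrix
        + weights.w_s * volume_term(x.shape[0], x.shape[1], weights)
        + weights.w_ov * overlap_term(genes, conditions, overlap)
        + weights.w_var / (1.0 + gene_variance(x))
    )


ExtraTerm = tuple[Callable[[np.ndarray], float], float]


@dataclass
class FitnessFunction:
    """Phi bound to a matrix, a weight configuration and an overlap state.

    Caches VE^t(M) once per run.  ``extra_terms`` is an ordered list of
    ``(term_function, weight)`` pairs appended to the built-in objectives;
    each term function receives the bicluster submatrix and must return a
    value to be minimised.
    """

    matrix: ExpressionMatrix
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    overlap: OverlapWeightMatrix | None = None
    extra_terms: Sequence[ExtraTerm] = ()

    def __post_init__(self) -> None:
        if self.overlap is None:
            self.overlap = OverlapWeightMatrix.zeros(self.matrix.shape)
        self.vet_matrix = vet(self.matrix.values)
        if self.vet_matrix <= 0:
            raise ValueError(
                "degenerate matrix: whole-matrix VE^t must be positive to "
                "normalise the pattern term")

    def terms(self, genes: np.ndarray, conditions: np.ndarray) -> dict[str, float]:
        """All objective values for the bicluster (unweighted where applicable)."""
        x = self.matrix.values[np.ix_(genes, conditions)]
        out = {
            "vet": vet(x),
            "volume_term": volume_term(len(genes), len(conditions), self.weights),
            "overlap_term": overlap_term(genes, conditions, self.overlap),
            "gene_variance": gene_variance(x),
        }
        for k, (fn, _) in enumerate(self.extra_terms):
            out[f"extra_{k}"] = fn(x)
        return out

    def combine(self, terms: dict[str, float]) -> float:
        w = self.weights
        phi = (terms["vet"] / self.vet_matrix
               + w.w_s * terms["volume_term"]
               + w.w_ov * terms["overlap_term"]
               + w.w_var / (1.0 + terms["gene_variance"]))
        for k, (_, weight) in enumerate(self.extra_terms):
            phi += weight * terms[f"extra_{k}"]
        return phi

    def __call__(self, genes: np.ndarray, conditions: np.ndarray) -> float:
        return self.combine(self.terms(genes, conditions))

    def evaluate_seed_batch(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorised Phi for a batch of equally-sized seed biclusters.

        ``rows`` is (S, k) gene indices and ``cols`` (S, k') condition
        indices; all S seeds share the same shape, which lets the whole
        batch be standardized in one stacked operation.
        """
        V = self.matrix.values
        B = V[rows[:, :, None], cols[:, None, :]]          # (S, k, k')
        mu_c = B.mean(axis=1, keepdims=True)
        sd_c = B.std(axis=1, keepdims=True)
        b_hat = np.divide(B - mu_c, sd_c, out=np.zeros_like(B), where=sd_c > 0)
        rho = B.mean(axis=2)
        mu_r = rho.mean(axis=1, keepdims=True)
        sd_r = rho.std(axis=1, keepdims=True)
        rho_hat = np.divide(rho - mu_r, sd_r, out=np.zeros_like(rho),
                            where=sd_r > 0)
        vet_b = np.abs(b_hat - rho_hat[:, :, None]).mean(axis=(1, 2))
        gv = ((B - rho[:, :, None]) ** 2).mean(axis=(1, 2))
        vol = volume_term(rows.shape[1], cols.shape[1], self.weights)
        if self.overlap.n_b > 1:
            Wsum = self.overlap.W[rows[:, :, None], cols[:, None, :]].sum(axis=(1, 2))
            ov = Wsum / (rows.shape[1] * cols.shape[1] * (self.overlap.n_b - 1))
        else:
            ov = np.zeros(rows.shape[0])
        phi = (vet_b / self.vet_matrix
               + self.weights.w_s * vol
               + self.weights.w_ov * ov
               + self.weights.w_var / (1.0 + gv))
        if self.extra_terms:
            for fn, weight in self.extra_terms:
                phi = phi + weight * np.array([fn(B[s]) for s in range(B.shape[0])])
        return phi
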