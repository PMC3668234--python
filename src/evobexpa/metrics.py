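"""Bicluster coherence measures.

The central measure is the transposed Virtual Error (VE^t): the mean
absolute deviation between the per-condition standardized bicluster values
and the standardized *virtual condition* (the vector of row means).  It is
zero exactly on biclusters following the combined shifting-and-scaling
pattern b_ij = pi_i * alpha_j + beta_j with positive alpha_j, because each
such column is a positive affine image of the virtual condition and
per-column standardization removes affine differences.

MSR (mean squared residue), SMSR (its scaling counterpart) and mean gene
variance are provided as companion measures: MSR vanishes only on shifting
(additive) patterns, SMSR only on multiplicative ones, while VE^t handles
both simultaneously.

All measures accept either a :class:`Bicluster` view into an
:class:`~evobexpa.matrixio.ExpressionMatrix` or a raw 2-D array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .matrixio import ExpressionMatrix

__all__ = [
    "Bicluster",
    "StandardizedBicluster",
    "UndefinedMetricError",
    "virtual_condition",
    "standardize",
    "vet",
    "msr",
    "smsr",
    "gene_variance",
]

#: Absolute tolerance below which a pattern is considered perfect.
PERFECT_PATTERN_TOL = 1e-9


class UndefinedMetricError(ZeroDivisionError):
    """A metric's defining formula divides by zero for this bicluster."""


@dataclass
class Bicluster:
    """A pair of index sets (genes I, conditions J) over a parent matrix."""

    parent: ExpressionMatrix
    genes: np.ndarray
    conditions: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.intp)
        self.conditions = np.asarray(self.conditions, dtype=np.intp)
        m, n = self.parent.shape
        if self.genes.size < 1 or self.conditions.size < 1:
            raise ValueError("bicluster index sets must be non-empty")
        if len(set(self.genes.tolist())) != self.genes.size:
            raise ValueError("duplicate gene indices")
        if len(set(self.conditions.tolist())) != self.conditions.size:
            raise ValueError("duplicate condition indices")
        if self.genes.min() < 0 or self.genes.max() >= m:
            raise ValueError("gene index out of range")
        if self.conditions.min() < 0 or self.conditions.max() >= n:
            raise ValueError("condition index out of range")

    @property
    def submatrix(self) -> np.ndarray:
        return self.parent.values[np.ix_(self.genes, self.conditions)]

    @property
    def gene_ids(self) -> list[str]:
        return [self.parent.gene_ids[i] for i in self.genes]

    @property
    def condition_ids(self) -> list[str]:
        return [self.parent.condition_ids[j] for j in self.conditions]


BiclusterLike = Union[Bicluster, np.ndarray]


def as_submatrix(b: BiclusterLike) -> np.ndarray:
    """Return the |I| x |J| value matrix of a bicluster (or pass an array through)."""
    if isinstance(b, Bicluster):
        return b.submatrix
    arr = np.asarray(b, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("bicluster values must form a non-empty 2-D matrix")
    return arr


@dataclass
class StandardizedBicluster:
    """Per-condition z-scores of a bicluster plus its standardized virtual condition."""

    b_hat: np.ndarray
    rho: np.ndarray
    rho_hat: np.ndarray


def virtual_condition(b: BiclusterLike) -> np.ndarray:
    """Row means of the bicluster: the common tendency of its genes."""
    return as_submatrix(b).mean(axis=1)


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    # Population sd; an exactly constant column standardizes to all zeros
    # (constant columns are pattern-compatible, not an error).
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = x - mu
    nonzero = sd > 0
    out[:, nonzero] /= sd[nonzero]
    out[:, ~nonzero] = 0.0
    return out


def standardize(b: BiclusterLike) -> StandardizedBicluster:
    """Standardize each condition column and the virtual condition.

    Means and deviations are taken over the bicluster's own genes only:
    this is the choice under which a perfect shifting+scaling pattern
    standardizes every column onto the standardized virtual condition.
    """
    x = as_submatrix(b)
    rho = x.mean(axis=1)
    b_hat = _zscore_columns(x)
    rho_hat = _zscore_columns(rho[:, None])[:, 0]
    return StandardizedBicluster(b_hat=b_hat, rho=rho, rho_hat=rho_hat)


def vet(b: BiclusterLike) -> float:
    """Transposed Virtual Error: mean |b_hat_ij - rho_hat_i|.

    Always >= 0; equals 0 (to numerical precision) iff every condition
    column is a positive affine transform of the virtual condition.
    """
    std = standardize(b)
    return float(np.abs(std.b_hat - std.rho_hat[:, None]).mean())


def msr(b: BiclusterLike) -> float:
    """Mean squared residue: zero exactly on additive (shifting) patterns."""
    x = as_submatrix(b)
    row = x.mean(axis=1, keepdims=True)
    col = x.mean(axis=0, keepdims=True)
    overall = x.mean()
    resid = x - row - col + overall
    return float((resid ** 2).mean())


def smsr(b: BiclusterLike) -> float:
    """Scaling mean squared residue: zero exactly on multiplicative patterns.

    Raises :class:`UndefinedMetricError` when any row or column mean is
    zero, since the formula divides by their squares.
    """
    x = as_submatrix(b)
    row = x.mean(axis=1, keepdims=True)
    col = x.mean(axis=0, keepdims=True)
    if np.any(row == 0.0) or np.any(col == 0.0):
        raise UndefinedMetricError("SMSR undefined: zero row or column mean")
    overall = x.mean()
    num = (row * col - x * overall) ** 2
    return float((num / (row ** 2 * col ** 2)).mean())


def gene_variance(b: BiclusterLike) -> float:
    """Mean per-gene variance over the bicluster's conditions.

    High values indicate fluctuating (non-trivial) genes; the evolutionary
    fitness rewards them through an inverse term.
    """
    x = as_submatrix(b)
    dev = x - x.mean(axis=1, keepdims=True)
    return float((dev ** 2).mean())
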