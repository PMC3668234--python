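"""Expression-matrix and result-set I/O.

The on-disk contract for expression data is plain delimited text: a header
row of condition identifiers and a first column of gene identifiers, every
remaining cell a finite real.  Result sets are written as JSON (identifier
lists plus per-bicluster metric values) with a sibling human-readable
summary in the style of a per-algorithm results table row.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BiclusterRecord",
    "MatrixFormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_result_set",
    "read_result_set",
    "summarize_records_text",
]


class MatrixFormatError(ValueError):
    """Raised when an input file violates the expression-matrix contract."""


@dataclass
class ExpressionMatrix:
    """A genes x conditions real matrix with identifier metadata.

    Rows are genes, columns are experimental conditions.  The matrix must
    be complete (no missing values) and have unique identifiers on both
    axes.  The evolutionary search additionally requires at least 3x3 (the
    smallest size able to host a search seed); that is enforced at search
    time, not on load.
    """

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        if self.values.ndim != 2:
            raise MatrixFormatError("expression values must form a 2-D matrix")
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.condition_ids):
            raise MatrixFormatError(
                f"shape {m}x{n} does not match {len(self.gene_ids)} gene ids "
                f"and {len(self.condition_ids)} condition ids"
            )
        if m < 1 or n < 1:
            raise MatrixFormatError("empty expression matrix")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixFormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"condition {self.condition_ids[j]!r}"
            )
        if len(set(self.gene_ids)) != m:
            raise MatrixFormatError("duplicate gene identifiers")
        if len(set(self.condition_ids)) != n:
            raise MatrixFormatError("duplicate condition identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def gene_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in ids], dtype=np.intp)

    def condition_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {c: j for j, c in enumerate(self.condition_ids)}
        return np.array([lookup[c] for c in ids], dtype=np.intp)


@dataclass
class BiclusterRecord:
    """A discovered bicluster, serialised by identifier (never by index)."""

    gene_ids: list[str]
    condition_ids: list[str]
    order_index: int
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1 or len(self.condition_ids) < 1:
            raise ValueError("a bicluster record needs >=1 gene and condition")
        if self.order_index < 1:
            raise ValueError("order_index is 1-based and positive")


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(path)[1].lower()
    return "," if ext == ".csv" else "\t"


def read_expression_matrix(path: str, delimiter: str | None = None) -> ExpressionMatrix:
    """Load a delimited expression matrix.

    The delimiter is inferred from the extension (``.csv`` -> comma,
    anything else -> tab) unless given explicitly.  Any cell that does not
    parse as a finite real raises :class:`MatrixFormatError` naming the
    offending gene/condition.
    """
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str,
                     keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: empty expression matrix")
    gene_ids = [str(g) for g in df.index]
    condition_ids = [str(c) for c in df.columns]
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=np.float64)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            try:
                v = float(cell)
            except ValueError:
                v = math.nan
            if not math.isfinite(v):
                raise MatrixFormatError(
                    f"{path}: cell at gene {gene_ids[i]!r}, condition "
                    f"{condition_ids[j]!r} is not a finite number: {cell!r}"
                )
            values[i, j] = v
    return ExpressionMatrix(values, gene_ids, condition_ids)


def write_expression_matrix(matrix: ExpressionMatrix, path: str,
                            delimiter: str | None = None) -> None:
    """Write a matrix in the same delimited layout :func:`read_expression_matrix` expects."""
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                      columns=matrix.condition_ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    # Sample (n-1) deviation; a single observation reports sd 0.
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        return float("nan"), float("nan")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def summarize_records_text(records: Sequence[BiclusterRecord]) -> str:
    """Human-readable summary: count and mean +/- sd of size and quality metrics."""
    lines = [f"{len(records)} biclusters"]
    if not records:
        return "\n".join(lines) + "\n"
    specs = [
        ("genes", [len(r.gene_ids) for r in records]),
        ("conditions", [len(r.condition_ids) for r in records]),
        ("vet", [r.metrics.get("vet", math.nan) for r in records]),
        ("gene_variance", [r.metrics.get("gene_variance", math.nan) for r in records]),
    ]
    for name, vals in specs:
        mean, sd = _mean_sd(vals)
        lines.append(f"{name}: {mean:.4g} +/- {sd:.4g}")
    return "\n".join(lines) + "\n"


def write_result_set(records: Sequence[BiclusterRecord], path: str,
                     matrix_name: str = "", weights: dict | None = None) -> None:
    """Write a JSON result set plus a sibling ``<path>.summary.txt``."""
    payload = {
        "matrix": matrix_name,
        "weights": dict(weights) if weights else {},
        "biclusters": [
            {
                "n_b": r.order_index,
                "genes": list(r.gene_ids),
                "conditions": list(r.condition_ids),
                **{k: float(v) for k, v in r.metrics.items()},
            }
            for r in records
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    with open(path + ".summary.txt", "w") as fh:
        fh.write(summarize_records_text(records))


_METRIC_KEYS = ("vet", "volume_term", "overlap_term", "gene_variance", "fitness")


def read_result_set(path: str) -> list[BiclusterRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    records = []
    for entry in payload["biclusters"]:
        metrics = {k: float(entry[k]) for k in _METRIC_KEYS if k in entry}
        records.append(BiclusterRecord(
            gene_ids=list(entry["genes"]),
            condition_ids=list(entry["conditions"]),
            order_index=int(entry["n_b"]),
            metrics=metrics,
        ))
    return records
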