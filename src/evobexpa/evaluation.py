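"""Recovery scoring against planted ground truth, and result summaries.

Match scores are Jaccard indexes: S_I on gene sets, S_J on condition
sets, and the bicluster match score is their product S_I * S_J — 0 for
disjoint biclusters, 1 for a complete match.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matrixio import BiclusterRecord, ExpressionMatrix
from .synthetic import PlantedPattern

__all__ = [
    "MatchScoreReport",
    "gene_match_score",
    "condition_match_score",
    "bicluster_match_score",
    "score_result_set",
    "summarize_result_set",
    "write_score_csv",
]


@dataclass
class MatchScoreReport:
    gene_score: float
    condition_score: float
    bicluster_score: float
    case_id: str = ""
    algorithm: str = ""
    truth_index: int = -1

    def __post_init__(self) -> None:
        assert math.isclose(self.bicluster_score,
                            self.gene_score * self.condition_score)


def _jaccard(a: Iterable, b: Iterable) -> float:
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise ValueError("match score undefined for two empty sets")
    return len(sa & sb) / len(union)


def gene_match_score(I1: Iterable, I2: Iterable) -> float:
    """S_I(I1, I2) = |I1 n I2| / |I1 u I2|."""
    return _jaccard(I1, I2)


def condition_match_score(J1: Iterable, J2: Iterable) -> float:
    """S_J(J1, J2) = |J1 n J2| / |J1 u J2|."""
    return _jaccard(J1, J2)


def bicluster_match_score(genes1: Iterable, conditions1: Iterable,
                          genes2: Iterable, conditions2: Iterable) -> float:
    """S_I * S_J: 1 when the biclusters completely match, 0 when disjoint."""
    return (gene_match_score(genes1, genes2)
            * condition_match_score(conditions1, conditions2))


def score_result_set(records: Sequence[BiclusterRecord],
                     truth: Sequence[PlantedPattern],
                     matrix: ExpressionMatrix,
                     case_id: str = "", algorithm: str = "evobexpa",
                     ) -> list[MatchScoreReport]:
    """Score each record against its best-matching planted pattern.

    When several truths exist, each record is assigned to the truth
    maximising the bicluster match score (ties: first truth in order).
    """
    if not truth:
        raise ValueError("at least one ground-truth pattern is required")
    reports = []
    for record in records:
        genes = set(matrix.gene_index(record.gene_ids).tolist())
        conditions = set(matrix.condition_index(record.condition_ids).tolist())
        best = None
        for t_idx, t in enumerate(truth):
            s_i = gene_match_score(genes, t.row_positions.tolist())
            s_j = condition_match_score(conditions, t.col_positions.tolist())
            if best is None or s_i * s_j > best[0]:
                best = (s_i * s_j, s_i, s_j, t_idx)
        score, s_i, s_j, t_idx = best
        reports.append(MatchScoreReport(
            gene_score=s_i, condition_score=s_j, bicluster_score=score,
            case_id=case_id, algorithm=algorithm, truth_index=t_idx))
    return reports


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=np.float64)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def summarize_result_set(records: Sequence[BiclusterRecord]) -> dict:
    """Count plus mean +/- sample sd of |I|, |J|, VE^t and gene variance."""
    if not records:
        return {"count": 0}
    out: dict[str, float | int] = {"count": len(records)}
    for key, vals in (
        ("genes", [len(r.gene_ids) for r in records]),
        ("conditions", [len(r.condition_ids) for r in records]),
        ("vet", [r.metrics.get("vet", math.nan) for r in records]),
        ("gene_variance",
         [r.metrics.get("gene_variance", math.nan) for r in records]),
    ):
        mean, sd = _mean_sd(vals)
        out[f"{key}_mean"], out[f"{key}_sd"] = mean, sd
    return out


def write_score_csv(reports: Sequence[MatchScoreReport], path: str) -> None:
    """Per-case score table suitable for external rank testing."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "algorithm", "gene_score",
                         "condition_score", "bicluster_score"])
        for r in reports:
            writer.writerow([r.case_id, r.algorithm,
                             f"{r.gene_score:.6f}", f"{r.condition_score:.6f}",
                             f"{r.bicluster_score:.6f}"])
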