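"""Sequential-covering driver: extract n biclusters one at a time.

The outer loop maintains an integer weight matrix W, all-zero at the
start; after each inner genetic search the cells of the found bicluster
are incremented.  The overlap term of the fitness reads W, so later
searches are steered away from already-covered cells without ever
modifying the expression values themselves (in contrast to approaches
that mask found biclusters with random data).
"""

from __future__ import annotations

from typing import Callable

from .evolution import GAParams, run_bexpa
from .fitness import ObjectiveWeights, OverlapWeightMatrix
from .matrixio import BiclusterRecord, ExpressionMatrix

__all__ = ["evo_bexpa"]


def evo_bexpa(
    m: ExpressionMatrix,
    n_biclusters: int,
    weights: ObjectiveWeights | None = None,
    params: GAParams | None = None,
    drop_duplicates: bool = False,
    progress: Callable[[BiclusterRecord], None] | None = None,
) -> list[BiclusterRecord]:
    """Run the inner search ``n_biclusters`` times under overlap control.

    Each inner run draws its random stream from ``params.rng_seed`` plus
    the (0-based) bicluster index, so any single run can be reproduced in
    isolation.  With ``drop_duplicates`` exact repeats of an earlier
    solution are filtered from the returned list (they still consumed a
    run and still updated W).
    """
    if n_biclusters < 1:
        raise ValueError("n_biclusters must be >= 1")
    weights = weights or ObjectiveWeights()
    params = params or GAParams()
    overlap = OverlapWeightMatrix.zeros(m.shape)
    records: list[BiclusterRecord] = []
    seen: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    for k in range(n_biclusters):
        run_params = params.with_seed(params.rng_seed + k)
        record = run_bexpa(m, overlap=overlap, weights=weights,
                           params=run_params)
        overlap.record(m.gene_index(record.gene_ids),
                       m.condition_index(record.condition_ids))
        key = (tuple(record.gene_ids), tuple(record.condition_ids))
        if drop_duplicates and key in seen:
            continue
        seen.add(key)
        records.append(record)
        if progress is not None:
            progress(record)
    return records
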