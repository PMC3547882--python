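"""Expression Similarity (ES) scorer: condition selection + profile correlation."""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .data_io import ExpressionMatrix, PairScoreTable, pair_key

logger = logging.getLogger("linkmark")

MIN_SHARED_CONDITIONS = 3


def select_varying_conditions(matrix: ExpressionMatrix, k: int = 300) -> ExpressionMatrix:
    """Keep the ``k`` most varying conditions.

    Conditions are ranked by the variance of their values across genes
    (missing values excluded), ties broken by condition id; retained columns
    keep their original order.  If ``k`` is at least the number of
    conditions, the matrix is returned unchanged.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= len(matrix.condition_ids):
        return matrix
    variances = np.nanvar(matrix.values, axis=0)
    variances = np.where(np.isfinite(variances), variances, 0.0)
    order = sorted(range(len(matrix.condition_ids)),
                   key=lambda j: (-variances[j], matrix.condition_ids[j]))
    keep = sorted(order[:k])
    values = matrix.values[:, keep]
    # column selection can strand rows below the 2-finite-value floor
    row_ok = np.isfinite(values).sum(axis=1) >= 2
    for gid in np.array(matrix.gene_ids, dtype=object)[~row_ok]:
        logger.info("dropping gene %s after condition selection: <2 finite values", gid)
    return ExpressionMatrix(
        gene_ids=[g for g, ok in zip(matrix.gene_ids, row_ok) if ok],
        condition_ids=[matrix.condition_ids[j] for j in keep],
        values=values[row_ok],
    )


def es_scores(pairs: Iterable[tuple[str, str]], matrix: ExpressionMatrix) -> PairScoreTable:
    """Pearson correlation of expression profiles, clamped below at 0.

    Correlation is computed over conditions where both genes have finite
    values; pairs with fewer than 3 shared conditions, a gene absent from the
    matrix, or a constant profile are undefined with score 0 (logged, not an
    error).
    """
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    X = matrix.values
    finite = np.isfinite(X)
    table = PairScoreTable(method="ES")
    for a, b in (pair_key(*p) for p in pairs):
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            logger.info("ES pair (%s,%s): gene absent from expression matrix", a, b)
            table.set(a, b, 0.0, undefined=True)
            continue
        both = finite[ia] & finite[ib]
        if both.sum() < MIN_SHARED_CONDITIONS:
            table.set(a, b, 0.0, undefined=True)
            continue
        x = X[ia, both]
        y = X[ib, both]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            table.set(a, b, 0.0, undefined=True)
            continue
        r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
        table.set(a, b, min(1.0, max(0.0, r)))
    return table
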