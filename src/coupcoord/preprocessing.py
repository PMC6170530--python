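"""Min-max standardization of raw indicator matrices.

Each indicator column is rescaled to [0, 1] over the plots:
``x' = (x - min) / (max - min)`` for benefit indicators and the
reflection ``x' = (max - x) / (max - min)`` for cost indicators, so
that larger normalized values always mean "better". A constant column
(max == min) carries no information to rank plots by; it is mapped to
all zeros (with a warning) so the entropy stage downstream assigns it
zero weight instead of the pipeline failing.
"""

from __future__ import annotations

import logging

import numpy as np

from .index_system import COST, IndexSystem, IndicatorMatrix, MatrixError

__all__ = ["minmax_normalize"]

logger = logging.getLogger(__name__)


def minmax_normalize(matrix: IndicatorMatrix, index: IndexSystem) -> IndicatorMatrix:
    """Return the min-max normalized copy of a raw matrix.

    Normalization is per indicator column, min/max taken across plots.
    Direction (benefit/cost) is looked up in the index system.
    """
    if matrix.scale != "raw":
        raise MatrixError("minmax_normalize expects a raw-scale matrix")
    if tuple(matrix.indicator_ids) != index.indicator_ids:
        raise MatrixError("matrix columns do not match the index system")
    directions = index.directions()
    out = np.empty_like(matrix.values)
    for j, ind_id in enumerate(matrix.indicator_ids):
        col = matrix.values[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            logger.warning(
                "indicator %s is constant across plots; normalized to all zeros",
                ind_id,
            )
            out[:, j] = 0.0
            continue
        if directions[ind_id] == COST:
            out[:, j] = (hi - col) / (hi - lo)
        else:
            out[:, j] = (col - lo) / (hi - lo)
    # guard against float round-off leaking outside [0, 1]
    np.clip(out, 0.0, 1.0, out=out)
    return IndicatorMatrix(
        plot_ids=matrix.plot_ids,
        indicator_ids=matrix.indicator_ids,
        values=out,
        scale="normalized",
    )
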