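"""Indicator weighting: entropy weights, AHP priorities, combination.

Weights are built in two layers and multiplied:

* **Entropy weights** (objective) rank indicators *within a
  subsystem* by how much their normalized values vary across plots.
  With ``P_ij = x'_ij / sum_i x'_ij`` the information entropy is
  ``e_j = -(1/ln m) * sum_i P_ij ln P_ij`` (convention 0*ln 0 = 0),
  and ``w_j = (1 - e_j) / sum_j (1 - e_j)`` over the subsystem's
  indicators. A uniform column has e = 1 and gets zero weight.

* **AHP priorities** (subjective) weight the subsystems *within a
  system* from a reciprocal pairwise comparison matrix via its
  principal right eigenvector (power iteration), with Saaty's
  consistency ratio CR = CI / RI as the sanity check (CR <= 0.1 is
  conventionally acceptable).

The combined weight of an indicator is the product
``subsystem_weight * entropy_weight``; because each factor sums to 1
in its own scope, combined weights sum to 1 within each system with
no renormalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .index_system import IndexSystem, IndicatorMatrix

__all__ = [
    "PairwiseComparisonMatrix",
    "WeightSet",
    "ConsistencyError",
    "WeightingError",
    "SAATY_RI",
    "entropy_weights",
    "ahp_priority",
    "ahp_priority_geometric",
    "consistent_pcm",
    "combine_weights",
]

logger = logging.getLogger(__name__)

# Saaty's random consistency index, indexed by matrix order k.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
            6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

_RECIPROCITY_RTOL = 1e-9


class WeightingError(ValueError):
    """Invalid input to a weighting operation."""


class ConsistencyError(WeightingError):
    """Pairwise judgments exceed the allowed consistency ratio."""


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """A k x k positive reciprocal judgment matrix over named items."""

    labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", a)
        k = len(self.labels)
        if k < 1:
            raise WeightingError("pairwise matrix needs at least one item")
        if a.shape != (k, k):
            raise WeightingError(
                f"pairwise matrix shape {a.shape} does not match {k} labels"
            )
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise WeightingError("pairwise entries must be positive and finite")
        if not np.allclose(np.diag(a), 1.0, rtol=_RECIPROCITY_RTOL, atol=0):
            raise WeightingError("pairwise matrix diagonal must be all 1")
        if not np.allclose(a * a.T, 1.0, rtol=3 * _RECIPROCITY_RTOL, atol=0):
            raise WeightingError("pairwise matrix is not reciprocal (a_ji != 1/a_ij)")

    @property
    def order(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class WeightSet:
    """All three weight layers plus their diagnostics.

    ``entropy_weights`` sum to 1 within each subsystem,
    ``subsystem_weights`` within each system, and
    ``combined_weights`` within each system.
    ``consistency`` maps system -> (lambda_max, CI, CR) when the
    subsystem weights came from pairwise judgments.
    """

    entropy_weights: Mapping[str, float]          # indicator id -> w
    subsystem_weights: Mapping[tuple[str, str], float]  # (system, subsystem) -> w
    combined_weights: Mapping[str, float]         # indicator id -> w
    entropies: Mapping[str, float]                # indicator id -> e_j
    consistency: Mapping[str, tuple[float, float, float]]

    def system_weight_vector(self, index: IndexSystem, system: str) -> np.ndarray:
        return np.array(
            [self.combined_weights[i.id] for i in index.indicators_of_system(system)]
        )


# -- entropy layer -------------------------------------------------------


def entropy_weights(
    normalized: IndicatorMatrix, subsystem_columns: Sequence[str]
) -> tuple[dict[str, float], dict[str, float]]:
    """Entropy-based weights for one subsystem's indicator columns.

    Returns ``(entropies, weights)`` keyed by indicator id; weights
    sum to 1 over the subsystem. Requires a normalized matrix with at
    least two plots (entropy is undefined for m = 1 since ln m = 0).
    A column summing to zero provides no information and is assigned
    e = 1, hence weight 0; if *every* column is uninformative the
    subsystem falls back to equal weights with a warning.
    """
    if normalized.scale != "normalized":
        raise WeightingError("entropy_weights expects a normalized matrix")
    m = normalized.n_plots
    if m < 2:
        raise WeightingError(f"entropy weights need at least 2 plots, got {m}")
    missing = [c for c in subsystem_columns if c not in normalized.indicator_ids]
    if missing:
        raise WeightingError(f"columns not in matrix: {missing}")

    entropies: dict[str, float] = {}
    for col_id in subsystem_columns:
        col = normalized.column(col_id)
        total = col.sum()
        if total == 0:
            entropies[col_id] = 1.0
            continue
        p = col / total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        e = -terms.sum() / math.log(m)
        entropies[col_id] = float(min(1.0, max(0.0, e)))

    info = {c: 1.0 - e for c, e in entropies.items()}
    denom = sum(info.values())
    if denom <= 0:
        logger.warning(
            "all columns %s carry zero information (e_j = 1); assigning equal weights",
            list(subsystem_columns),
        )
        w = 1.0 / len(subsystem_columns)
        weights = {c: w for c in subsystem_columns}
    else:
        weights = {c: info[c] / denom for c in subsystem_columns}
    return entropies, weights


# -- AHP layer -----------------------------------------------------------


def _consistency_stats(k: int, lambda_max: float) -> tuple[float, float]:
    if k < 2:
        return 0.0, 0.0
    ci = (lambda_max - k) / (k - 1)
    if k > max(SAATY_RI):
        raise WeightingError(f"no random index tabulated for order {k}")
    ri = SAATY_RI[k]
    cr = 0.0 if ri == 0 else ci / ri
    return ci, cr


def ahp_priority(
    pcm: PairwiseComparisonMatrix,
    cr_max: float = 0.1,
    strict: bool = False,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[dict[str, float], float, float, float]:
    """Principal-eigenvector priorities of a pairwise matrix.

    Power iteration on the positive matrix converges to the Perron
    eigenvector; priorities are normalized to sum 1. Returns
    ``(weights, lambda_max, CI, CR)``. By default a CR above
    ``cr_max`` only logs a warning; ``strict=True`` raises
    :class:`ConsistencyError` instead.
    """
    a = pcm.entries
    k = pcm.order
    if k == 1:
        return {pcm.labels[0]: 1.0}, 1.0, 0.0, 0.0
    w = np.full(k, 1.0 / k)
    lambda_max = float(k)
    for _ in range(max_iter):
        aw = a @ w
        w_next = aw / aw.sum()
        lambda_max = float((a @ w_next).sum() / w_next.sum())
        if np.max(np.abs(w_next - w)) < tol:
            w = w_next
            break
        w = w_next
    ci, cr = _consistency_stats(k, lambda_max)
    if cr > cr_max:
        msg = (
            f"consistency ratio {cr:.4f} exceeds {cr_max} for items "
            f"{list(pcm.labels)}; judgments should be revised"
        )
        if strict:
            raise ConsistencyError(msg)
        logger.warning(msg)
    weights = {label: float(wi) for label, wi in zip(pcm.labels, w)}
    return weights, lambda_max, ci, cr


def ahp_priority_geometric(
    pcm: PairwiseComparisonMatrix,
) -> dict[str, float]:
    """Geometric-mean (log least squares) priorities; a cross-check
    for the eigenvector method, exact on consistent matrices."""
    g = np.exp(np.log(pcm.entries).mean(axis=1))
    g = g / g.sum()
    return {label: float(wi) for label, wi in zip(pcm.labels, g)}


def consistent_pcm(
    labels: Sequence[str], weights: Sequence[float]
) -> PairwiseComparisonMatrix:
    """Build the perfectly consistent matrix ``a_ij = w_i / w_j``."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise WeightingError("weights must be positive")
    return PairwiseComparisonMatrix(
        labels=tuple(labels), entries=np.outer(w, 1.0 / w)
    )


# -- combination ---------------------------------------------------------


def combine_weights(
    subsystem_weights: Mapping[tuple[str, str], float],
    indicator_entropy_weights: Mapping[str, float],
    index: IndexSystem,
    entropies: Mapping[str, float] | None = None,
    consistency: Mapping[str, tuple[float, float, float]] | None = None,
) -> WeightSet:
    """Multiply the two weight layers into per-indicator weights.

    ``combined(j) = subsystem_weight(subsystem of j) * entropy_weight(j)``.
    Because entropy weights sum to 1 per subsystem and subsystem
    weights to 1 per system, combined weights sum to 1 per system by
    construction and no renormalization is applied.
    """
    combined: dict[str, float] = {}
    for ind in index.indicators:
        key = (ind.system, ind.subsystem)
        if key not in subsystem_weights:
            raise WeightingError(
                f"indicator {ind.id!r}: no subsystem weight for {key}"
            )
        if ind.id not in indicator_entropy_weights:
            raise WeightingError(f"indicator {ind.id!r}: no entropy weight")
        combined[ind.id] = (
            subsystem_weights[key] * indicator_entropy_weights[ind.id]
        )
    return WeightSet(
        entropy_weights=dict(indicator_entropy_weights),
        subsystem_weights=dict(subsystem_weights),
        combined_weights=combined,
        entropies=dict(entropies or {}),
        consistency=dict(consistency or {}),
    )
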