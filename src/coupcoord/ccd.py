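"""Coupling coordination degree (CCD) model for two system scores.

Given per-plot comprehensive scores ``V`` (vegetation) and ``S``
(soil) — weighted sums of normalized indicators — the model computes:

* coupling degree ``C = sqrt(V*S / (V+S)^2)``, a symmetric measure of
  interaction intensity, maximal at 0.5 when V = S;
* composite development ``T = alpha*V + beta*S`` (alpha = beta = 0.5
  by default: the two systems are taken as equally important);
* coupling coordination degree ``D = sqrt(C * T)``, blending
  interaction with overall level. With alpha = beta = 0.5 this has
  the closed form ``D = (V*S)**0.25 / sqrt(2)``.

``D`` bands classify plots from low to high coordination, and the lag
ratio ``V/S`` diagnoses which system is the "short plank": <= 0.8
vegetation lagging, 0.8–1.2 synchronous, > 1.2 soil lagging.

A variant without the radical, ``D = C * T``, is available via
``literal=True`` for comparison studies; it compresses the scale and
is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .index_system import IndexSystem, IndicatorMatrix
from .weighting import WeightSet, WeightingError

__all__ = [
    "PlotScores",
    "ClassificationScheme",
    "CCDError",
    "DEFAULT_SCHEME",
    "system_scores",
    "coupling_degree",
    "coordination_degree",
    "lag_ratio",
    "classify",
]


class CCDError(ValueError):
    """Invalid input to a coupling-coordination operation."""


@dataclass(frozen=True)
class ClassificationScheme:
    """Banded classification of D and of the lag ratio V/S.

    Bands are half-open-left ``(lower, upper]`` intervals; they must
    be contiguous, non-overlapping and carry unique labels. A value
    equal to the overall lower bound (e.g. D = 0) falls in the first
    band.
    """

    d_bands: tuple[tuple[float, float, str], ...]
    ratio_bands: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        for name, bands in (("d_bands", self.d_bands), ("ratio_bands", self.ratio_bands)):
            if not bands:
                raise CCDError(f"{name} is empty")
            labels = [b[2] for b in bands]
            if len(set(labels)) != len(labels):
                raise CCDError(f"{name} labels are not unique")
            for (lo, hi, _) in bands:
                if not lo < hi:
                    raise CCDError(f"{name} band ({lo}, {hi}] is empty")
            for (_, hi_prev, _), (lo_next, _, _) in zip(bands, bands[1:]):
                if hi_prev != lo_next:
                    raise CCDError(f"{name} bands are not contiguous")

    @staticmethod
    def _lookup(bands, value: float, what: str) -> str:
        lo0 = bands[0][0]
        if value < lo0 or value > bands[-1][1]:
            raise CCDError(f"{what} = {value} outside classified range")
        if value == lo0:  # degenerate lower edge folded into first band
            return bands[0][2]
        for lo, hi, label in bands:
            if lo < value <= hi:
                return label
        raise CCDError(f"{what} = {value} outside classified range")

    def coordination_class(self, d: float) -> str:
        return self._lookup(self.d_bands, d, "D")

    def lag_class(self, ratio: float) -> str:
        return self._lookup(self.ratio_bands, ratio, "V/S")


#: Standard five-band D scheme and three-band lag scheme.
DEFAULT_SCHEME = ClassificationScheme(
    d_bands=(
        (0.0, 0.2, "low coordination"),
        (0.2, 0.4, "primary coordination"),
        (0.4, 0.6, "intermediate coordination"),
        (0.6, 0.8, "well coordination"),
        (0.8, 1.0, "high coordination"),
    ),
    ratio_bands=(
        (0.0, 0.8, "vegetation lagging behind"),
        (0.8, 1.2, "synchronous development"),
        (1.2, math.inf, "soil lagging behind"),
    ),
)


@dataclass(frozen=True)
class PlotScores:
    """All per-plot outputs of the model, at full precision."""

    plot_id: str
    V: float
    S: float
    C: float
    T: float
    D: float
    ratio: float | None          # None when S = 0 (undefined)
    coordination_class: str
    lag_class: str
    degenerate: bool = False     # V + S = 0: C forced to 0


# -- elementary operations ----------------------------------------------


def system_scores(
    normalized: IndicatorMatrix, weights: WeightSet, index: IndexSystem
) -> dict[str, dict[str, float]]:
    """Per-plot comprehensive score of each system.

    ``score_i(system) = sum_{j in system} w_j * x'_ij`` with the
    combined weights, which sum to 1 per system, so scores lie in
    [0, 1]. Returns ``{system: {plot_id: score}}``.
    """
    if normalized.scale != "normalized":
        raise CCDError("system_scores expects a normalized matrix")
    for ind_id in normalized.indicator_ids:
        if ind_id not in weights.combined_weights:
            raise WeightingError(f"indicator {ind_id!r} has no combined weight")
    out: dict[str, dict[str, float]] = {}
    for system in index.systems:
        ids = [i.id for i in index.indicators_of_system(system)]
        cols = [normalized.indicator_ids.index(i) for i in ids]
        w = np.array([weights.combined_weights[i] for i in ids])
        scores = normalized.values[:, cols] @ w
        out[system] = {
            pid: float(s) for pid, s in zip(normalized.plot_ids, scores)
        }
    return out


def coupling_degree(V: float, S: float) -> float:
    """Coupling degree ``C = sqrt(V*S) / (V + S)``, in [0, 0.5].

    C is maximal (0.5) exactly when the two scores are equal and
    positive; it is 0 when either score is 0. The degenerate case
    V = S = 0 is defined as C = 0.
    """
    if V < 0 or S < 0:
        raise CCDError(f"system scores must be nonnegative, got V={V}, S={S}")
    if V + S == 0:
        return 0.0
    # sqrt(V)*sqrt(S) rather than sqrt(V*S): the product can
    # underflow for very small scores
    return math.sqrt(V) * math.sqrt(S) / (V + S)


def coordination_degree(
    C: float, V: float, S: float,
    alpha: float = 0.5, beta: float = 0.5,
    literal: bool = False,
) -> float:
    """Coordination degree ``D = sqrt(C * (alpha*V + beta*S))``.

    ``alpha`` and ``beta`` are the contribution coefficients of the
    two systems; they must be nonnegative and sum to 1. With
    ``literal=True`` the radical is dropped (``D = C * T``), a variant
    retained for comparison only.
    """
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-9:
        raise CCDError(
            f"contribution coefficients must be nonnegative and sum to 1, "
            f"got alpha={alpha}, beta={beta}"
        )
    t = alpha * V + beta * S
    return C * t if literal else math.sqrt(C * t)


def lag_ratio(V: float, S: float) -> float | None:
    """Lag ratio ``V/S``; ``None`` (undefined) when S = 0."""
    if S == 0:
        return None
    return V / S


def classify(
    D: float,
    ratio: float | None,
    scheme: ClassificationScheme = DEFAULT_SCHEME,
    V: float | None = None,
) -> tuple[str, str]:
    """Map (D, V/S) to (coordination class, lag class).

    An undefined ratio (S = 0) classifies as extreme soil lag when
    V > 0 (pass ``V`` to distinguish), else as degenerate.
    """
    if not 0.0 <= D <= 1.0:
        raise CCDError(f"D = {D} outside [0, 1]")
    coord = scheme.coordination_class(D)
    if ratio is None:
        lag = "degenerate" if (V is None or V == 0) else "soil lagging behind"
    else:
        lag = scheme.lag_class(ratio)
    return coord, lag
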