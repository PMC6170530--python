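"""Synthetic plot x indicator matrices with known ground truth.

Field campaigns behind indicator systems like this one rarely publish
their raw plot tables, so the generator works backwards: ground truth
is specified on the *normalized* scale (values in [0, 1]) and mapped
affinely into user-chosen raw ranges, ``raw = low + x' * (high - low)``
for benefit indicators and the reflection for cost ones. Provided
every target column contains an exact 0 and an exact 1 (anchoring the
column extrema), min-max normalization of the generated raw matrix
reproduces the targets exactly — making any desired downstream result
an executable fixture.

:func:`scenario_from_scores` goes one step further: to realize given
per-plot system scores (V_i, S_i), it sets every vegetation-system
column of plot i to V_i and every soil-system column to S_i (plus two
anchor plots at 0 and 1). Because weights sum to 1 within each
system, the weighted score of a constant row equals that constant for
*any* valid weight set — so printed score tables can be reproduced
end-to-end without the original data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .index_system import COST, IndexSystem, IndicatorMatrix

__all__ = [
    "SyntheticScenario",
    "ScenarioError",
    "ANCHOR_LOW",
    "ANCHOR_HIGH",
    "generate_matrix",
    "scenario_from_scores",
]

ANCHOR_LOW = "__anchor_low__"
ANCHOR_HIGH = "__anchor_high__"

_DEFAULT_RANGE = (0.0, 1.0)


class ScenarioError(ValueError):
    """Invalid synthetic-scenario specification."""


@dataclass(frozen=True)
class SyntheticScenario:
    """Specification of one synthetic matrix.

    Either ``target_normalized`` pins the normalized values exactly
    (each column must attain 0 and 1 so the affine inversion
    round-trips), or targets are absent and raw values are drawn
    uniformly within ``column_ranges`` with optional Gaussian jitter
    of standard deviation ``noise_sd`` (raw scale), seeded by
    ``seed``.
    """

    index: IndexSystem
    n_plots: int
    plot_ids: tuple[str, ...] = ()
    column_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    target_normalized: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 2:
            raise ScenarioError("scenario needs at least 2 plots")
        plot_ids = self.plot_ids or tuple(
            f"P{i + 1}" for i in range(self.n_plots)
        )
        if len(plot_ids) != self.n_plots or len(set(plot_ids)) != self.n_plots:
            raise ScenarioError("plot_ids must be unique and match n_plots")
        object.__setattr__(self, "plot_ids", tuple(plot_ids))
        for ind_id, (lo, hi) in self.column_ranges.items():
            if ind_id not in self.index.indicator_ids:
                raise ScenarioError(f"range given for unknown indicator {ind_id!r}")
            if not lo < hi:
                raise ScenarioError(
                    f"indicator {ind_id!r}: range ({lo}, {hi}) needs low < high"
                )
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be nonnegative")
        if self.target_normalized is not None:
            t = np.asarray(self.target_normalized, dtype=float)
            n = len(self.index.indicator_ids)
            if t.shape != (self.n_plots, n):
                raise ScenarioError(
                    f"target_normalized shape {t.shape} != ({self.n_plots}, {n})"
                )
            if t.min() < 0 or t.max() > 1:
                raise ScenarioError("targets must lie in [0, 1]")
            for j, ind_id in enumerate(self.index.indicator_ids):
                col = t[:, j]
                if col.min() != 0.0 or col.max() != 1.0:
                    raise ScenarioError(
                        f"target column {ind_id!r} must attain an exact 0 and 1 "
                        "so min-max inversion round-trips"
                    )
            object.__setattr__(self, "target_normalized", t)

    def range_of(self, ind_id: str) -> tuple[float, float]:
        return self.column_ranges.get(ind_id, _DEFAULT_RANGE)


def generate_matrix(scenario: SyntheticScenario) -> IndicatorMatrix:
    """Materialize the scenario as a raw-scale matrix.

    With targets: a deterministic affine inversion of min-max
    normalization. Without: seeded uniform draws within each column's
    range plus Gaussian jitter (clipped back into range so the stated
    bounds stay honest).
    """
    index = scenario.index
    n = len(index.indicator_ids)
    raw = np.empty((scenario.n_plots, n))
    directions = index.directions()
    if scenario.target_normalized is not None:
        for j, ind_id in enumerate(index.indicator_ids):
            lo, hi = scenario.range_of(ind_id)
            x = scenario.target_normalized[:, j]
            if directions[ind_id] == COST:
                raw[:, j] = hi - x * (hi - lo)
            else:
                raw[:, j] = lo + x * (hi - lo)
    else:
        rng = np.random.default_rng(scenario.seed)
        for j, ind_id in enumerate(index.indicator_ids):
            lo, hi = scenario.range_of(ind_id)
            col = rng.uniform(lo, hi, size=scenario.n_plots)
            if scenario.noise_sd > 0:
                col = col + rng.normal(0.0, scenario.noise_sd, size=scenario.n_plots)
            raw[:, j] = np.clip(col, lo, hi)
    return IndicatorMatrix(
        plot_ids=scenario.plot_ids,
        indicator_ids=index.indicator_ids,
        values=raw,
        scale="raw",
    )


def scenario_from_scores(
    V_targets: Mapping[str, float] | Sequence[float],
    S_targets: Mapping[str, float] | Sequence[float],
    index: IndexSystem,
    column_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> SyntheticScenario:
    """Build a scenario whose pipeline scores equal the given (V, S).

    ``V_targets``/``S_targets`` map plot id -> desired score in [0, 1]
    (or are equal-length sequences, auto-labelled). The first and
    second system of ``index`` receive the V and S values
    respectively. Two anchor plots, all-0 and all-1, are appended
    whenever some column would otherwise miss an extreme; they pin
    the min-max range and should be dropped from downstream readings.
    """
    if len(index.systems) != 2:
        raise ScenarioError("scenario_from_scores needs exactly 2 systems")
    if not isinstance(V_targets, Mapping):
        V_targets = {f"P{i + 1}": v for i, v in enumerate(V_targets)}
    if not isinstance(S_targets, Mapping):
        S_targets = {pid: s for pid, s in zip(V_targets, S_targets)}
    if set(V_targets) != set(S_targets):
        raise ScenarioError("V and S targets must cover the same plots")
    plot_ids = list(V_targets)
    vals = list(V_targets.values()) + list(S_targets.values())
    if any(not 0 <= x <= 1 for x in vals):
        raise ScenarioError("score targets must lie in [0, 1]")

    sys_v, sys_s = index.systems
    n = len(index.indicator_ids)
    rows = []
    for pid in plot_ids:
        row = [
            V_targets[pid] if ind.system == sys_v else S_targets[pid]
            for ind in index.indicators
        ]
        rows.append(row)
    t = np.array(rows, dtype=float)
    # anchor plots guarantee every column attains 0 and 1 exactly
    need_low = not np.all(t.min(axis=0) == 0.0)
    need_high = not np.all(t.max(axis=0) == 1.0)
    if need_low:
        t = np.vstack([t, np.zeros(n)])
        plot_ids.append(ANCHOR_LOW)
    if need_high:
        t = np.vstack([t, np.ones(n)])
        plot_ids.append(ANCHOR_HIGH)
    return SyntheticScenario(
        index=index,
        n_plots=len(plot_ids),
        plot_ids=tuple(plot_ids),
        column_ranges=dict(column_ranges or {}),
        target_normalized=t,
    )
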