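"""Hierarchical indicator systems and plot x indicator matrices.

An evaluation here is parameterized by a two-level hierarchy:
*systems* (e.g. vegetation, soil) are split into *subsystems*
(e.g. tree / herb / litter), each holding one or more measured
*indicators*. Every downstream stage — normalization, entropy
weighting, score aggregation — takes its column layout from the
:class:`IndexSystem`, never from file order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IndicatorSpec",
    "IndexSystem",
    "IndicatorMatrix",
    "IndexSystemError",
    "MatrixError",
    "load_index_system",
    "dump_index_system",
    "read_matrix",
    "write_matrix",
]

BENEFIT = "benefit"
COST = "cost"


class IndexSystemError(ValueError):
    """Raised when an index-system definition violates its invariants."""


class MatrixError(ValueError):
    """Raised when a plot x indicator table violates its contract."""


@dataclass(frozen=True)
class IndicatorSpec:
    """One measured indicator and its place in the hierarchy.

    Parameters
    ----------
    id :
        Short unique token, e.g. ``"X1"``.
    name :
        Human-readable name, e.g. ``"canopy density"``.
    system :
        Name of the top-level system this indicator scores.
    subsystem :
        Name of the subsystem within ``system``.
    direction :
        ``"benefit"`` if larger raw values are better, ``"cost"``
        otherwise; controls the min-max normalization orientation.
    units :
        Free-text measurement units (may be empty).
    """

    id: str
    name: str
    system: str
    subsystem: str
    direction: str = BENEFIT
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (BENEFIT, COST):
            raise IndexSystemError(
                f"indicator {self.id!r}: direction must be "
                f"'benefit' or 'cost', got {self.direction!r}"
            )


@dataclass(frozen=True)
class IndexSystem:
    """A validated two-level indicator hierarchy.

    ``indicators`` order is authoritative: it fixes column order for
    every matrix, weight vector and report downstream.
    """

    systems: tuple[str, ...]
    subsystems: Mapping[str, tuple[str, ...]]  # system -> subsystem names
    indicators: tuple[IndicatorSpec, ...]

    def __post_init__(self) -> None:
        if not self.systems:
            raise IndexSystemError("index system declares no systems")
        if len(set(self.systems)) != len(self.systems):
            raise IndexSystemError("duplicate system names")
        for sys_name in self.systems:
            subs = self.subsystems.get(sys_name, ())
            if not subs:
                raise IndexSystemError(f"system {sys_name!r} has no subsystems")
            if len(set(subs)) != len(subs):
                raise IndexSystemError(f"duplicate subsystems in system {sys_name!r}")
        seen: set[str] = set()
        for ind in self.indicators:
            if ind.id in seen:
                raise IndexSystemError(f"duplicate indicator id {ind.id!r}")
            seen.add(ind.id)
            if ind.system not in self.systems:
                raise IndexSystemError(
                    f"indicator {ind.id!r} references undeclared system {ind.system!r}"
                )
            if ind.subsystem not in self.subsystems[ind.system]:
                raise IndexSystemError(
                    f"indicator {ind.id!r} references subsystem "
                    f"{ind.subsystem!r} not declared under system {ind.system!r}"
                )
        for sys_name in self.systems:
            for sub in self.subsystems[sys_name]:
                if not any(
                    i.system == sys_name and i.subsystem == sub
                    for i in self.indicators
                ):
                    raise IndexSystemError(
                        f"subsystem {sub!r} of system {sys_name!r} has no indicators"
                    )

    # -- lookups ---------------------------------------------------------

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(i.id for i in self.indicators)

    def indicator(self, indicator_id: str) -> IndicatorSpec:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def indicators_of_system(self, system: str) -> tuple[IndicatorSpec, ...]:
        return tuple(i for i in self.indicators if i.system == system)

    def indicators_of_subsystem(
        self, system: str, subsystem: str
    ) -> tuple[IndicatorSpec, ...]:
        return tuple(
            i
            for i in self.indicators
            if i.system == system and i.subsystem == subsystem
        )

    def directions(self) -> dict[str, str]:
        return {i.id: i.direction for i in self.indicators}


@dataclass(frozen=True)
class IndicatorMatrix:
    """A plot x indicator value table tied to an :class:`IndexSystem`.

    ``scale`` distinguishes raw field measurements from min-max
    normalized values; normalized matrices must lie in [0, 1].
    """

    plot_ids: tuple[str, ...]
    indicator_ids: tuple[str, ...]
    values: np.ndarray  # shape (m plots, n indicators), float64
    scale: str = "raw"  # "raw" | "normalized"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        m, n = len(self.plot_ids), len(self.indicator_ids)
        if values.shape != (m, n):
            raise MatrixError(
                f"values shape {values.shape} does not match "
                f"{m} plots x {n} indicators"
            )
        if len(set(self.plot_ids)) != m:
            raise MatrixError("duplicate plot labels")
        if len(set(self.indicator_ids)) != n:
            raise MatrixError("duplicate indicator ids")
        if not np.all(np.isfinite(values)):
            raise MatrixError("matrix contains non-finite or missing entries")
        if self.scale not in ("raw", "normalized"):
            raise MatrixError(f"unknown scale {self.scale!r}")
        if self.scale == "normalized" and (
            values.min(initial=0.0) < -1e-12 or values.max(initial=0.0) > 1 + 1e-12
        ):
            raise MatrixError("normalized matrix has entries outside [0, 1]")

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def column(self, indicator_id: str) -> np.ndarray:
        j = self.indicator_ids.index(indicator_id)
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.plot_ids), columns=list(self.indicator_ids)
        )


# -- config I/O ----------------------------------------------------------


def load_index_system(config_source) -> IndexSystem:
    """Load and validate an index system from YAML/JSON.

    ``config_source`` may be a path, an open text stream, or an
    already-parsed mapping with keys ``systems``, ``subsystems`` and
    ``indicators`` (each indicator: ``id, name, system, subsystem,
    direction, units``; ``direction`` defaults to benefit).
    """
    if isinstance(config_source, Mapping):
        cfg = config_source
    elif isinstance(config_source, io.TextIOBase):
        cfg = yaml.safe_load(config_source)
    else:
        cfg = yaml.safe_load(Path(config_source).read_text())
    if not isinstance(cfg, Mapping):
        raise IndexSystemError("index-system config must be a mapping")
    for key in ("systems", "subsystems", "indicators"):
        if key not in cfg:
            raise IndexSystemError(f"index-system config missing key {key!r}")
    indicators = tuple(
        IndicatorSpec(
            id=str(item["id"]),
            name=str(item.get("name", item["id"])),
            system=str(item["system"]),
            subsystem=str(item["subsystem"]),
            direction=str(item.get("direction", BENEFIT)),
            units=str(item.get("units", "")),
        )
        for item in cfg["indicators"]
    )
    return IndexSystem(
        systems=tuple(str(s) for s in cfg["systems"]),
        subsystems={
            str(k): tuple(str(s) for s in v) for k, v in cfg["subsystems"].items()
        },
        indicators=indicators,
    )


def dump_index_system(index: IndexSystem, path) -> None:
    """Write an index system back to YAML (round-trips with load)."""
    doc = {
        "systems": list(index.systems),
        "subsystems": {k: list(v) for k, v in index.subsystems.items()},
        "indicators": [
            {
                "id": i.id,
                "name": i.name,
                "system": i.system,
                "subsystem": i.subsystem,
                "direction": i.direction,
                "units": i.units,
            }
            for i in index.indicators
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_matrix(table_source, index: IndexSystem, sep: str | None = None) -> IndicatorMatrix:
    """Read a raw plot x indicator CSV/TSV against an index system.

    The first column holds plot labels; remaining columns are matched
    to indicator ids by name, so file column order is irrelevant —
    output column order always follows the index system.
    """
    if sep is None:
        sep = "\t" if str(table_source).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(table_source, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise MatrixError(f"duplicate plot labels: {dupes}")
    missing = [i for i in index.indicator_ids if i not in df.columns]
    if missing:
        raise MatrixError(f"table is missing indicator columns: {missing}")
    df = df[list(index.indicator_ids)]
    if df.isna().any().any():
        bad = sorted(df.columns[df.isna().any()])
        raise MatrixError(f"missing values in columns: {bad}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MatrixError(f"non-numeric cell in table: {exc}") from exc
    return IndicatorMatrix(
        plot_ids=tuple(df.index),
        indicator_ids=index.indicator_ids,
        values=values,
        scale="raw",
    )


def write_matrix(matrix: IndicatorMatrix, path, sep: str = ",") -> None:
    """Write a matrix as delimited text (round-trips with read_matrix)."""
    df = matrix.to_frame()
    df.index.name = "plot"
    df.to_csv(path, sep=sep)
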