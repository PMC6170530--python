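"""End-to-end pipeline: raw matrix -> weights -> scores -> CCD report.

The stages compose deterministically:

1. min-max normalize the raw matrix (direction-aware);
2. entropy weights per subsystem;
3. AHP (or direct) subsystem weights per system, with consistency check;
4. multiply the layers into per-indicator combined weights;
5. per-plot system scores V and S;
6. coupling degree C, composite T, coordination degree D, lag ratio;
7. band classification of D and V/S.

Every intermediate is kept on the report so each stage is inspectable.
Class labels are assigned from values rounded to the report precision
(2 decimals for D and V/S by default), matching how banded tables are
read in practice; set ``classification_precision=None`` to band the
full-precision values instead.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .ccd import (
    DEFAULT_SCHEME,
    CCDError,
    ClassificationScheme,
    PlotScores,
    classify,
    coordination_degree,
    coupling_degree,
    lag_ratio,
    system_scores,
)
from .index_system import IndexSystem, IndicatorMatrix
from .preprocessing import minmax_normalize
from .weighting import (
    PairwiseComparisonMatrix,
    WeightSet,
    WeightingError,
    ahp_priority,
    combine_weights,
    entropy_weights,
)

__all__ = [
    "PipelineError",
    "PipelineOptions",
    "PipelineReport",
    "load_ahp_config",
    "subsystem_weights_from_config",
    "load_classification_scheme",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineOptions:
    """Tunable pipeline behaviour.

    alpha, beta :
        Contribution coefficients of the first and second system in
        the composite term T; equal weighting (0.5/0.5) by default.
    cr_max, cr_strict :
        Consistency-ratio threshold for AHP judgments and whether
        exceeding it is an error (default: warn only).
    literal_d :
        Use the radical-free variant D = C*T instead of sqrt(C*T).
    classification_precision :
        Decimals D and V/S are rounded to before band lookup
        (None = classify at full precision).
    """

    alpha: float = 0.5
    beta: float = 0.5
    cr_max: float = 0.1
    cr_strict: bool = False
    literal_d: bool = False
    classification_precision: int | None = 2
    scheme: ClassificationScheme = DEFAULT_SCHEME


# -- AHP / scheme configuration ------------------------------------------


def load_ahp_config(config_source) -> dict[str, Any]:
    """Parse the per-system subsystem-weighting config.

    YAML/JSON mapping ``system -> {pairwise: [[...]], order: [...]}``
    or ``system -> {direct_weights: {subsystem: w}}``.
    """
    if isinstance(config_source, Mapping):
        cfg = config_source
    elif isinstance(config_source, io.TextIOBase):
        cfg = yaml.safe_load(config_source)
    else:
        cfg = yaml.safe_load(Path(config_source).read_text())
    if not isinstance(cfg, Mapping):
        raise WeightingError("AHP config must map system -> specification")
    return dict(cfg)


def subsystem_weights_from_config(
    cfg: Mapping[str, Any],
    index: IndexSystem,
    cr_max: float = 0.1,
    strict: bool = False,
) -> tuple[dict[tuple[str, str], float], dict[str, tuple[float, float, float]]]:
    """Resolve subsystem weights per system from pairwise or direct form.

    Direct weights are normalized to sum 1 within the system; pairwise
    matrices go through the AHP eigenvector with consistency checking.
    Returns ``(weights, consistency)`` where consistency holds
    (lambda_max, CI, CR) for pairwise-specified systems.
    """
    weights: dict[tuple[str, str], float] = {}
    consistency: dict[str, tuple[float, float, float]] = {}
    for system in index.systems:
        subs = index.subsystems[system]
        spec = cfg.get(system)
        if spec is None:
            raise WeightingError(f"AHP config missing system {system!r}")
        if "direct_weights" in spec:
            dw = spec["direct_weights"]
            missing = [s for s in subs if s not in dw]
            if missing:
                raise WeightingError(
                    f"system {system!r}: direct_weights missing {missing}"
                )
            vec = np.array([float(dw[s]) for s in subs])
            if np.any(vec < 0) or vec.sum() <= 0:
                raise WeightingError(
                    f"system {system!r}: direct weights must be nonnegative "
                    "with positive sum"
                )
            vec = vec / vec.sum()
            for s, w in zip(subs, vec):
                weights[(system, s)] = float(w)
        elif "pairwise" in spec:
            order = tuple(spec.get("order", subs))
            if set(order) != set(subs):
                raise WeightingError(
                    f"system {system!r}: pairwise order {order} does not "
                    f"cover subsystems {subs}"
                )
            pcm = PairwiseComparisonMatrix(
                labels=order, entries=np.array(spec["pairwise"], dtype=float)
            )
            w, lam, ci, cr = ahp_priority(pcm, cr_max=cr_max, strict=strict)
            consistency[system] = (lam, ci, cr)
            for s in subs:
                weights[(system, s)] = w[s]
        else:
            raise WeightingError(
                f"system {system!r}: config needs 'pairwise' or 'direct_weights'"
            )
    return weights, consistency


def load_classification_scheme(config_source) -> ClassificationScheme:
    """Load band definitions from YAML: keys ``d_bands`` / ``ratio_bands``,
    each a list of ``[lower, upper, label]`` (upper ``.inf`` allowed)."""
    if isinstance(config_source, Mapping):
        cfg = config_source
    else:
        cfg = yaml.safe_load(Path(config_source).read_text())

    def _bands(rows):
        return tuple((float(lo), float(hi), str(label)) for lo, hi, label in rows)

    return ClassificationScheme(
        d_bands=_bands(cfg["d_bands"]), ratio_bands=_bands(cfg["ratio_bands"])
    )


# -- report --------------------------------------------------------------


def _round_opt(x: float | None, ndigits: int | None) -> float | None:
    if x is None or ndigits is None:
        return x
    return round(x, ndigits)


@dataclass(frozen=True)
class PipelineReport:
    """All intermediates of one pipeline run.

    ``plots`` holds full-precision :class:`PlotScores`; the summary
    table applies presentation rounding (C to 4 decimals, the rest to
    2) without touching the stored values.
    """

    index: IndexSystem
    raw: IndicatorMatrix
    normalized: IndicatorMatrix
    weights: WeightSet
    system_pair: tuple[str, str]
    plots: tuple[PlotScores, ...]
    options: PipelineOptions

    def summary_frame(self) -> pd.DataFrame:
        sys_v, sys_s = self.system_pair
        rows = []
        for p in self.plots:
            rows.append(
                {
                    "plot": p.plot_id,
                    f"{sys_v}_score": round(p.V, 2),
                    f"{sys_s}_score": round(p.S, 2),
                    "ratio": None if p.ratio is None else round(p.ratio, 2),
                    "C": round(p.C, 4),
                    "D": round(p.D, 2),
                    "coordination_class": p.coordination_class,
                    "lag_class": p.lag_class,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict[str, Any]:
        sys_v, sys_s = self.system_pair
        return {
            "systems": list(self.system_pair),
            "options": {
                "alpha": self.options.alpha,
                "beta": self.options.beta,
                "cr_max": self.options.cr_max,
                "literal_d": self.options.literal_d,
                "classification_precision": self.options.classification_precision,
            },
            "normalized": {
                pid: dict(zip(self.normalized.indicator_ids, map(float, row)))
                for pid, row in zip(self.normalized.plot_ids, self.normalized.values)
            },
            "entropies": {k: float(v) for k, v in self.weights.entropies.items()},
            "entropy_weights": {
                k: float(v) for k, v in self.weights.entropy_weights.items()
            },
            "subsystem_weights": {
                f"{sys}/{sub}": float(w)
                for (sys, sub), w in self.weights.subsystem_weights.items()
            },
            "combined_weights": {
                k: float(v) for k, v in self.weights.combined_weights.items()
            },
            "consistency": {
                sys: {"lambda_max": lam, "CI": ci, "CR": cr}
                for sys, (lam, ci, cr) in self.weights.consistency.items()
            },
            "plots": [
                {
                    "plot": p.plot_id,
                    sys_v: p.V,
                    sys_s: p.S,
                    "C": p.C,
                    "T": p.T,
                    "D": p.D,
                    "ratio": p.ratio,
                    "coordination_class": p.coordination_class,
                    "lag_class": p.lag_class,
                    "degenerate": p.degenerate,
                }
                for p in self.plots
            ],
        }

    def write(self, out_dir, stem: str = "report") -> dict[str, Path]:
        """Write the JSON report (full precision) and CSV summary.

        Output bytes are a pure function of inputs and options, so
        repeated runs are byte-identical.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        json_path = out / f"{stem}.json"
        csv_path = out / f"{stem}_summary.csv"
        json_path.write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        self.summary_frame().to_csv(csv_path, index=False)
        return {"json": json_path, "csv": csv_path}


# -- pipeline ------------------------------------------------------------


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(
    raw: IndicatorMatrix,
    index: IndexSystem,
    ahp_config: Mapping[str, Any],
    options: PipelineOptions | None = None,
) -> PipelineReport:
    """Run the full evaluation on a raw matrix.

    The coupling step pairs the index system's first two systems (the
    engine requires exactly two for C and D). Errors from any stage
    are re-raised as :class:`PipelineError` tagged with the stage.
    """
    opts = options or PipelineOptions()
    if len(index.systems) != 2:
        raise PipelineError(
            "setup", f"coupling needs exactly 2 systems, got {list(index.systems)}"
        )
    sys_v, sys_s = index.systems

    with _stage("normalize"):
        normalized = minmax_normalize(raw, index)

    with _stage("entropy"):
        all_entropies: dict[str, float] = {}
        all_entropy_w: dict[str, float] = {}
        for system in index.systems:
            for sub in index.subsystems[system]:
                cols = [i.id for i in index.indicators_of_subsystem(system, sub)]
                e, w = entropy_weights(normalized, cols)
                all_entropies.update(e)
                all_entropy_w.update(w)

    with _stage("ahp"):
        sub_w, consistency = subsystem_weights_from_config(
            ahp_config, index, cr_max=opts.cr_max, strict=opts.cr_strict
        )

    with _stage("combine"):
        weights = combine_weights(
            sub_w, all_entropy_w, index,
            entropies=all_entropies, consistency=consistency,
        )

    with _stage("scores"):
        scores = system_scores(normalized, weights, index)

    with _stage("ccd"):
        prec = opts.classification_precision
        plots: list[PlotScores] = []
        for pid in raw.plot_ids:
            v, s = scores[sys_v][pid], scores[sys_s][pid]
            c = coupling_degree(v, s)
            t = opts.alpha * v + opts.beta * s
            d = coordination_degree(
                c, v, s, alpha=opts.alpha, beta=opts.beta, literal=opts.literal_d
            )
            ratio = lag_ratio(v, s)
            coord_cls, lag_cls = classify(
                _round_opt(d, prec), _round_opt(ratio, prec),
                scheme=opts.scheme, V=v,
            )
            plots.append(
                PlotScores(
                    plot_id=pid, V=v, S=s, C=c, T=t, D=d, ratio=ratio,
                    coordination_class=coord_cls, lag_class=lag_cls,
                    degenerate=(v + s == 0),
                )
            )

    return PipelineReport(
        index=index, raw=raw, normalized=normalized, weights=weights,
        system_pair=(sys_v, sys_s), plots=tuple(plots), options=opts,
    )
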