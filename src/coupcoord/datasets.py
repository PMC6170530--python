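"""Shipped fixtures: the Pingshuo reclaimed-mine evaluation study.

The study scored five plots on a Loess Plateau opencast coal-mine
dump — four reclamation patterns plus one undisturbed original
landform — against an 18-indicator soil/vegetation hierarchy:

====  =================================================
RUA   R. pseudoacacia - U. pumila - A. altissima mixture
RP    R. pseudoacacia - Pi. tabuliformis mixture
RM    R. pseudoacacia monoculture
PM    Pi. tabuliformis monoculture
OP    original Prunus simonii monoculture (reference)
====  =================================================

The raw field table was never published, but the study's printed
per-plot system scores, combined indicator weights and coupling
results are reproduced here so the full pipeline can be exercised
against them via :mod:`coupcoord.synthetic`.
"""

from __future__ import annotations

from importlib import resources

from .index_system import IndexSystem, load_index_system
from .pipeline import load_ahp_config

__all__ = [
    "pingshuo_index",
    "pingshuo_ahp_config",
    "PINGSHUO_SYSTEM_SCORES",
    "PINGSHUO_REPORTED",
    "PINGSHUO_COMBINED_WEIGHTS",
]


def _data_path(name: str):
    return resources.files("coupcoord.data").joinpath(name)


def pingshuo_index() -> IndexSystem:
    """The 2-system / 5-subsystem / 18-indicator hierarchy."""
    with resources.as_file(_data_path("pingshuo_index.yaml")) as p:
        return load_index_system(p)


def pingshuo_ahp_config() -> dict:
    """Direct subsystem weights (judgment matrices were unpublished)."""
    with resources.as_file(_data_path("pingshuo_ahp.yaml")) as p:
        return load_ahp_config(p)


#: Published per-plot comprehensive scores (V = vegetation, S = soil).
PINGSHUO_SYSTEM_SCORES: dict[str, tuple[float, float]] = {
    "RUA": (0.32, 0.25),
    "RP": (0.57, 0.74),
    "RM": (0.16, 0.35),
    "PM": (0.41, 0.46),
    "OP": (0.50, 0.21),
}

#: Published coupling results per plot:
#: (C, D, V/S ratio, coordination class, lag class).
PINGSHUO_REPORTED: dict[str, tuple[float, float, float, str, str]] = {
    "RUA": (0.4966, 0.38, 1.26, "primary coordination", "soil lagging behind"),
    "RP": (0.4958, 0.57, 0.77, "intermediate coordination", "vegetation lagging behind"),
    "RM": (0.4632, 0.34, 0.45, "primary coordination", "vegetation lagging behind"),
    "PM": (0.4992, 0.46, 0.89, "intermediate coordination", "synchronous development"),
    "OP": (0.4577, 0.40, 2.35, "primary coordination", "soil lagging behind"),
}

#: Published combined (AHP x entropy) weight of each indicator; sums
#: to 1 within each system (X1-X9 vegetation, X10-X18 soil).
PINGSHUO_COMBINED_WEIGHTS: dict[str, float] = {
    "X1": 0.1064, "X2": 0.1451, "X3": 0.1460, "X4": 0.1501, "X5": 0.1263,
    "X6": 0.0837, "X7": 0.0586, "X8": 0.0832,
    "X9": 0.1007,
    "X10": 0.0763, "X11": 0.1237,
    "X12": 0.1548, "X13": 0.2272, "X14": 0.1141, "X15": 0.0427,
    "X16": 0.0688, "X17": 0.0833, "X18": 0.1092,
}
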