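"""Category-keyed parameter schedules.

Four control parameters adapt to the benchmark-function category, with
harder overrides for high-deception landscapes: the base cyclone
probability, the base somersault factor ``S0``, the local-search trigger
period ``F_local`` and the stagnation window ``T_restart``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["CategorySchedule", "schedule_for", "CATEGORIES"]

CATEGORIES = ("unimodal", "multimodal", "hybrid", "composition")

# (P_cyclone_base, S0, F_local, T_restart) per category; deceptive override second.
_TABLE = {
    "unimodal": ((0.85, 1.2, 3, 20), (0.85, 1.2, 3, 20)),
    "multimodal": ((0.65, 2.0, 6, 15), (0.45, 3.0, 3, 8)),
    "hybrid": ((0.55, 2.2, 7, 12), (0.35, 2.8, 3, 10)),
    "composition": ((0.45, 2.5, 8, 10), (0.35, 3.5, 3, 6)),
}


@dataclass(frozen=True)
class CategorySchedule:
    category: str
    deceptive: bool
    p_cyclone_base: float
    s0: float
    f_local: int
    t_restart: int


def schedule_for(category: str, deceptive: bool = False) -> CategorySchedule:
    """Look up the adaptive parameter set for a (category, deceptive) pair.

    Unknown categories fall back to the multimodal schedule with a warning.
    """
    if category not in _TABLE:
        warnings.warn(f"unknown function category {category!r}; using multimodal defaults")
        category = "multimodal"
    row = _TABLE[category][1 if deceptive else 0]
    return CategorySchedule(category, deceptive, *row)
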