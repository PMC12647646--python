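"""Sensitivity-grid and component-ablation harnesses.

The sensitivity grid crosses chaotic map x base crossover rate x
initialization mode and reports mean and SD of the final fitness per cell
plus an improvement-vs-baseline percentage ``(baseline - cell) / baseline
* 100``.  The ablation harness runs named component presets ("Full",
"Adaptive Only", "No Lévy", ...) built from the optimizer's toggles and
ranks them the same way.  No claim is made about absolute fitness values
on any particular problem — the harness reproduces the table mechanics
and qualitative orderings.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .core import OptimizerConfig, Toggles, optimize
from .initialization import Bounds
from .kernels import MapKind

__all__ = ["ABLATION_PRESETS", "preset_toggles", "run_sensitivity_grid", "run_ablation", "improvement_pct"]

_COMPONENTS = ("chaos", "levy", "memory", "elite_guidance", "adaptive_params", "restart", "local_search")

_NAME_OF = {
    "chaos": "Chaos",
    "levy": "Lévy",
    "memory": "Memory",
    "elite_guidance": "Elite",
    "adaptive_params": "Adaptive",
    "restart": "Restart",
    "local_search": "Local Search",
}
_KEY_OF = {v: k for k, v in _NAME_OF.items()}

ABLATION_PRESETS = (
    ["Full"]
    + [f"{_NAME_OF[c]} Only" for c in _COMPONENTS]
    + [f"No {_NAME_OF[c]}" for c in _COMPONENTS]
    + ["Adaptive+Restart", "Chaos+Lévy", "Baseline"]
)


def preset_toggles(name: str) -> Toggles:
    """Build the toggle set for a named ablation preset.

    ``Full`` turns every component on, ``<X> Only`` exactly one,
    ``No <X>`` all but one, ``A+B`` exactly those two, and ``Baseline``
    none.
    """
    if name == "Full":
        return Toggles()
    if name == "Baseline":
        return Toggles(**{c: False for c in _COMPONENTS})
    if name.startswith("No "):
        return Toggles(**{_KEY_OF[name[3:]]: False})
    if name.endswith(" Only"):
        on = _KEY_OF[name[:-5]]
        return Toggles(**{c: (c == on) for c in _COMPONENTS})
    if "+" in name:
        keys = [_KEY_OF[part] for part in name.split("+")]
        return Toggles(**{c: (c in keys) for c in _COMPONENTS})
    raise ValueError(f"unknown ablation preset {name!r}")


def improvement_pct(baseline: float, value: float) -> float:
    """Percentage improvement of ``value`` over ``baseline`` (lower is better)."""
    return (baseline - value) / baseline * 100.0


def _mean_sd(f, bounds: Bounds, cfg: OptimizerConfig, runs: int, seed: int) -> tuple[float, float]:
    finals = [
        optimize(f, bounds, cfg, seed=seed + i, batch=getattr(f, "supports_batch", False)).final_error
        for i in range(runs)
    ]
    return float(np.mean(finals)), float(np.std(finals, ddof=1)) if runs > 1 else 0.0


def run_sensitivity_grid(
    f,
    bounds: Bounds,
    maps: tuple[str, ...] = ("circle", "logistic", "tent"),
    cr0_values: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    init_modes: tuple[str, ...] = ("random", "chaotic"),
    runs: int = 5,
    seed: int = 0,
    config: OptimizerConfig | None = None,
    baseline_cell: tuple[str, float, str] = ("logistic", 0.1, "random"),
) -> pd.DataFrame:
    """Mean +/- SD final error per (map, CR0, init) cell, with improvement
    relative to the designated baseline cell."""
    base_cfg = OptimizerConfig() if config is None else config
    rows = []
    for m in maps:
        for cr0 in cr0_values:
            for init in init_modes:
                cfg = replace(
                    base_cfg, map_kind=MapKind(m), cr0=cr0, chaotic_init=(init == "chaotic")
                )
                mu, sd = _mean_sd(f, bounds, cfg, runs, seed)
                rows.append(
                    {"map": m, "cr0": cr0, "init": init, "mean": mu, "sd": sd, "n": runs}
                )
    df = pd.DataFrame(rows)
    sel = df[
        (df["map"] == baseline_cell[0])
        & (df["cr0"] == baseline_cell[1])
        & (df["init"] == baseline_cell[2])
    ]
    baseline = float(sel["mean"].iloc[0]) if len(sel) else float(df["mean"].iloc[0])
    df["improvement_pct"] = [improvement_pct(baseline, v) if baseline != 0 else 0.0 for v in df["mean"]]
    return df


def run_ablation(
    f,
    bounds: Bounds,
    presets: tuple[str, ...] = tuple(ABLATION_PRESETS),
    runs: int = 5,
    seed: int = 0,
    config: OptimizerConfig | None = None,
) -> pd.DataFrame:
    """Mean/SD final error per component preset, ranked best-first, with
    improvement relative to the ``Baseline`` (all components off) preset."""
    base_cfg = OptimizerConfig() if config is None else config
    rows = []
    for name in presets:
        cfg = replace(base_cfg, toggles=preset_toggles(name))
        mu, sd = _mean_sd(f, bounds, cfg, runs, seed)
        rows.append({"preset": name, "mean": mu, "sd": sd, "n": runs})
    df = pd.DataFrame(rows).sort_values("mean").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    base_row = df[df["preset"] == "Baseline"]
    baseline = float(base_row["mean"].iloc[0]) if len(base_row) else float(df["mean"].max())
    df["improvement_pct"] = [
        improvement_pct(baseline, v) if baseline != 0 else 0.0 for v in df["mean"]
    ]
    return df
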