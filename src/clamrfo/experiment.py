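"""Benchmark experiment runner: functions x algorithms x runs.

Runs every algorithm on every suite function over a common seed list,
persists per-run records, and summarises mean error, standard deviation,
success rate (error <= 1e-2) and mean convergence iteration per cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .benchmarks import BenchmarkFunction, mrfo_baseline_optimize, success_rate
from .core import OptimizerConfig, RunRecord, optimize

__all__ = ["ExperimentResult", "run_experiment", "ALGORITHMS"]

#: registered algorithms; peers are pluggable via the same signature
ALGORITHMS: dict[str, Callable] = {
    "clamrfo": optimize,
    "mrfo": mrfo_baseline_optimize,
}


@dataclass
class ExperimentResult:
    errors: dict[tuple[str, str], np.ndarray]  # (function, algorithm) -> per-run errors
    records: dict[tuple[str, str], list[RunRecord]]
    summary: pd.DataFrame

    def error_matrix(self) -> pd.DataFrame:
        """Functions x algorithms matrix of mean errors (Friedman input)."""
        funcs = sorted({f for f, _ in self.errors})
        algos = sorted({a for _, a in self.errors})
        data = [[float(np.mean(self.errors[(f, a)])) for a in algos] for f in funcs]
        return pd.DataFrame(data, index=funcs, columns=algos)


def run_experiment(
    suite: Sequence[BenchmarkFunction],
    algorithms: dict[str, Callable] | Sequence[str],
    runs: int = 30,
    seed_base: int = 1000,
    config: OptimizerConfig | None = None,
    out: str | Path | None = None,
    keep_traces: bool = False,
) -> ExperimentResult:
    """Full cross of suite functions, algorithms, and seeded runs.

    Seeds are ``seed_base + run_index``, shared across algorithms so the
    comparison is paired. A failing run marks its cell entry NaN and the
    experiment continues.
    """
    if not isinstance(algorithms, dict):
        algorithms = {name: ALGORITHMS[name] for name in algorithms}
    seeds = [seed_base + i for i in range(runs)]
    base_cfg = OptimizerConfig() if config is None else config
    errors: dict[tuple[str, str], np.ndarray] = {}
    records: dict[tuple[str, str], list[RunRecord]] = {}
    rows = []
    for fn in suite:
        cfg = replace(
            base_cfg, category=fn.category, deceptive=fn.deceptive, hard=fn.hard,
            f_star=fn.bias,
        )
        for name, algo in algorithms.items():
            cell: list[RunRecord] = []
            errs = np.full(runs, np.nan)
            for i, s in enumerate(seeds):
                try:
                    rec = algo(fn, fn.bounds, cfg, seed=s, batch=True)
                    cell.append(rec)
                    errs[i] = rec.final_error
                except Exception as exc:  # cell marked failed, experiment continues
                    cell.append(None)
                    print(f"run failed ({fn.name}, {name}, seed {s}): {exc}")
            ok = errs[np.isfinite(errs)]
            conv = [r.convergence_iteration for r in cell if r is not None]
            conv_done = [c for c in conv if c is not None]
            rows.append(
                {
                    "function": fn.name,
                    "category": fn.category,
                    "algorithm": name,
                    "n": int(ok.size),
                    "mean_error": float(np.mean(ok)) if ok.size else np.nan,
                    "sd_error": float(np.std(ok, ddof=1)) if ok.size > 1 else np.nan,
                    "success_rate": success_rate(ok) if ok.size else np.nan,
                    "mean_convergence_iter": float(np.mean(conv_done)) if conv_done else np.nan,
                    "n_converged": len(conv_done),
                }
            )
            errors[(fn.name, name)] = errs
            records[(fn.name, name)] = cell
    summary = pd.DataFrame(rows)
    result = ExperimentResult(errors, records, summary)
    if out is not None:
        _persist(result, Path(out), keep_traces)
    return result


def _persist(result: ExperimentResult, out: Path, keep_traces: bool) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "summary.csv", index=False)
    result.error_matrix().to_csv(out / "mean_errors.csv")
    per_run = {
        f"{f}__{a}": e.tolist() for (f, a), e in result.errors.items()
    }
    (out / "per_run_errors.json").write_text(json.dumps(per_run, indent=1))
    if keep_traces:
        for (f, a), recs in result.records.items():
            for i, rec in enumerate(recs):
                if rec is not None:
                    (out / f"run_{f}_{a}_{i}.json").write_text(rec.to_json())
    _plot_convergence(result, out)


def _plot_convergence(result: ExperimentResult, out: Path) -> None:
    """Box plot of convergence-iteration distributions per (function, algorithm)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, data = [], []
    for (f, a), recs in sorted(result.records.items()):
        iters = [
            r.convergence_iteration if r.convergence_iteration is not None else r.iterations_run
            for r in recs
            if r is not None
        ]
        if iters:
            labels.append(f"{f}\n{a}")
            data.append(iters)
    if not data:
        return
    fig, ax = plt.subplots(figsize=(max(6, len(labels) * 1.2), 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("convergence iteration")
    fig.tight_layout()
    fig.savefig(out / "convergence_distribution.png", dpi=120)
    plt.close(fig)
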