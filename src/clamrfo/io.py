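"""Readers and writers shared by the CLI and the pipelines.

Expression matrices travel as delimited text (samples x genes, header row
of gene identifiers, first column the sample ID); labels as a two-column
file (sample ID, class).  Run records serialize to JSON with the error
trace as CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RunRecord
from .feature_selection import FSProblem

__all__ = ["read_expression", "write_expression", "write_run", "read_run_trace"]


def read_expression(x_path: str | Path, y_path: str | Path) -> FSProblem:
    """Load an expression matrix and labels, realigned by sample ID.

    The delimiter is sniffed (comma or tab). Duplicate sample IDs,
    non-numeric cells and label/sample mismatches raise informative
    errors.
    """
    X = pd.read_csv(x_path, sep=None, engine="python", index_col=0)
    if X.index.duplicated().any():
        dup = X.index[X.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID in expression matrix: {dup!r}")
    bad = X.columns[X.dtypes.eq(object)]
    if len(bad):
        raise ValueError(f"non-numeric expression column: {bad[0]!r}")
    labels = pd.read_csv(y_path, sep=None, engine="python", index_col=0)
    if labels.index.duplicated().any():
        raise ValueError("duplicate sample ID in label file")
    missing = X.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"sample missing from labels: {missing[0]!r}")
    y = labels.loc[X.index].iloc[:, 0]
    classes, y_codes = np.unique(y.to_numpy(), return_inverse=True)
    problem = FSProblem(X.to_numpy(dtype=float), y_codes, X.columns.to_numpy())
    problem.class_names = classes
    problem.sample_ids = X.index.to_numpy()
    return problem


def write_expression(problem: FSProblem, x_path: str | Path, y_path: str | Path,
                     class_names=None) -> None:
    ids = getattr(problem, "sample_ids", None)
    if ids is None:
        ids = np.array([f"s{i:03d}" for i in range(problem.X.shape[0])])
    df = pd.DataFrame(problem.X, index=pd.Index(ids, name="sample"), columns=problem.feature_names)
    df.to_csv(x_path)
    y = problem.y if class_names is None else np.asarray(class_names)[problem.y]
    pd.DataFrame({"class": y}, index=pd.Index(ids, name="sample")).to_csv(y_path)


def write_run(record: RunRecord, directory: str | Path) -> Path:
    """Persist a run: ``run.json`` (config, seed, best, counters) and
    ``trace.csv`` (iteration, best error, cumulative restarts)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "run.json").write_text(record.to_json())
    restart_iters = {r["iteration"] for r in record.restarts}
    with open(directory / "trace.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "best_error", "restarts_so_far"])
        n_restarts = 0
        for i, e in enumerate(record.error_trace):
            n_restarts += i in restart_iters
            w.writerow([i, repr(float(e)), n_restarts])
    return directory


def read_run_trace(directory: str | Path) -> np.ndarray:
    df = pd.read_csv(Path(directory) / "trace.csv")
    return df["best_error"].to_numpy()
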