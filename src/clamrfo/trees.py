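"""Compiled random-forest / bagged-tree ensemble for the wrapper objective.

The wrapper feature-selection objective evaluates a classifier inside a
5-fold cross-validation for every candidate feature mask — tens of
thousands of fits per selection run, each on a tiny matrix (tens of
samples, a handful of features).  This module provides a compiled CART
implementation (Gini impurity, depth-limited, bootstrap-bagged majority
vote, optional per-node feature subsampling) whose per-fit cost on such
matrices is tens of microseconds, which keeps whole nested
cross-validation studies tractable on one CPU.

Per-node subsampling of ``sqrt(p)`` candidate features (the classic
random-forest rule, and the default here) matters for wrapper selection:
it forces the ensemble to spread its splits across every supplied
feature, so a mask's cross-validated error genuinely reflects all its
members rather than whichever single gene dominates the first split.
With ``max_features=None`` the ensemble reduces to plain bagging.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["TreeEnsemble"]


@njit(cache=False)
def _fit_tree(X, y, sample_idx, max_depth, n_classes, mtry, tree_seed):
    np.random.seed(tree_seed)
    max_nodes = 2 ** (max_depth + 1) - 1
    feature = np.full(max_nodes, -1, np.int64)
    thresh = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    pred = np.zeros(max_nodes, np.int64)

    work = sample_idx.copy()
    n_total = work.shape[0]
    p = X.shape[1]
    feats = np.arange(p)

    # explicit DFS stack over (node, start, end, depth)
    stack_node = np.empty(max_nodes, np.int64)
    stack_s = np.empty(max_nodes, np.int64)
    stack_e = np.empty(max_nodes, np.int64)
    stack_d = np.empty(max_nodes, np.int64)
    stack_node[0], stack_s[0], stack_e[0], stack_d[0] = 0, 0, n_total, 0
    top = 1
    next_node = 1

    while top > 0:
        top -= 1
        node, s, e, depth = stack_node[top], stack_s[top], stack_e[top], stack_d[top]
        n = e - s
        counts = np.zeros(n_classes)
        for i in range(s, e):
            counts[y[work[i]]] += 1
        pred[node] = np.argmax(counts)
        n_major = counts[pred[node]]
        if depth >= max_depth or n_major == n or n < 2 or next_node + 2 > max_nodes:
            continue

        # partial Fisher-Yates: first mtry entries are the candidate features
        for t in range(mtry):
            j = t + np.random.randint(0, p - t)
            tmp_f = feats[t]
            feats[t] = feats[j]
            feats[j] = tmp_f

        best_feat = -1
        best_thresh = 0.0
        best_score = 1e18
        vals = np.empty(n)
        for jj in range(mtry):
            j = feats[jj]
            for i in range(n):
                vals[i] = X[work[s + i], j]
            order = np.argsort(vals, kind="mergesort")
            lc = np.zeros(n_classes)
            rc = counts.copy()
            for t in range(n - 1):
                c = y[work[s + order[t]]]
                lc[c] += 1.0
                rc[c] -= 1.0
                if vals[order[t]] == vals[order[t + 1]]:
                    continue
                nl = t + 1.0
                nr = n - nl
                gl = 1.0
                gr = 1.0
                for k in range(n_classes):
                    gl -= (lc[k] / nl) ** 2
                    gr -= (rc[k] / nr) ** 2
                score = (nl * gl + nr * gr) / n
                if score < best_score - 1e-12:
                    best_score = score
                    best_feat = j
                    best_thresh = 0.5 * (vals[order[t]] + vals[order[t + 1]])
        if best_feat < 0:
            continue

        # stable partition of work[s:e] by the chosen split
        tmp = np.empty(n, np.int64)
        nl = 0
        for i in range(s, e):
            if X[work[i], best_feat] <= best_thresh:
                tmp[nl] = work[i]
                nl += 1
        nr = nl
        for i in range(s, e):
            if X[work[i], best_feat] > best_thresh:
                tmp[nr] = work[i]
                nr += 1
        for i in range(n):
            work[s + i] = tmp[i]
        if nl == 0 or nl == n:
            continue

        feature[node] = best_feat
        thresh[node] = best_thresh
        left[node] = next_node
        right[node] = next_node + 1
        stack_node[top], stack_s[top], stack_e[top], stack_d[top] = next_node, s, s + nl, depth + 1
        top += 1
        stack_node[top], stack_s[top], stack_e[top], stack_d[top] = (
            next_node + 1, s + nl, e, depth + 1,
        )
        top += 1
        next_node += 2

    return feature, thresh, left, right, pred


@njit(cache=False)
def _predict_tree(X, feature, thresh, left, right, pred, out):
    for i in range(X.shape[0]):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= thresh[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = pred[node]


@njit(cache=False)
def _fit_predict_forest(Xtr, ytr, Xte, n_trees, max_depth, n_classes, mtry, boot, seeds):
    votes = np.zeros((Xte.shape[0], n_classes))
    out = np.empty(Xte.shape[0], np.int64)
    for b in range(n_trees):
        feature, thresh, left, right, pred = _fit_tree(
            Xtr, ytr, boot[b], max_depth, n_classes, mtry, seeds[b]
        )
        _predict_tree(Xte, feature, thresh, left, right, pred, out)
        for i in range(Xte.shape[0]):
            votes[i, out[i]] += 1.0
    return votes


def _resolve_mtry(p: int, max_features) -> int:
    if max_features is None:
        return p
    if max_features == "sqrt":
        return max(1, int(np.sqrt(p)))
    return max(1, min(int(max_features), p))


class TreeEnsemble:
    """Random forest (or, with ``max_features=None``, bagged trees) with an
    sklearn-like fit/predict API. Vote ties break toward the smaller class
    label."""

    def __init__(
        self,
        n_estimators: int = 50,
        max_depth: int = 5,
        random_state: int | None = None,
        max_features: str | int | None = "sqrt",
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state
        self.max_features = max_features
        self._trees: list | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TreeEnsemble":
        X = np.ascontiguousarray(X, dtype=np.float64)
        self.classes_, y_enc = np.unique(np.asarray(y), return_inverse=True)
        y_enc = y_enc.astype(np.int64)
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        mtry = _resolve_mtry(X.shape[1], self.max_features)
        self._trees = []
        for _ in range(self.n_estimators):
            idx = rng.integers(0, n, size=n).astype(np.int64)
            seed = int(rng.integers(0, 2**31 - 1))
            self._trees.append(
                _fit_tree(X, y_enc, idx, self.max_depth, len(self.classes_), mtry, seed)
            )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._trees is None:
            raise RuntimeError("fit must be called before predict")
        X = np.ascontiguousarray(X, dtype=np.float64)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        out = np.empty(X.shape[0], np.int64)
        for feature, thresh, left, right, pred in self._trees:
            _predict_tree(X, feature, thresh, left, right, pred, out)
            for i, o in enumerate(out):
                votes[i, o] += 1.0
        return self.classes_[np.argmax(votes, axis=1)]

    def fit_predict_fast(
        self,
        Xtr: np.ndarray,
        ytr: np.ndarray,
        Xte: np.ndarray,
        rng: np.random.Generator | None,
        n_classes: int,
        boot: np.ndarray | None = None,
        seeds: np.ndarray | None = None,
    ) -> np.ndarray:
        """Single-call fit+predict on pre-encoded labels (hot path).

        ``ytr`` must already be 0..n_classes-1 int64; returns predicted
        encoded labels for ``Xte``.  ``boot`` (n_estimators x n_train) and
        ``seeds`` (n_estimators) freeze the bootstrap resamples and
        per-tree feature-subsampling streams; otherwise both are drawn
        from ``rng``.
        """
        if boot is None:
            boot = rng.integers(0, Xtr.shape[0], size=(self.n_estimators, Xtr.shape[0]))
        if seeds is None:
            src = rng if rng is not None else np.random.default_rng(self.random_state)
            seeds = src.integers(0, 2**31 - 1, size=self.n_estimators)
        votes = _fit_predict_forest(
            np.ascontiguousarray(Xtr, dtype=np.float64),
            np.ascontiguousarray(ytr, dtype=np.int64),
            np.ascontiguousarray(Xte, dtype=np.float64),
            self.n_estimators,
            self.max_depth,
            n_classes,
            _resolve_mtry(Xtr.shape[1], self.max_features),
            np.ascontiguousarray(boot, dtype=np.int64),
            np.ascontiguousarray(seeds, dtype=np.int64),
        )
        return np.argmax(votes, axis=1)
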