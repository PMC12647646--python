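"""Binary-encoded wrapper feature selection with a nested CV protocol.

The optimizer searches the continuous relaxation ``[0, 1]^p`` of the
feature-mask space; a position is binarized at 0.5 only when evaluated
(somersault and Lévy dynamics therefore operate unchanged).  The wrapper
objective is the mean misclassification rate of a compact bagged-tree
ensemble under stratified internal 5-fold cross-validation, plus a small
compactness penalty ``lambda * k / p`` on the selected-feature count.

Preprocessing follows the standard two-stage screen for high-dimensional
low-sample-size expression data: a variance filter, then a Welch two-sample
t-test ranking that keeps the top 100 differentially expressed genes.  The
nested protocol refits the entire preprocessing + selection chain inside
each outer training partition, so outer test folds never leak into
selection.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps
from sklearn.feature_selection import VarianceThreshold
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import OptimizerConfig, RunRecord, optimize
from .initialization import Bounds
from .trees import TreeEnsemble

__all__ = [
    "FSProblem",
    "consensus_mask",
    "FSObjectiveConfig",
    "FSObjective",
    "variance_filter",
    "ttest_screen",
    "binarize",
    "select_features",
    "nested_cv",
    "diagnostic_metrics",
    "NestedCVResult",
]


@dataclass
class FSProblem:
    """Expression matrix (samples x genes) with aligned class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be samples x genes with rows(X) == len(y)")
        if np.isnan(self.X).any():
            raise ValueError("expression matrix contains missing values")
        if self.feature_names is None:
            self.feature_names = np.array([f"g{j}" for j in range(self.X.shape[1])])

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "FSProblem":
        return FSProblem(self.X[idx], self.y[idx], self.feature_names)

    def subset_features(self, idx: np.ndarray) -> "FSProblem":
        return FSProblem(self.X[:, idx], self.y, self.feature_names[idx])


def variance_filter(problem: FSProblem, min_var: float = 0.0) -> tuple[FSProblem, np.ndarray]:
    """Drop features with variance at or below ``min_var``; returns kept indices."""
    vt = VarianceThreshold(threshold=min_var)
    vt.fit(problem.X)
    kept = np.nonzero(vt.get_support())[0]
    if kept.size == 0:
        raise ValueError("variance filter removed every feature")
    return problem.subset_features(kept), kept


def ttest_screen(problem: FSProblem, top_k: int = 100) -> tuple[FSProblem, np.ndarray]:
    """Keep the ``top_k`` features by |Welch t| between the two classes."""
    classes = np.unique(problem.y)
    if classes.size != 2:
        raise ValueError("t-test screen requires binary labels")
    a = problem.X[problem.y == classes[0]]
    b = problem.X[problem.y == classes[1]]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples for the t-test")
    t, _ = sps.ttest_ind(a, b, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    order = np.argsort(-np.abs(t), kind="stable")
    kept = np.sort(order[: min(top_k, problem.n_features)])
    out = problem.subset_features(kept)
    out.screen_scores = np.abs(t)[kept]  # |t| of the kept features, for init bias
    return out, kept


def binarize(
    position: np.ndarray, threshold: float = 0.5, max_k: int | None = None
) -> np.ndarray:
    """Mask bits ``position > threshold``; an all-zero mask gets its largest
    coordinate forced on so every evaluated mask selects >= 1 feature.

    ``max_k`` caps the mask at the top-``max_k`` coordinates, restricting
    the search to ultra-compact subsets; continuous moves that would
    binarize to dense masks (e.g. somersaults across the threshold in many
    coordinates at once) then compete on their best-supported features
    instead of flooding the mask.
    """
    position = np.asarray(position, dtype=float)
    mask = position > threshold
    if not mask.any():
        mask = mask.copy()
        mask[int(np.argmax(position))] = True
    if max_k is not None and mask.sum() > max_k:
        mask = np.zeros_like(mask)
        mask[np.argsort(-position, kind="stable")[:max_k]] = True
    return mask


@dataclass
class FSObjectiveConfig:
    """Wrapper-objective configuration."""

    inner_folds: int = 5
    n_estimators: int = 50
    max_depth: int = 5
    max_features: str | int | None = "sqrt"
    compactness_weight: float = 0.01
    margin_weight: float = 0.02
    threshold: float = 0.5
    max_selected: int | None = 8
    consensus_top: int = 30  # elite masks aggregated into the final mask
    consensus_frac: float = 0.5  # bit-frequency threshold for the consensus

    def __post_init__(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.compactness_weight < 0:
            raise ValueError("compactness weight must be >= 0")


def _forest_votes(model, Xtr, ytr, Xte, n_classes, boot, seeds):
    from .trees import _fit_predict_forest, _resolve_mtry

    return _fit_predict_forest(
        np.ascontiguousarray(Xtr), np.ascontiguousarray(ytr),
        np.ascontiguousarray(Xte), model.n_estimators, model.max_depth,
        n_classes, _resolve_mtry(Xtr.shape[1], model.max_features),
        np.ascontiguousarray(boot, dtype=np.int64),
        np.ascontiguousarray(seeds, dtype=np.int64),
    )


class FSObjective:
    """Cached cross-validated misclassification objective over feature masks.

    Folds are stratified once at construction (seeded) and shared by every
    mask, so the objective is deterministic and mask values can be cached:
    repeated evaluation of the same mask costs a dictionary lookup.
    """

    def __init__(
        self,
        problem: FSProblem,
        cfg: FSObjectiveConfig | None = None,
        seed: int = 0,
    ):
        self.cfg = FSObjectiveConfig() if cfg is None else cfg
        self.classes_, self._y = np.unique(problem.y, return_inverse=True)
        self._y = self._y.astype(np.int64)
        self._X = np.ascontiguousarray(problem.X, dtype=np.float64)
        self.p = problem.n_features
        skf = StratifiedKFold(n_splits=self.cfg.inner_folds, shuffle=True, random_state=seed)
        self._folds = [
            (tr.astype(np.int64), te.astype(np.int64))
            for tr, te in skf.split(self._X, self._y)
        ]
        self._seed = seed
        self._model = TreeEnsemble(
            self.cfg.n_estimators, self.cfg.max_depth, max_features=self.cfg.max_features
        )
        # bootstrap resamples are frozen per fold and shared by every mask,
        # so mask comparisons are paired: the search cannot chase lucky
        # resampling noise, only genuine differences in fold fit
        boot_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB001]))
        self._boot = [
            boot_rng.integers(0, tr.size, size=(self.cfg.n_estimators, tr.size))
            for tr, _ in self._folds
        ]
        self._tree_seeds = [
            boot_rng.integers(0, 2**31 - 1, size=self.cfg.n_estimators)
            for _ in self._folds
        ]
        self.cache: dict[bytes, float] = {}
        self.distinct_evaluations = 0

    def evaluate_mask(self, mask: np.ndarray) -> float:
        """Mean CV misclassification + margin tie-break + compactness penalty.

        The primary term is the majority-vote misclassification rate, which
        moves in steps of one held-out sample and therefore plateaus; a
        small vote-margin term (mean fraction of trees voting wrongly)
        orders masks within a plateau — features that genuinely separate
        the classes produce near-unanimous votes, chance-fit noise features
        produce split ones.  The weights keep both secondary terms well
        below one misclassified sample except on exact plateaus.
        """
        key = np.packbits(mask).tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        self.distinct_evaluations += 1
        cols = np.nonzero(mask)[0]
        Xm = self._X[:, cols]
        hard = 0.0
        soft = 0.0
        for (tr, te), boot, seeds in zip(self._folds, self._boot, self._tree_seeds):
            votes = _forest_votes(
                self._model, Xm[tr], self._y[tr], Xm[te], len(self.classes_), boot, seeds
            )
            pred = np.argmax(votes, axis=1)
            hard += float(np.mean(pred != self._y[te]))
            correct = votes[np.arange(te.size), self._y[te]]
            soft += float(np.mean(1.0 - correct / votes.sum(axis=1)))
        k = len(self._folds)
        value = (
            hard / k
            + self.cfg.margin_weight * soft / k
            + self.cfg.compactness_weight * cols.size / self.p
        )
        self.cache[key] = value
        return value

    def __call__(self, position: np.ndarray) -> float:
        return self.evaluate_mask(
            binarize(position, self.cfg.threshold, self.cfg.max_selected)
        )


def _sparse_init(
    n: int,
    p: int,
    k0: int,
    rng: np.random.Generator,
    scores: np.ndarray | None = None,
) -> np.ndarray:
    """Initial relaxed positions whose masks select about ``k0`` features.

    Coordinates start below the binarization threshold; a subset of
    roughly ``k0`` per individual is lifted above it.  When filter scores
    (|t| statistics from the screening stage) are available, the lifted
    bits are drawn with probability proportional to the score rank — the
    classic hybrid filter-wrapper warm start.  Starting compact suits the
    ultra-sparse solutions the wrapper targets and keeps early objective
    evaluations cheap.
    """
    pos = rng.uniform(0.0, 0.5, size=(n, p))
    if scores is not None:
        ranks = np.empty(p)
        ranks[np.argsort(-np.asarray(scores), kind="stable")] = np.arange(p)
        weights = 1.0 / (1.0 + ranks) ** 2
    else:
        weights = np.ones(p)
    weights = weights / weights.sum()
    for i in range(n):
        k = min(max(1, rng.poisson(k0)), p)
        on = rng.choice(p, size=k, replace=False, p=weights)
        pos[i, on] = rng.uniform(0.5, 1.0, size=on.size)
    return pos


def select_features(
    problem: FSProblem,
    cfg: FSObjectiveConfig | None = None,
    seed: int = 0,
    n: int = 200,
    t_max: int = 300,
    init_k: int = 5,
) -> tuple[np.ndarray, RunRecord, FSObjective]:
    """Run the optimizer in ``[0,1]^p`` with binarize-before-evaluate.

    Returns the best mask, the run record, and the (cache-bearing)
    objective. Memory distances are Hamming on the binarized masks.
    """
    cfg = FSObjectiveConfig() if cfg is None else cfg
    obj = FSObjective(problem, cfg, seed=seed)
    p = problem.n_features
    bounds = Bounds.cube(0.0, 1.0, p)
    opt_cfg = OptimizerConfig(
        n=n,
        t_max=t_max,
        category="multimodal",
        binary_mode=True,
        f_star=0.0,
        success_threshold=0.0,
        convergence_threshold=0.0,
    )
    init_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1A5]))
    scores = getattr(problem, "screen_scores", None)
    opt_cfg.init_positions = _sparse_init(n, p, init_k, init_rng, scores=scores)
    rec = optimize(obj, bounds, opt_cfg, seed=seed, batch=False)
    mask = consensus_mask(obj, cfg.consensus_top, cfg.consensus_frac)
    if mask is None:
        mask = binarize(rec.best_position, cfg.threshold, cfg.max_selected)
    return mask, rec, obj


def consensus_mask(
    obj: FSObjective, top: int = 30, frac: float = 0.5
) -> np.ndarray | None:
    """Stability-style aggregate of the best evaluated masks.

    Bits selected by at least ``frac`` of the ``top`` best distinct masks
    form the final mask.  Individual near-optimal masks disagree on
    features that merely fit the particular training draw, but agree on
    consistently informative ones, so the consensus is more stable than
    the single best mask.
    """
    if top <= 0 or not obj.cache:
        return None
    items = sorted(obj.cache.items(), key=lambda kv: kv[1])[:top]
    bits = np.array(
        [np.unpackbits(np.frombuffer(k, np.uint8))[: obj.p] for k, _ in items]
    ).astype(float)
    mask = bits.mean(axis=0) >= frac
    if not mask.any():  # degenerate: fall back to the best mask
        return bits[0].astype(bool)
    return mask


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def diagnostic_metrics(tp: int, fp: int, tn: int, fn: int) -> DiagnosticMetrics:
    """Sensitivity, specificity, precision and F1 from summed 2x2 counts.

    Undefined ratios (zero denominators) are reported as NaN.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = ratio(2 * prec * sens, prec + sens) if np.isfinite(prec) and np.isfinite(sens) else float("nan")
    return DiagnosticMetrics(sens, spec, prec, f1)


def _default_final_learners() -> dict[str, Callable]:
    return {
        "random_forest": lambda seed: TreeEnsemble(50, 5, random_state=seed),
        "linear_svm": lambda seed: SVC(kernel="linear", random_state=seed),
    }


@dataclass
class FoldResult:
    mask: np.ndarray
    n_selected: int
    selected_names: np.ndarray
    metrics: dict[str, dict[str, float]]  # learner -> metric -> value
    confusion: dict[str, np.ndarray]
    train_fingerprint: int


@dataclass
class NestedCVResult:
    folds: list[FoldResult]
    aggregate: dict[str, dict[str, float]]  # learner -> metric -> mean/sd
    summed_confusion: dict[str, np.ndarray]
    diagnostics: dict[str, DiagnosticMetrics]
    mean_selected: float


def nested_cv(
    problem: FSProblem,
    cfg: FSObjectiveConfig | None = None,
    outer_folds: int = 5,
    seed: int = 0,
    n: int = 200,
    t_max: int = 300,
    top_k: int = 100,
    min_var: float = 0.0,
    final_learners: dict[str, Callable] | None = None,
    init_k: int = 5,
) -> NestedCVResult:
    """Leakage-free nested cross-validation of the whole selection pipeline.

    The variance filter, t-test screen and wrapper selection are refit on
    each outer training partition only; the resulting mask is evaluated by
    the final learners on the held-out outer fold.
    """
    cfg = FSObjectiveConfig() if cfg is None else cfg
    learners = _default_final_learners() if final_learners is None else final_learners
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    all_idx = np.arange(problem.X.shape[0])
    for k_fold, (tr, te) in enumerate(skf.split(problem.X, problem.y)):
        assert np.intersect1d(tr, te).size == 0  # leakage guard
        train = problem.subset_samples(tr)
        fingerprint = hash(tr.tobytes())
        filtered, kept_var = variance_filter(train, min_var)
        screened, kept_t = ttest_screen(filtered, top_k)
        mask, _rec, _obj = select_features(
            screened, cfg, seed=seed * 1000 + k_fold, n=n, t_max=t_max, init_k=init_k
        )
        # map mask back to original feature indices
        sel_local = np.nonzero(mask)[0]
        sel_global = kept_var[kept_t[sel_local]]
        Xtr = problem.X[np.ix_(tr, sel_global)]
        Xte = problem.X[np.ix_(te, sel_global)]
        ytr, yte = problem.y[tr], problem.y[te]
        classes = np.unique(problem.y)
        pos_label = classes[np.argmin([np.sum(problem.y == c) for c in classes])]
        metrics: dict[str, dict[str, float]] = {}
        confusion: dict[str, np.ndarray] = {}
        for lname, factory in learners.items():
            model = factory(seed * 1000 + k_fold)
            model.fit(Xtr, ytr)
            pred = model.predict(Xte)
            metrics[lname] = {
                "accuracy": float(accuracy_score(yte, pred)),
                "precision": float(precision_score(yte, pred, average="weighted", zero_division=0)),
                "recall": float(recall_score(yte, pred, average="weighted", zero_division=0)),
                "f1": float(f1_score(yte, pred, average="weighted", zero_division=0)),
            }
            if classes.size == 2:
                neg = classes[classes != pos_label][0]
                confusion[lname] = confusion_matrix(yte, pred, labels=[pos_label, neg])
        folds.append(
            FoldResult(
                mask=mask,
                n_selected=int(mask.sum()),
                selected_names=problem.feature_names[sel_global],
                metrics=metrics,
                confusion=confusion,
                train_fingerprint=fingerprint,
            )
        )
    aggregate: dict[str, dict[str, float]] = {}
    summed: dict[str, np.ndarray] = {}
    diags: dict[str, DiagnosticMetrics] = {}
    for lname in learners:
        aggregate[lname] = {}
        for m in ("accuracy", "precision", "recall", "f1"):
            vals = [f.metrics[lname][m] for f in folds]
            aggregate[lname][f"{m}_mean"] = float(np.mean(vals))
            aggregate[lname][f"{m}_sd"] = float(np.std(vals, ddof=1))
        if folds[0].confusion:
            cm = sum(f.confusion[lname] for f in folds)
            summed[lname] = cm
            tp, fn = int(cm[0, 0]), int(cm[0, 1])
            fp, tn = int(cm[1, 0]), int(cm[1, 1])
            diags[lname] = diagnostic_metrics(tp, fp, tn, fn)
    return NestedCVResult(
        folds=folds,
        aggregate=aggregate,
        summed_confusion=summed,
        diagnostics=diags,
        mean_selected=float(np.mean([f.n_selected for f in folds])),
    )
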