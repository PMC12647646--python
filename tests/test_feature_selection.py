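"""Wrapper selection pipeline: preprocessing, objective, masks, nested CV."""

import numpy as np
import pytest

from clamrfo.feature_selection import (
    FSObjective,
    FSObjectiveConfig,
    FSProblem,
    binarize,
    diagnostic_metrics,
    nested_cv,
    select_features,
    ttest_screen,
    variance_filter,
)


def test_problem_validation():
    with pytest.raises(ValueError):
        FSProblem(np.zeros((3, 2)), np.zeros(4))
    with pytest.raises(ValueError):
        FSProblem(np.array([[1.0, np.nan]]), np.zeros(1))


def test_variance_filter_removes_constant_column():
    X = np.array([[1.0, 5.0, 2.0], [2.0, 5.0, 1.0], [3.0, 5.0, 4.0],
                  [0.0, 5.0, 3.0], [1.5, 5.0, 2.5]])
    prob = FSProblem(X, np.array([0, 0, 1, 1, 0]))
    out, kept = variance_filter(prob)
    assert list(kept) == [0, 2]
    assert out.n_features == 2
    np.testing.assert_array_equal(out.feature_names, ["g0", "g2"])


def test_variance_filter_identity_when_nothing_constant(rng):
    prob = FSProblem(rng.normal(size=(6, 4)), np.array([0, 1, 0, 1, 0, 1]))
    out, kept = variance_filter(prob, 0.0)
    assert list(kept) == [0, 1, 2, 3]


def test_ttest_screen_ranks_shifted_feature_first():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 3))
    X[3:, 1] += 10.0  # large shift in feature 1 for class 1
    prob = FSProblem(X, np.array([0, 0, 0, 1, 1, 1]))
    out, kept = ttest_screen(prob, top_k=1)
    assert list(kept) == [1]
    # identical-in-both-classes feature ranks last: with top_k = p all kept
    out_all, _ = ttest_screen(prob, top_k=10)
    assert out_all.n_features == 3


def test_ttest_screen_requires_two_per_class():
    prob = FSProblem(np.random.default_rng(1).normal(size=(3, 2)), np.array([0, 1, 1]))
    with pytest.raises(ValueError):
        ttest_screen(prob)


def test_binarize_contracts():
    np.testing.assert_array_equal(binarize(np.array([0.7, 0.2]), 0.5), [True, False])
    # all below threshold: argmax forced on
    m = binarize(np.array([0.1, 0.4, 0.3]), 0.5)
    assert m.sum() == 1 and m[1]
    assert binarize(np.array([0.3, 0.2]), 0.0).all()  # threshold 0 -> all on
    capped = binarize(np.array([0.9, 0.8, 0.7, 0.6]), 0.5, max_k=2)
    assert capped.sum() == 2 and capped[0] and capped[1]


def _separable_problem(n=40, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < 0.5).astype(int)
    X[y == 1, 0] += 100.0  # feature 0 separates perfectly
    return FSProblem(X, y)


def test_objective_zero_error_on_separable_feature():
    prob = _separable_problem()
    obj = FSObjective(prob, FSObjectiveConfig(compactness_weight=0.0, margin_weight=0.0), seed=1)
    mask = np.zeros(6, bool)
    mask[0] = True
    assert obj.evaluate_mask(mask) == 0.0


def test_objective_matches_majority_rate_under_label_shuffle():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(72, 8))
    y = np.array([0] * 47 + [1] * 25)
    rng.shuffle(y)  # labels carry no signal
    obj = FSObjective(FSProblem(X, y), FSObjectiveConfig(compactness_weight=0.0, margin_weight=0.0), seed=2)
    mask = np.ones(8, bool)
    err = obj.evaluate_mask(mask)
    assert err == pytest.approx(25 / 72, abs=0.1)


def test_objective_deterministic_and_cached():
    prob = _separable_problem(seed=5)
    cfg = FSObjectiveConfig()
    a = FSObjective(prob, cfg, seed=7)
    b = FSObjective(prob, cfg, seed=7)
    mask = np.array([True, False, True, False, True, False])
    assert a.evaluate_mask(mask) == b.evaluate_mask(mask)
    a.evaluate_mask(mask)
    assert a.distinct_evaluations == 1  # second call served from cache


def test_objective_agrees_with_sklearn_forest_ordering():
    """Cross-check: mask ordering by the compiled forest's CV error matches
    sklearn's random forest on clearly separated alternatives."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 5))
    y = np.array([0, 1] * 30)
    X[y == 1, 0] += 2.5
    X[y == 1, 1] += 2.5
    prob = FSProblem(X, y)
    obj = FSObjective(prob, FSObjectiveConfig(compactness_weight=0.0, margin_weight=0.0), seed=3)
    good = np.array([True, True, False, False, False])
    bad = np.array([False, False, True, True, False])
    assert obj.evaluate_mask(good) < obj.evaluate_mask(bad)
    skf = StratifiedKFold(5, shuffle=True, random_state=0)
    sk_good = 1 - cross_val_score(
        RandomForestClassifier(50, max_depth=5, random_state=0), X[:, good], y, cv=skf
    ).mean()
    sk_bad = 1 - cross_val_score(
        RandomForestClassifier(50, max_depth=5, random_state=0), X[:, bad], y, cv=skf
    ).mean()
    assert sk_good < sk_bad


def test_select_features_recovers_planted_pair_vs_exhaustive_oracle():
    """p = 10 with two strongly informative features: the returned mask
    contains both in >= 9/10 seeds, and matches the exhaustive-search
    optimum's informative content."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 10))
    y = np.array([0, 1] * 20)
    X[y == 1, 2] += 3.0
    X[y == 1, 7] += 3.0
    prob = FSProblem(X, y)
    hits = 0
    for seed in range(10):
        mask, rec, obj = select_features(prob, seed=seed, n=30, t_max=30)
        if mask[2] and mask[7]:
            hits += 1
    assert hits >= 9
    # exhaustive oracle over all 2^10 - 1 masks confirms {2, 7} is optimal content
    oracle = FSObjective(prob, FSObjectiveConfig(), seed=0)
    best_val, best_mask = np.inf, None
    for bits in range(1, 1024):
        m = np.array([(bits >> j) & 1 for j in range(10)], dtype=bool)
        v = oracle.evaluate_mask(m)
        if v < best_val:
            best_val, best_mask = v, m
    assert best_mask[2] and best_mask[7]


def test_large_compactness_weight_forces_single_feature():
    prob = _separable_problem(seed=9)
    cfg = FSObjectiveConfig(compactness_weight=50.0, consensus_top=0)
    mask, rec, obj = select_features(prob, cfg, seed=1, n=20, t_max=25)
    assert mask.sum() == 1


def test_select_features_deterministic():
    prob = _separable_problem(seed=2)
    a, _, _ = select_features(prob, seed=3, n=20, t_max=15)
    b, _, _ = select_features(prob, seed=3, n=20, t_max=15)
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize(
    "tp,fp,tn,fn,sens,spec,prec,f1",
    [
        (22, 1, 46, 3, 0.880, 0.979, 0.957, 0.917),
        (23, 2, 45, 2, 0.920, 0.957, 0.920, 0.920),
        (23, 1, 46, 2, 0.920, 0.979, 0.958, 0.938),
        (23, 3, 44, 2, 0.920, 0.936, 0.885, 0.902),
        (13, 0, 20, 1, 0.929, 1.000, 1.000, 0.963),
    ],
)
def test_diagnostic_metrics_from_confusion_counts(tp, fp, tn, fn, sens, spec, prec, f1):
    d = diagnostic_metrics(tp, fp, tn, fn)
    assert d.sensitivity == pytest.approx(sens, abs=5e-4)
    assert d.specificity == pytest.approx(spec, abs=5e-4)
    assert d.precision == pytest.approx(prec, abs=5e-4)
    assert d.f1 == pytest.approx(f1, abs=1e-3)


def test_diagnostic_metrics_degenerate():
    d = diagnostic_metrics(0, 0, 10, 5)
    assert d.sensitivity == 0.0
    assert np.isnan(d.precision)
    perfect = diagnostic_metrics(10, 0, 10, 0)
    assert perfect.sensitivity == perfect.specificity == perfect.precision == perfect.f1 == 1.0
    with pytest.raises(ValueError):
        diagnostic_metrics(-1, 0, 0, 0)


def test_nested_cv_fold_sizes_and_aggregation(synth_problem):
    problem, _ = synth_problem
    res = nested_cv(problem, outer_folds=5, seed=0, n=12, t_max=6, top_k=20)
    sizes = []
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(5, shuffle=True, random_state=0)
    for tr, te in skf.split(problem.X, problem.y):
        sizes.append(te.size)
    assert sorted(sizes, reverse=True) == [15, 15, 14, 14, 14]
    for lname, agg in res.aggregate.items():
        per_fold = [f.metrics[lname]["accuracy"] for f in res.folds]
        assert agg["accuracy_mean"] == pytest.approx(np.mean(per_fold))
    assert len(res.folds) == 5
    assert res.mean_selected == pytest.approx(np.mean([f.n_selected for f in res.folds]))
    # leakage guard: every fold trained on a distinct proper subset
    assert len({f.train_fingerprint for f in res.folds}) == 5
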