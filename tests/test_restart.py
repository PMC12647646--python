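"""Stagnation counting, strategy choice, and partial reinitialization."""

import numpy as np
import pytest

from clamrfo.initialization import Bounds
from clamrfo.memory import MemoryBanks
from clamrfo.restart import (
    AGGRESSIVE_WEIGHTS,
    DEFAULT_WEIGHTS,
    RestartPolicy,
    StagnationCounter,
    choose_strategy,
    population_entropy,
    restart_population,
)


def test_counter_resets_on_strict_improvement():
    c = StagnationCounter()
    for v in [10.0, 9.0, 8.0, 7.0]:
        c.update(v)
    assert c.iterations_without_improvement == 0


def test_counter_triggers_exactly_at_window():
    c = StagnationCounter()
    c.update(5.0)
    for t in range(1, 13):
        c.update(5.0)
        assert c.triggered(12) == (t >= 12)


def test_sub_tolerance_improvement_counts_as_stagnation():
    c = StagnationCounter(tol=1e-12)
    c.update(1.0)
    c.update(1.0 - 1e-14)
    assert c.iterations_without_improvement == 1


def test_choose_strategy_degenerate_weights(rng):
    for _ in range(50):
        assert choose_strategy("unimodal", 0.9, (1.0, 0.0, 0.0), rng) == "memory_based"


def test_choose_strategy_frequencies(rng):
    draws = [choose_strategy("unimodal", 0.9, DEFAULT_WEIGHTS, rng) for _ in range(10_000)]
    for name, w in zip(("memory_based", "levy_restart", "random_restart"), DEFAULT_WEIGHTS):
        assert np.mean([d == name for d in draws]) == pytest.approx(w, abs=0.02)


def test_early_or_deceptive_is_more_aggressive(rng):
    early = [choose_strategy("composition", 0.1, DEFAULT_WEIGHTS, rng) for _ in range(4000)]
    late = [choose_strategy("unimodal", 0.9, DEFAULT_WEIGHTS, rng) for _ in range(4000)]
    agg_early = np.mean([d != "memory_based" for d in early])
    agg_late = np.mean([d != "memory_based" for d in late])
    assert agg_early > agg_late
    assert agg_early == pytest.approx(AGGRESSIVE_WEIGHTS[1] + AGGRESSIVE_WEIGHTS[2], abs=0.03)


def test_restart_replaces_exact_count_and_preserves_best(rng):
    n, d = 200, 5
    b = Bounds.cube(-100, 100, d)
    pos = rng.uniform(-100, 100, (n, d))
    fit = rng.random(n)
    best = int(np.argmin(fit))
    policy = RestartPolicy(fraction=0.35)
    out, victims, strategy = restart_population(
        pos, fit, None, policy, b, "multimodal", 0.5, rng
    )
    assert victims.size == int(np.ceil(0.35 * n)) == 70
    assert best not in victims
    np.testing.assert_array_equal(out[best], pos[best])
    untouched = np.setdiff1d(np.arange(n), victims)
    np.testing.assert_array_equal(out[untouched], pos[untouched])


def test_memory_strategy_falls_back_when_empty(rng):
    b = Bounds.cube(-1, 1, 2)
    pos = rng.uniform(-1, 1, (10, 2))
    fit = rng.random(10)
    policy = RestartPolicy(weights=(1.0, 0.0, 0.0))
    _, _, strategy = restart_population(
        pos, fit, MemoryBanks(), policy, b, "unimodal", 0.9, rng
    )
    assert strategy == "levy_restart"


def test_levy_restart_clusters_near_midpoint(rng):
    b = Bounds.cube(-100, 100, 3)
    pos = rng.uniform(-100, 100, (400, 3))
    fit = rng.random(400)
    policy = RestartPolicy(weights=(0.0, 1.0, 0.0))
    out, victims, strategy = restart_population(
        pos, fit, None, policy, b, "unimodal", 0.9, rng
    )
    assert strategy == "levy_restart"
    dist = np.linalg.norm(out[victims], axis=1)
    assert np.median(dist) < 0.25 * 200


def test_restart_increases_diversity_on_converged_population(rng):
    """Mean pairwise distance strictly grows in >= 95% of stress trials."""
    b = Bounds.cube(-100, 100, 4)
    wins = 0
    for trial in range(100):
        trng = np.random.default_rng(trial)
        centre = trng.uniform(-50, 50, 4)
        pos = centre + trng.normal(scale=0.01, size=(40, 4))
        fit = trng.random(40)
        out, _, _ = restart_population(
            pos, fit, None, RestartPolicy(), b, "multimodal", 0.5, trng
        )

        def mean_pdist(x):
            diff = x[:, None, :] - x[None, :, :]
            return np.sqrt((diff**2).sum(-1)).mean()

        wins += mean_pdist(out) > mean_pdist(pos)
    assert wins >= 95


def test_population_entropy_ranges(rng):
    b = Bounds.cube(0, 1, 3)
    spread = rng.uniform(0, 1, (500, 3))
    collapsed = np.full((500, 3), 0.55) + rng.normal(scale=1e-4, size=(500, 3))
    assert population_entropy(spread, b) > 0.9
    assert population_entropy(collapsed, b) < 0.2


def test_policy_validation():
    with pytest.raises(ValueError):
        RestartPolicy(fraction=0.5)
    with pytest.raises(ValueError):
        RestartPolicy(weights=(0.5, 0.2, 0.2))
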