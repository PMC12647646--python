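"""Ablation presets, improvement arithmetic, sensitivity-grid mechanics."""

import numpy as np
import pytest

from clamrfo.benchmarks import make_function
from clamrfo.core import OptimizerConfig, Toggles, optimize
from clamrfo.harness import (
    ABLATION_PRESETS,
    improvement_pct,
    preset_toggles,
    run_ablation,
    run_sensitivity_grid,
)


def test_full_preset_equals_defaults():
    assert preset_toggles("Full") == Toggles()


def test_only_and_no_presets():
    only = preset_toggles("Elite Only")
    assert only.elite_guidance
    assert not any([only.chaos, only.levy, only.memory, only.adaptive_params,
                    only.restart, only.local_search])
    no_levy = preset_toggles("No Lévy")
    assert not no_levy.levy
    assert all([no_levy.chaos, no_levy.memory, no_levy.elite_guidance,
                no_levy.adaptive_params, no_levy.restart, no_levy.local_search])
    combo = preset_toggles("Chaos+Lévy")
    assert combo.chaos and combo.levy and not combo.memory
    assert not any(vars(preset_toggles("Baseline")).values())
    with pytest.raises(ValueError):
        preset_toggles("Turbo Mode")


@pytest.mark.parametrize(
    "cell,pct",
    [(0.478, 85.2), (1.673, 48.3), (1.496, 53.8), (0.894, 72.4), (2.338, 27.8)],
)
def test_improvement_reproduces_sensitivity_grid_rows(cell, pct):
    """Each printed grid percentage follows from its mean and the printed
    baseline 3.236 by pure arithmetic."""
    assert improvement_pct(3.236, cell) == pytest.approx(pct, abs=0.06)


def test_ablation_percentages_share_one_implied_baseline():
    """The printed ablation percentages are mutually consistent: every
    (mean, pct) row implies the same baseline value to within rounding.
    (That implied baseline is ~0.714, not the grid baseline.)"""
    rows = [(0.246, 65.5), (0.242, 66.7), (0.245, 66.3), (0.276, 61.4),
            (0.370, 48.1), (0.382, 46.3), (0.442, 38.2), (0.627, 12.2),
            (0.389, 45.7), (0.474, 33.8), (0.521, 26.9), (0.793, -10.9),
            (1.250, -75.1)]
    implied = [cell / (1 - pct / 100.0) for cell, pct in rows]
    assert np.ptp(implied) < 0.02
    assert improvement_pct(1.0, 1.0) == 0.0


def test_every_preset_runs_on_2d_sphere():
    fn = make_function("sphere", 2, seed=1)
    cfg = OptimizerConfig(n=12, t_max=20, category="unimodal", f_star=fn.bias)
    df = run_ablation(fn, fn.bounds, presets=tuple(ABLATION_PRESETS), runs=1, seed=0, config=cfg)
    assert len(df) == len(ABLATION_PRESETS)
    assert set(df.columns) >= {"preset", "mean", "sd", "rank", "improvement_pct"}
    assert df["mean"].is_monotonic_increasing
    base = df[df["preset"] == "Baseline"]["improvement_pct"].iloc[0]
    assert base == pytest.approx(0.0)


def test_sensitivity_grid_single_cell():
    fn = make_function("sphere", 2, seed=2)
    cfg = OptimizerConfig(n=10, t_max=15, category="unimodal", f_star=fn.bias)
    df = run_sensitivity_grid(
        fn, fn.bounds, maps=("logistic",), cr0_values=(0.1,), init_modes=("random",),
        runs=2, seed=0, config=cfg,
    )
    assert len(df) == 1
    assert df["n"].iloc[0] == 2
    assert df["improvement_pct"].iloc[0] == pytest.approx(0.0)  # baseline vs itself


def test_grid_covers_cross_product():
    fn = make_function("sphere", 2, seed=3)
    cfg = OptimizerConfig(n=8, t_max=10, category="unimodal", f_star=fn.bias)
    df = run_sensitivity_grid(
        fn, fn.bounds, maps=("circle", "tent"), cr0_values=(0.3, 0.9),
        init_modes=("random", "chaotic"), runs=1, seed=1, config=cfg,
    )
    assert len(df) == 8
    assert set(df["map"]) == {"circle", "tent"}


def test_no_chaos_preset_changes_control_distribution():
    fn = make_function("sphere", 2, seed=4)
    cfg = OptimizerConfig(n=10, t_max=300, category="unimodal", f_star=fn.bias,
                          toggles=preset_toggles("No Chaos"))
    rec = optimize(fn, fn.bounds, cfg, seed=0, batch=True)
    c = rec.c_log
    # uniform draws on [0.1, 0.9]: mean near 0.5 and no mass outside
    assert np.all((c >= 0.1) & (c <= 0.9))
    assert abs(np.mean(c) - 0.5) < 0.05


def test_disabling_restart_prolongs_stagnation():
    fn = make_function("composition", 3, seed=6, deceptive=True)
    longest_stall_full, longest_stall_norestart = [], []
    for seed in range(6):
        for log, name in ((longest_stall_full, "Full"), (longest_stall_norestart, "No Restart")):
            cfg = OptimizerConfig(n=20, t_max=120, category="composition", deceptive=True,
                                  f_star=fn.bias, toggles=preset_toggles(name))
            rec = optimize(fn, fn.bounds, cfg, seed=seed, batch=True)
            # longest run of non-improving iterations in the trace
            d = np.diff(rec.error_trace) == 0
            stall = best = 0
            for flat in d:
                stall = stall + 1 if flat else 0
                best = max(best, stall)
            log.append(best)
    assert np.mean(longest_stall_norestart) > np.mean(longest_stall_full)
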