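"""Stagnation detection and partial-population restart.

A counter tracks iterations without strict improvement of the global best
(improvements below an absolute tolerance count as stagnation).  When the
counter reaches the category's ``T_restart`` window, the worst 30-40% of
the population is reinitialised by one of three strategies drawn at
random:

* **memory_based** — a bank sample plus Gaussian perturbation,
* **levy_restart** — Lévy steps around the domain midpoint,
* **random_restart** — uniform redraw inside the bounds.

Early in the run (``r_t < 0.3``) and on deceptive landscapes the draw
shifts toward the more aggressive Lévy/random strategies.  The best
individual is never replaced.  A Shannon diversity entropy of the
population (average over per-dimension 10-bin histograms) is logged as a
diagnostic and can optionally co-trigger restarts via an entropy floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .initialization import Bounds
from .kernels import LevyParams, levy_sample
from .memory import MemoryBanks

__all__ = [
    "RestartPolicy",
    "StagnationCounter",
    "choose_strategy",
    "restart_population",
    "population_entropy",
]

STRATEGIES = ("memory_based", "levy_restart", "random_restart")
DEFAULT_WEIGHTS = (0.4, 0.3, 0.3)
AGGRESSIVE_WEIGHTS = (0.2, 0.4, 0.4)


@dataclass(frozen=True)
class RestartPolicy:
    """Restart configuration; ``fraction`` of worst individuals replaced."""

    t_restart: int = 12
    fraction: float = 0.35
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    tol: float = 1e-12
    entropy_floor: float | None = None
    memory_sigma_frac: float = 0.05  # Gaussian perturbation, fraction of range
    levy_scale_frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0.30 - 1e-9 <= self.fraction <= 0.40 + 1e-9:
            raise ValueError("restart fraction must lie in [0.30, 0.40]")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("strategy weights must sum to 1")


@dataclass
class StagnationCounter:
    """Counts consecutive iterations without strict best-fitness improvement."""

    tol: float = 1e-12
    best_so_far: float = np.inf
    iterations_without_improvement: int = 0

    def update(self, new_best: float) -> "StagnationCounter":
        if new_best < self.best_so_far - self.tol:
            self.best_so_far = new_best
            self.iterations_without_improvement = 0
        else:
            self.best_so_far = min(self.best_so_far, new_best)
            self.iterations_without_improvement += 1
        return self

    def triggered(self, t_restart: int) -> bool:
        return self.iterations_without_improvement >= t_restart

    def reset(self) -> None:
        self.iterations_without_improvement = 0


def choose_strategy(
    category: str,
    r_t: float,
    weights: tuple[float, float, float],
    rng: np.random.Generator,
    deceptive: bool = False,
) -> str:
    """Draw a restart strategy; aggressive mass early or on deceptive runs."""
    if r_t < 0.3 or deceptive:
        weights = AGGRESSIVE_WEIGHTS if weights == DEFAULT_WEIGHTS else weights
    return STRATEGIES[int(rng.choice(3, p=np.asarray(weights)))]


def population_entropy(positions: np.ndarray, bounds: Bounds, bins: int = 10) -> float:
    """Shannon entropy of per-dimension occupancy histograms, averaged
    over dimensions and normalised to [0, 1]."""
    unit = (positions - bounds.lb) / bounds.range
    ent = 0.0
    for j in range(positions.shape[1]):
        counts, _ = np.histogram(unit[:, j], bins=bins, range=(0.0, 1.0))
        p = counts / counts.sum()
        p = p[p > 0]
        ent += float(-(p * np.log(p)).sum()) / np.log(bins)
    return ent / positions.shape[1]


def restart_population(
    positions: np.ndarray,
    fitness: np.ndarray,
    banks: MemoryBanks | None,
    policy: RestartPolicy,
    bounds: Bounds,
    category: str,
    r_t: float,
    rng: np.random.Generator,
    deceptive: bool = False,
    levy: LevyParams | None = None,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Replace the worst ``ceil(fraction N)`` individuals in place.

    Returns ``(new_positions, replaced_index_array, strategy)``; replaced
    rows have undefined fitness and must be re-evaluated by the caller.
    The incumbent best row is never replaced.
    """
    n, d = positions.shape
    n_replace = int(np.ceil(policy.fraction * n))
    order = np.argsort(fitness)  # ascending: best first
    victims = order[n - n_replace:]  # worst tail, never contains the best (n_replace < n)
    strategy = choose_strategy(category, r_t, policy.weights, rng, deceptive)
    if strategy == "memory_based" and (banks is None or len(banks) == 0):
        strategy = "levy_restart"
    levy = LevyParams() if levy is None else levy
    new = np.empty((n_replace, d))
    if strategy == "memory_based":
        sigma = policy.memory_sigma_frac * bounds.range
        for i in range(n_replace):
            ref = banks.sample_reference(rng)
            new[i] = ref + rng.normal(size=d) * sigma
    elif strategy == "levy_restart":
        mid = (bounds.lb + bounds.ub) / 2.0
        steps = levy_sample(levy, n_replace * d, rng, size=(n_replace, d))
        new = mid + policy.levy_scale_frac * bounds.range * steps
    else:
        new = bounds.lb + rng.random((n_replace, d)) * bounds.range
    out = positions.copy()
    out[victims] = bounds.clamp(new)
    return out, victims, strategy
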