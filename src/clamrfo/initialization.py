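"""Hybrid population initialization.

The starting population mixes three samplers whose proportions depend on
the benchmark-function category:

* Latin Hypercube stratification with within-stratum offsets from a
  scrambled Sobol stream (60-70% of the population) for uniform coverage,
* Lévy-flight steps centred on the domain midpoint (20-35%; composition
  landscapes get the top of the range) for exploratory spread, and
* plain uniform sampling for the remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .kernels import LevyParams, levy_sample

__all__ = ["Bounds", "InitMix", "lhs_sobol", "levy_centered", "initial_positions"]

#: Default sampler mix (lhs, levy, uniform) keyed by function category.
DEFAULT_MIX = {
    "unimodal": (0.65, 0.225, 0.125),
    "multimodal": (0.65, 0.225, 0.125),
    "hybrid": (0.65, 0.225, 0.125),
    "composition": (0.60, 0.35, 0.05),
}

#: Lévy step scale as a fraction of the per-dimension range.
DEFAULT_LEVY_SCALE = 0.1


@dataclass(frozen=True)
class Bounds:
    """Box constraints ``[lb, ub]^D`` of the search space."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if lb.shape != ub.shape or lb.ndim != 1:
            raise ValueError("lb and ub must be 1-D arrays of equal length")
        if not np.all(lb < ub):
            raise ValueError("require lb < ub elementwise")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @classmethod
    def cube(cls, lo: float, hi: float, dim: int) -> "Bounds":
        return cls(np.full(dim, float(lo)), np.full(dim, float(hi)))

    @property
    def dim(self) -> int:
        return self.lb.size

    @property
    def range(self) -> np.ndarray:
        return self.ub - self.lb

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lb) and np.all(x <= self.ub))


@dataclass(frozen=True)
class InitMix:
    """Sampler proportions (LHS/Sobol, Lévy-centred, uniform); must sum to 1."""

    frac_lhs: float
    frac_levy: float

    @property
    def frac_uniform(self) -> float:
        return 1.0 - self.frac_lhs - self.frac_levy

    def __post_init__(self) -> None:
        if self.frac_lhs < 0 or self.frac_levy < 0 or self.frac_lhs + self.frac_levy > 1 + 1e-12:
            raise ValueError("fractions must be nonnegative and sum to at most 1")


def apportion(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n`` slots across ``fractions``."""
    quotas = [n * f for f in fractions]
    counts = [int(q) for q in quotas]
    short = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def lhs_sobol(n: int, bounds: Bounds, rng: np.random.Generator) -> np.ndarray:
    """Latin-Hypercube positions with scrambled-Sobol within-stratum offsets.

    Each dimension is partitioned into ``n`` equal strata with exactly one
    point per stratum; the offset inside each stratum comes from a scrambled
    Sobol stream rather than plain uniform draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d = bounds.dim
    sobol = qmc.Sobol(d=d, scramble=True, seed=rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-power-of-two draw is fine here
        offsets = sobol.random(n)
    strata = np.empty((n, d))
    for j in range(d):
        strata[:, j] = rng.permutation(n)
    unit = (strata + offsets) / n
    return bounds.lb + unit * bounds.range


def levy_centered(
    n: int,
    bounds: Bounds,
    levy: LevyParams,
    rng: np.random.Generator,
    scale_frac: float = DEFAULT_LEVY_SCALE,
) -> np.ndarray:
    """Positions at the domain midpoint plus Lévy steps, clamped to bounds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mid = (bounds.lb + bounds.ub) / 2.0
    steps = levy_sample(levy, n * bounds.dim, rng, size=(n, bounds.dim))
    return bounds.clamp(mid + scale_frac * bounds.range * steps)


def initial_positions(
    n: int,
    bounds: Bounds,
    category: str = "multimodal",
    rng: np.random.Generator | None = None,
    mix: InitMix | None = None,
    levy: LevyParams | None = None,
    levy_scale: float = DEFAULT_LEVY_SCALE,
) -> np.ndarray:
    """Draw ``n`` starting positions with the category's sampler mix.

    For ``n < 3`` the three-way split cannot be honoured, so the sampler
    degrades to plain uniform with a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    levy = LevyParams() if levy is None else levy
    if n < 3:
        warnings.warn("population too small for hybrid initialization; using uniform")
        return bounds.lb + rng.random((n, bounds.dim)) * bounds.range
    if mix is None:
        f_lhs, f_levy, _ = DEFAULT_MIX.get(category, DEFAULT_MIX["multimodal"])
        mix = InitMix(f_lhs, f_levy)
    n_lhs, n_levy, n_uni = apportion(n, (mix.frac_lhs, mix.frac_levy, mix.frac_uniform))
    # guarantee at least one point per strategy when N >= 3
    for _ in range(3):
        counts = [n_lhs, n_levy, n_uni]
        if min(counts) > 0:
            break
        lo, hi = counts.index(min(counts)), counts.index(max(counts))
        counts[lo] += 1
        counts[hi] -= 1
        n_lhs, n_levy, n_uni = counts
    parts = [
        lhs_sobol(n_lhs, bounds, rng),
        levy_centered(n_levy, bounds, levy, rng, scale_frac=levy_scale),
        bounds.lb + rng.random((n_uni, bounds.dim)) * bounds.range,
    ]
    return np.vstack(parts)
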