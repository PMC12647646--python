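"""Manta-ray foraging movement operators with chaotic/adaptive coefficients.

Three moves act on the population every iteration:

* **chain foraging** (non-elite): per-dimension crossover toward the
  current best, with a chaotic weight ``C_i`` and the amplification
  ``alpha = 2 C_i sqrt(|log(C_i + eps)|)``;
* **cyclone foraging** (elite, i.e. top third by rank): spiral contraction
  around a reference point (current best 80% of the time, a memory sample
  otherwise) with coefficient ``beta = 2 exp(C_i (1 - r_t)) sin(2 pi C_i)``;
* **somersault foraging** (everyone): pivot about the reference with a
  time-decaying somersault factor ``S``.

All schedules anneal with the iteration ratio ``r_t = t / T_max``.
Scalar coefficient functions are kept separate from the vectorised
population updates so they can be checked against high-precision oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .initialization import Bounds
from .kernels import LevyParams, levy_sample

__all__ = [
    "ForageContext",
    "crossover_rate",
    "alpha_coeff",
    "beta_coeff",
    "cyclone_probability",
    "somersault_factor",
    "chain_forage",
    "cyclone_forage",
    "somersault_forage",
]

EPS_LOG = 1e-10  # guards the logarithm in alpha_coeff as C_i -> 0+

#: multiplier applied to the somersault factor while stagnating
STAGNATION_S_BOOST = 1.5


@dataclass(frozen=True)
class ForageContext:
    """Per-iteration scalars shared by the operators."""

    r_t: float
    CR0: float = 0.9
    S0: float = 2.0
    N: int = 200
    stagnating: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_t <= 1.0:
            raise ValueError("iteration ratio must lie in [0, 1]")
        if not 0.0 < self.CR0 <= 1.0:
            raise ValueError("CR0 must lie in (0, 1]")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


def crossover_rate(cr0: float, r_t: float) -> float:
    """Annealed per-dimension crossover rate ``CR = CR0 (1 - 0.3 r_t)``."""
    return cr0 * (1.0 - 0.3 * r_t)


def alpha_coeff(c: float | np.ndarray) -> float | np.ndarray:
    """Chain-foraging amplification ``2 C sqrt(|log(C + eps)|)``."""
    c = np.asarray(c, dtype=float)
    out = 2.0 * c * np.sqrt(np.abs(np.log(c + EPS_LOG)))
    return float(out) if out.ndim == 0 else out


def beta_coeff(c: float | np.ndarray, r_t: float) -> float | np.ndarray:
    """Cyclone spiral coefficient ``2 exp(C (1 - r_t)) sin(2 pi C)``."""
    c = np.asarray(c, dtype=float)
    out = 2.0 * np.exp(c * (1.0 - r_t)) * np.sin(2.0 * np.pi * c)
    return float(out) if out.ndim == 0 else out


def cyclone_probability(base: float, i: int | np.ndarray, n: int, r_t: float) -> float | np.ndarray:
    """Rank- and time-modulated cyclone probability, clipped to [0, 1].

    ``base`` is the category's scalar cyclone probability; better-ranked
    individuals (small ``i``) and later iterations raise it.
    """
    p = base * (1.0 - 0.5 * np.asarray(i) / n) * (1.0 + 0.3 * r_t)
    out = np.clip(p, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def somersault_factor(s0: float, r_t: float, stagnating: bool = False) -> float:
    """Annealed somersault factor; boosted while the search stagnates."""
    s = s0 * (1.0 - 0.3 * r_t)
    if stagnating:
        s *= STAGNATION_S_BOOST
    return s


def chain_forage(
    x: np.ndarray,
    x_best: np.ndarray,
    c: np.ndarray,
    cr: float,
    bounds: Bounds,
    rng: np.random.Generator,
    levy: LevyParams | None = None,
    levy_prob: float = 0.1,
    levy_scale_frac: float = 0.05,
) -> np.ndarray:
    """Vectorised chain move for rows of ``x`` (one chaotic ``c`` per row).

    Each dimension updates only when a uniform draw falls below the
    crossover rate. On functions flagged hard, Lévy steps are injected
    into a small fraction of rows to force non-local jumps.
    """
    x = np.atleast_2d(x)
    c = np.atleast_1d(c)[:, None]
    diff = x_best[None, :] - x
    step = (c + alpha_coeff(c)) * diff
    mask = rng.random(x.shape) < cr
    out = np.where(mask, x + step, x)
    if levy is not None and levy_prob > 0:
        inject = rng.random(x.shape[0]) < levy_prob
        if np.any(inject):
            steps = levy_sample(levy, int(inject.sum()) * x.shape[1], rng,
                                size=(int(inject.sum()), x.shape[1]))
            out[inject] += levy_scale_frac * bounds.range * steps
    return bounds.clamp(out)


def cyclone_forage(
    x: np.ndarray,
    x_ref: np.ndarray,
    c: np.ndarray,
    r_t: float,
    bounds: Bounds,
) -> np.ndarray:
    """Vectorised cyclone move: contraction/spiral of each row around its
    reference row in ``x_ref`` (same shape as ``x`` or a single vector)."""
    x = np.atleast_2d(x)
    x_ref = np.broadcast_to(np.atleast_2d(x_ref), x.shape)
    c = np.atleast_1d(c)[:, None]
    coef = c + beta_coeff(c, r_t)
    return bounds.clamp(x_ref + coef * (x_ref - x))


def somersault_forage(
    x: np.ndarray,
    x_ref: np.ndarray,
    s: float,
    bounds: Bounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised somersault pivot ``x + S (r X_ref - (1 - r) x)``.

    ``r`` is one uniform scalar per individual, so at ``r = 0.5`` with
    ``x = X_ref`` the move cancels exactly.
    """
    x = np.atleast_2d(x)
    x_ref = np.broadcast_to(np.atleast_2d(x_ref), x.shape)
    r = rng.random((x.shape[0], 1))
    return bounds.clamp(x + s * (r * x_ref - (1.0 - r) * x))
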