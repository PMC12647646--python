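"""Chaotic map iterators and Lévy-flight sampling.

All stochastic modulation inside the optimizer is driven by two primitives:

* per-individual chaotic control variables ``C_i`` in ``[0.1, 0.9]``,
  produced by iterating a fully chaotic one-dimensional map (circle,
  logistic, or tent) and affinely rescaling its state, and
* heavy-tailed Lévy-flight steps with stability index ``beta`` (default
  1.5), generated with Mantegna's algorithm.

Chaotic trajectories replace pseudo-random control parameters: they are
deterministic, ergodic and aperiodic, which gives reproducible but
well-mixed modulation. Each individual in the population carries its own
:class:`ChaoticState`, advanced once per iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "MapKind",
    "ChaoticState",
    "LevyParams",
    "control_value",
    "advance_map",
    "step_chaotic",
    "step_chaotic_batch",
    "seed_chaotic_states",
    "levy_sample",
]

# Degenerate seeds where the canonical maps stop being chaotic: fixed
# points, absorbing orbits and (for the tent map) dyadic rationals that
# collapse to 0 in finitely many steps.
_DEGENERATE_Z = {
    "logistic": (0.0, 0.25, 0.5, 0.75, 1.0),
    "tent": (0.0, 0.25, 0.5, 0.75, 1.0),
    "circle": (),
}
_COLLAPSE_EPS = 1e-6


class MapKind(str, Enum):
    CIRCLE = "circle"
    LOGISTIC = "logistic"
    TENT = "tent"


@dataclass(frozen=True)
class ChaoticState:
    """State of one chaotic control stream.

    ``z`` is the raw map state in (0, 1); ``C`` is the rescaled control
    value ``0.1 + 0.8 z`` in [0.1, 0.9] used by the foraging operators.
    """

    map_kind: MapKind
    z: float

    @property
    def C(self) -> float:
        return control_value(self.z)


@dataclass(frozen=True)
class LevyParams:
    """Stable-law step parameters: index ``beta`` in (1, 2], step ``scale``."""

    beta: float = 1.5
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not 1.0 < self.beta <= 2.0:
            raise ValueError(f"Lévy stability index must be in (1, 2], got {self.beta}")
        if self.scale <= 0:
            raise ValueError(f"Lévy scale must be positive, got {self.scale}")


def control_value(z: float | np.ndarray) -> float | np.ndarray:
    """Affine rescale of a map state in [0, 1] to the control range [0.1, 0.9]."""
    return 0.1 + 0.8 * np.asarray(z) if isinstance(z, np.ndarray) else 0.1 + 0.8 * z


def _advance(map_kind: MapKind, z: np.ndarray) -> np.ndarray:
    if map_kind == MapKind.CIRCLE:
        # Circle map with K chosen in the chaotic regime; mod 1 keeps z in [0,1).
        return np.mod(z + 0.2 - (0.5 / (2.0 * np.pi)) * np.sin(2.0 * np.pi * z), 1.0)
    if map_kind == MapKind.LOGISTIC:
        return 4.0 * z * (1.0 - z)
    if map_kind == MapKind.TENT:
        return np.where(z < 0.5, 2.0 * z, 2.0 * (1.0 - z))
    raise ValueError(f"unknown chaotic map {map_kind!r}")


def advance_map(map_kind: MapKind, z: float | np.ndarray) -> float | np.ndarray:
    """One raw map iteration without state validation (edge values allowed)."""
    out = _advance(map_kind, np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def _fresh_z(map_kind: MapKind, rng: np.random.Generator) -> float:
    """Draw a non-degenerate seed on (0.05, 0.95)."""
    bad = _DEGENERATE_Z[MapKind(map_kind).value]
    while True:
        z = float(rng.uniform(0.05, 0.95))
        if all(abs(z - b) > 1e-3 for b in bad):
            return z


def step_chaotic(state: ChaoticState, rng: np.random.Generator | None = None) -> ChaoticState:
    """Advance one map iteration, reseeding on numerical collapse.

    The update is deterministic except when ``z`` has collapsed onto the
    boundary (within ``1e-6`` of 0 or 1), where the logistic and tent maps
    absorb; then a fresh seed is drawn from ``rng`` (required in that case).
    """
    if not 0.0 < state.z < 1.0:
        raise ValueError(f"chaotic state z must lie in (0, 1), got {state.z}")
    z = float(_advance(state.map_kind, np.float64(state.z)))
    if z < _COLLAPSE_EPS or z > 1.0 - _COLLAPSE_EPS:
        if rng is None:
            raise ValueError("chaotic trajectory collapsed and no rng given to reseed")
        z = _fresh_z(state.map_kind, rng)
    return replace(state, z=z)


def step_chaotic_batch(
    map_kind: MapKind, z: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised map step for a whole population's states, with reseeding."""
    z = _advance(map_kind, z)
    collapsed = (z < _COLLAPSE_EPS) | (z > 1.0 - _COLLAPSE_EPS)
    if np.any(collapsed):
        z = z.copy()
        z[collapsed] = [_fresh_z(map_kind, rng) for _ in range(int(collapsed.sum()))]
    return z


def seed_chaotic_states(
    map_kind: MapKind, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent non-degenerate initial map states."""
    return np.array([_fresh_z(map_kind, rng) for _ in range(n)])


def _mantegna_sigma(beta: float) -> float:
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_sample(
    params: LevyParams,
    count: int,
    rng: np.random.Generator,
    size: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Symmetric heavy-tailed steps via Mantegna's algorithm.

    ``step = scale * u / |v|**(1/beta)`` with ``u ~ N(0, sigma_u^2)`` and
    ``v ~ N(0, 1)``; ``sigma_u`` is chosen so the steps follow a stable law
    of index ``beta``. ``size`` overrides the flat ``count`` shape.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    shape: tuple[int, ...] = size if size is not None else (count,)
    sigma = _mantegna_sigma(params.beta)
    u = rng.normal(0.0, sigma, size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    v = np.where(np.abs(v) < 1e-300, 1e-300, v)
    return params.scale * u / np.abs(v) ** (1.0 / params.beta)
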