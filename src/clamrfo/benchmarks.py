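"""Shifted/rotated benchmark functions and the original MRFO baseline.

Test instances follow the classic suite construction ``f(x) = base(M (x -
o)) + bias`` with a seeded random orthogonal rotation ``M`` (QR of a
Gaussian matrix) and a shift ``o`` drawn uniformly in ``[-80, 80]^D`` so
the optimum stays inside the ``[-100, 100]^D`` domain.  Hybrid and
composition exemplars are weighted sums of three shifted/rotated bases.
Official competition shift/rotation data files can be supplied instead of
the self-generated ones.

The baseline optimizer is the original manta-ray algorithm (chain /
cyclone / somersault with canonical coefficients and a fixed somersault
factor of 2), with no chaotic control, memory, local search or restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import OptimizerConfig, Objective, RunRecord, _config_dict, iteration_ratio
from .initialization import Bounds

__all__ = [
    "BenchmarkFunction",
    "make_function",
    "default_suite",
    "mrfo_baseline_optimize",
    "success_rate",
]


# -- base forms (vectorised over rows) ------------------------------------

def _sphere(z):
    return np.sum(z * z, axis=-1)


def _bent_cigar(z):
    return z[..., 0] ** 2 + 1e6 * np.sum(z[..., 1:] ** 2, axis=-1)


def _rastrigin(z):
    return np.sum(z * z - 10.0 * np.cos(2.0 * np.pi * z) + 10.0, axis=-1)


def _rosenbrock(z):
    # shifted so the optimum sits at z = 0
    w = z + 1.0
    return np.sum(100.0 * (w[..., 1:] - w[..., :-1] ** 2) ** 2 + (w[..., :-1] - 1.0) ** 2, axis=-1)


def _ackley(z):
    d = z.shape[-1]
    a = -20.0 * np.exp(-0.2 * np.sqrt(np.sum(z * z, axis=-1) / d))
    b = -np.exp(np.sum(np.cos(2.0 * np.pi * z), axis=-1) / d)
    return a + b + 20.0 + np.e


def _griewank(z):
    d = z.shape[-1]
    idx = np.sqrt(np.arange(1, d + 1))
    return 1.0 + np.sum(z * z, axis=-1) / 4000.0 - np.prod(np.cos(z / idx), axis=-1)


BASES: dict[str, Callable] = {
    "sphere": _sphere,
    "bent_cigar": _bent_cigar,
    "rastrigin": _rastrigin,
    "rosenbrock": _rosenbrock,
    "ackley": _ackley,
    "griewank": _griewank,
}

_CATEGORY_OF_BASE = {
    "sphere": "unimodal",
    "bent_cigar": "unimodal",
    "rastrigin": "multimodal",
    "rosenbrock": "multimodal",
    "ackley": "multimodal",
    "griewank": "multimodal",
}


def random_rotation(d: int, rng: np.random.Generator) -> np.ndarray:
    """Random orthogonal matrix from the QR decomposition of a Gaussian."""
    q, r = np.linalg.qr(rng.normal(size=(d, d)))
    return q * np.sign(np.diag(r))


@dataclass
class BenchmarkFunction:
    """A shifted/rotated instance ``f(x) = base(M (x - o)) + bias``."""

    name: str
    base: Callable
    shift: np.ndarray
    rotation: np.ndarray
    bias: float
    category: str
    deceptive: bool = False
    hard: bool = False
    bounds: Bounds = None
    components: list = field(default_factory=list)  # (weight, BenchmarkFunction)
    supports_batch: bool = True

    def __post_init__(self) -> None:
        m = self.rotation
        if not np.allclose(m @ m.T, np.eye(m.shape[0]), atol=1e-10):
            raise ValueError("rotation matrix must be orthogonal (M M^T = I to 1e-10)")

    @property
    def dim(self) -> int:
        return self.shift.size

    def __call__(self, x: np.ndarray) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        x2 = np.atleast_2d(x)
        if self.components:
            vals = sum(w * g.raw(x2) for w, g in self.components) + self.bias
        else:
            vals = self.raw(x2) + self.bias
        return float(vals[0]) if scalar else vals

    def raw(self, x2: np.ndarray) -> np.ndarray:
        z = (x2 - self.shift) @ self.rotation.T
        return self.base(z)

    def error(self, x: np.ndarray) -> np.ndarray | float:
        return self(x) - self.bias


def make_function(
    base: str,
    dim: int,
    seed: int | None = None,
    shift: np.ndarray | None = None,
    rotation: np.ndarray | None = None,
    bias: float = 0.0,
    category: str | None = None,
    deceptive: bool = False,
    hard: bool = False,
    domain: tuple[float, float] = (-100.0, 100.0),
) -> BenchmarkFunction:
    """Build a shifted/rotated instance of a registered base function.

    ``base`` may also be ``"hybrid"`` or ``"composition"``, which combine
    three shifted/rotated bases with fixed mixture weights.  Supplied
    ``shift``/``rotation`` arrays (e.g. from official data files) replace
    the self-generated ones.
    """
    rng = np.random.default_rng(seed)
    bounds = Bounds.cube(domain[0], domain[1], dim)
    if base in ("hybrid", "composition"):
        parts, weights = [], np.array([0.5, 0.3, 0.2])
        part_bases = (
            ("sphere", "rastrigin", "rosenbrock")
            if base == "hybrid"
            else ("rastrigin", "ackley", "griewank")
        )
        for pb in part_bases:
            parts.append(
                make_function(pb, dim, seed=int(rng.integers(2**31)), domain=domain)
            )
        o = parts[0].shift  # common optimum: first component's shift
        for p in parts[1:]:
            p.shift = o.copy()
        fn = BenchmarkFunction(
            name=base, base=_sphere, shift=o, rotation=np.eye(dim), bias=bias,
            category=category or base, deceptive=deceptive, hard=hard, bounds=bounds,
            components=[(w, p) for w, p in zip(weights, parts)],
        )
        return fn
    if base not in BASES:
        raise ValueError(f"unknown base function {base!r}; choose from {sorted(BASES)}")
    if shift is None:
        shift = rng.uniform(-80.0, 80.0, size=dim)
    if rotation is None:
        rotation = random_rotation(dim, rng)
    return BenchmarkFunction(
        name=base,
        base=BASES[base],
        shift=np.asarray(shift, dtype=float),
        rotation=np.asarray(rotation, dtype=float),
        bias=bias,
        category=category or _CATEGORY_OF_BASE[base],
        deceptive=deceptive,
        hard=hard,
        bounds=bounds,
    )


def default_suite(dim: int = 10, seed: int = 2017) -> list[BenchmarkFunction]:
    """A small category-spanning suite of self-generated instances."""
    rng = np.random.default_rng(seed)
    specs = [
        ("sphere", {}),
        ("bent_cigar", {}),
        ("rastrigin", {}),
        ("ackley", {}),
        ("rosenbrock", {"hard": True}),
        ("griewank", {}),
        ("hybrid", {}),
        ("composition", {"deceptive": True}),
    ]
    return [
        make_function(b, dim, seed=int(rng.integers(2**31)), **kw) for b, kw in specs
    ]


def success_rate(errors: np.ndarray, threshold: float = 1e-2) -> float:
    """Fraction of runs with final error at or below the threshold."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("success_rate of an empty error vector is undefined")
    if not np.all(np.isfinite(errors)):
        raise ValueError("errors must be finite")
    return float(np.mean(errors <= threshold))


# -- original MRFO baseline ------------------------------------------------

SOMERSAULT_FACTOR_CANONICAL = 2.0


def mrfo_baseline_optimize(
    f: Callable,
    bounds: Bounds,
    config: OptimizerConfig | None = None,
    seed: int | None = None,
    batch: bool | None = None,
) -> RunRecord:
    """Original manta-ray foraging optimization (no adaptive components).

    Chain and cyclone foraging with their canonical random coefficients
    (``alpha = 2 r sqrt(|log r|)``, ``beta = 2 exp(r1 (T - t + 1)/T)
    sin(2 pi r1)``), somersault with fixed factor 2, uniform random
    initialization, and best-so-far elitism in the trace.
    """
    cfg = OptimizerConfig() if config is None else config
    rng = np.random.default_rng(seed)
    obj = Objective(f, batch=batch)
    n, d = cfg.n, bounds.dim
    t_max = cfg.t_max

    x = bounds.lb + rng.random((n, d)) * bounds.range
    fit = obj.many(x)
    i_best = int(np.argmin(fit))
    best_x, best_f = x[i_best].copy(), float(fit[i_best])
    trace = [best_f - cfg.f_star]

    t = 0
    for t in range(1, t_max + 1):
        coin = rng.random(n) < 0.5  # chain vs cyclone per individual
        r = rng.random((n, d))
        prev = np.vstack([best_x, x[:-1]])  # predecessor in the chain
        new = np.empty_like(x)

        alpha = 2.0 * r * np.sqrt(np.abs(np.log(r + 1e-300)))
        chain = x + r * (prev - x) + alpha * (best_x - x)

        r1 = rng.random((n, 1))
        beta = 2.0 * np.exp(r1 * (t_max - t + 1) / t_max) * np.sin(2.0 * np.pi * r1)
        if iteration_ratio(t, t_max) < rng.random():
            x_rand = bounds.lb + rng.random((1, d)) * bounds.range
            ref = x_rand
        else:
            ref = best_x[None, :]
        cyclone = ref + r * (prev - x) + beta * (ref - x)

        new[coin] = chain[coin]
        new[~coin] = cyclone[~coin]
        x = bounds.clamp(new)
        fit = obj.many(x)
        i = int(np.argmin(fit))
        if fit[i] < best_f:
            best_f, best_x = float(fit[i]), x[i].copy()

        r2 = rng.random((n, 1))
        r3 = rng.random((n, 1))
        x = bounds.clamp(x + SOMERSAULT_FACTOR_CANONICAL * (r2 * best_x - r3 * x))
        fit = obj.many(x)
        i = int(np.argmin(fit))
        if fit[i] < best_f:
            best_f, best_x = float(fit[i]), x[i].copy()

        trace.append(best_f - cfg.f_star)
        if cfg.target_error is not None and trace[-1] <= cfg.target_error:
            break

    errors = np.array(trace)
    conv = np.nonzero(errors <= cfg.convergence_threshold)[0]
    return RunRecord(
        best_position=best_x,
        best_fitness=best_f,
        error_trace=errors,
        convergence_iteration=int(conv[0]) if conv.size else None,
        success=bool(errors[-1] <= cfg.success_threshold),
        restarts=[],
        evaluations=obj.evaluations,
        iterations_run=t,
        seed=seed,
        config={**_config_dict(cfg), "algorithm": "mrfo_baseline", "somersault_factor": 2.0},
    )
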