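"""Synthetic two-class expression data for exercising the selection pipeline.

Emulates the high-dimensional low-sample-size design of a two-class
leukemia microarray study: 72 samples split 47/25 between classes, with a
small set of truly informative genes shifted between classes by a stated
effect size (in within-class SD units) on a log-expression scale.  Noise
genes are standard Gaussians (optionally heavy-tailed Student-t), and
informative genes can be correlated in a block through a shared latent
factor.  The generator returns the ground-truth informative indices so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_selection import FSProblem

__all__ = ["SynthSpec", "make_dataset", "make_easy_preset", "make_hard_preset"]


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters; defaults mirror the motivating 72-sample study."""

    n_samples: int = 72
    class_counts: tuple[int, int] = (47, 25)
    p_genes: int = 100
    k_informative: int = 5
    effect: float = 2.0
    correlation: float = 0.0
    noise_df: float | None = None  # Student-t degrees of freedom; None = Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.p_genes:
            raise ValueError("k_informative must not exceed p_genes")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if sum(self.class_counts) != self.n_samples:
            raise ValueError("class counts must sum to n_samples")


def make_dataset(spec: SynthSpec) -> tuple[FSProblem, np.ndarray]:
    """Generate one dataset; returns the problem and informative indices.

    Informative genes get a mean shift of ``effect`` (in units of the
    within-class SD, which is 1 by construction) in the second class, and
    share a latent factor with loading ``sqrt(correlation)`` when block
    correlation is requested.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_samples, spec.p_genes, spec.k_informative
    if spec.noise_df is not None:
        df = spec.noise_df
        if df <= 2:
            raise ValueError("noise_df must exceed 2 so the variance is finite")
        X = rng.standard_t(df, size=(n, p)) / np.sqrt(df / (df - 2.0))
    else:
        X = rng.normal(size=(n, p))
    informative = rng.choice(p, size=k, replace=False)
    informative.sort()
    if spec.correlation > 0 and k > 1:
        lam = np.sqrt(spec.correlation)
        factor = rng.normal(size=n)
        X[:, informative] = (
            lam * factor[:, None] + np.sqrt(1.0 - spec.correlation) * X[:, informative]
        )
    y = np.concatenate(
        [np.zeros(spec.class_counts[0], dtype=int), np.ones(spec.class_counts[1], dtype=int)]
    )
    X[np.ix_(y == 1, informative)] += spec.effect
    perm = rng.permutation(n)
    names = np.array([f"gene_{j:05d}" for j in range(p)])
    return FSProblem(X[perm], y[perm], names), informative


def make_easy_preset(seed: int = 0, p_genes: int = 100) -> SynthSpec:
    """Well-separated classes: effect 3.0, independent genes."""
    return SynthSpec(effect=3.0, correlation=0.0, p_genes=p_genes, seed=seed)


def make_hard_preset(seed: int = 0, p_genes: int = 100) -> SynthSpec:
    """Weak, correlated, heavy-tailed signal: effect 1.0, rho 0.6, t(3) noise."""
    return SynthSpec(effect=1.0, correlation=0.6, noise_df=3.0, p_genes=p_genes, seed=seed)
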