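"""Nonparametric algorithm-comparison statistics.

Friedman rank test over an algorithms-by-problems matrix of mean errors,
the Nemenyi critical difference for post-hoc pairwise rank comparisons,
and the Wilcoxon signed-rank test for paired algorithm results (exact
null distribution by sign-pattern enumeration for small samples, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps

__all__ = ["FriedmanResult", "friedman_test", "nemenyi_cd", "wilcoxon_signed_rank"]

EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class FriedmanResult:
    mean_ranks: np.ndarray  # per algorithm; rank 1 = lowest mean error
    statistic: float
    df: int
    pvalue: float
    n_problems: int


def friedman_test(errors: np.ndarray) -> FriedmanResult:
    """Friedman test on a problems x algorithms matrix of mean errors.

    Each row is ranked (rank 1 for the lowest error, average ranks on
    ties); rows containing NaN are dropped with a warning.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.ndim != 2 or errors.shape[0] < 2 or errors.shape[1] < 2:
        raise ValueError("need a problems x algorithms matrix with at least 2 of each")
    keep = ~np.isnan(errors).any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} problem row(s) with NaN entries")
        errors = errors[keep]
    n, k = errors.shape
    if n < 2:
        raise ValueError("fewer than 2 usable problem rows")
    ranks = np.apply_along_axis(sps.rankdata, 1, errors)
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * (np.sum(mean_ranks**2) - k * (k + 1) ** 2 / 4.0)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return FriedmanResult(mean_ranks, float(chi2), df, p, n)


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference ``q_alpha sqrt(k (k + 1) / (6 n))``.

    ``q_alpha`` is the studentized-range quantile at infinite degrees of
    freedom divided by sqrt(2). Mean-rank differences above the CD are
    significant at level ``alpha``.
    """
    if alpha not in (0.05, 0.10):
        raise ValueError("alpha must be 0.05 or 0.10")
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 algorithms and n >= 1 problems")
    q = sps.studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n)))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns ``(W, p)`` where ``W`` is the smaller of the positive and
    negative rank sums. Zero differences are dropped. The p-value is
    exact (enumeration of all sign patterns over the observed ranks) for
    up to 12 nonzero pairs, and a tie-corrected normal approximation
    beyond that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    if n <= EXACT_WILCOXON_MAX_N:
        # exact two-sided p over all 2^n assignments of signs to the ranks
        count = 0
        total = 2**n
        for signs in product((0, 1), repeat=n):
            wp = sum(r for r, s in zip(ranks, signs) if s)
            wn = ranks.sum() - wp
            if min(wp, wn) <= w + 1e-12:
                count += 1
        p = count / total
    else:
        mean = n * (n + 1) / 4.0
        tie_term = _tie_correction(ranks)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w - mean + 0.5) / np.sqrt(var)  # continuity-corrected
        p = float(2.0 * sps.norm.cdf(z))
    return w, min(p, 1.0)


def _tie_correction(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts) / 48.0)
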