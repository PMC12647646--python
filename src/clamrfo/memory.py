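"""Three-bank elite archive (short-term / diversity / long-term).

The archive keeps a bounded history of good solutions (total capacity 15,
split equally):

* the **short-term** bank holds recently found high-quality solutions and
  prefers evicting stale entries;
* the **diversity** bank holds mutually distant solutions — a candidate is
  admitted only if its minimum distance to stored members exceeds half of
  their minimum pairwise distance;
* the **long-term** bank preserves the best solutions seen in the run.

Quality banks accept a candidate when not full, or when it improves the
bank's worst stored fitness by at least 10% (relative, scale-safe).
Retrieval mixes the banks 70/20/10 (short/long/diversity) with a
softmax-over-rank preference for better fitness inside each bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

__all__ = ["MemoryBanks", "InsertReport"]

IMPROVE_FRAC = 0.10
DIVERSITY_DIST_FRAC = 0.5
REL_EPS = 1e-12


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def hamming_binarized(a: np.ndarray, b: np.ndarray, threshold: float = 0.5) -> float:
    """Hamming distance between binarized positions (for feature-mask mode)."""
    return float(np.sum((a > threshold) != (b > threshold)))


def relative_improvement(f_worst: float, f_new: float) -> float:
    """Scale-safe relative improvement of ``f_new`` over ``f_worst``
    (minimization; positive means better)."""
    return (f_worst - f_new) / (abs(f_worst) + REL_EPS)


@dataclass
class InsertReport:
    short_term: bool = False
    diversity: bool = False
    long_term: bool = False

    @property
    def any(self) -> bool:
        return self.short_term or self.diversity or self.long_term


@dataclass(eq=False)  # identity comparison so list.remove works with array fields
class _Entry:
    position: np.ndarray
    fitness: float
    born: int  # iteration of insertion, for staleness


@dataclass
class MemoryBanks:
    """Bounded three-bank archive with quantitative insertion rules."""

    capacity_total: int = 15
    staleness: int = 50
    bank_weights: tuple[float, float, float] = (0.7, 0.2, 0.1)  # short/long/diversity
    distance: Callable[[np.ndarray, np.ndarray], float] = euclidean
    short_term: list[_Entry] = field(default_factory=list)
    diversity: list[_Entry] = field(default_factory=list)
    long_term: list[_Entry] = field(default_factory=list)

    @property
    def capacity_per_bank(self) -> int:
        return self.capacity_total // 3

    def __len__(self) -> int:
        return len(self.short_term) + len(self.diversity) + len(self.long_term)

    # -- insertion ---------------------------------------------------------

    def try_insert(
        self, position: np.ndarray, fitness: float, iteration: int = 0
    ) -> InsertReport:
        """Offer a candidate to all three banks; report which accepted."""
        report = InsertReport()
        if not np.isfinite(fitness):
            return report
        position = np.array(position, dtype=float, copy=True)
        cap = self.capacity_per_bank
        report.short_term = self._insert_quality(
            self.short_term, position, fitness, iteration, cap, prefer_stale=True
        )
        report.long_term = self._insert_quality(
            self.long_term, position, fitness, iteration, cap, prefer_stale=False
        )
        report.diversity = self._insert_diverse(position, fitness, iteration, cap)
        return report

    def _insert_quality(
        self,
        bank: list[_Entry],
        position: np.ndarray,
        fitness: float,
        iteration: int,
        cap: int,
        prefer_stale: bool,
    ) -> bool:
        if len(bank) < cap:
            bank.append(_Entry(position, fitness, iteration))
            return True
        if prefer_stale:
            stale = [e for e in bank if iteration - e.born > self.staleness]
            if stale:
                victim = max(stale, key=lambda e: e.fitness)
                if fitness < victim.fitness:  # still must not degrade the bank
                    bank.remove(victim)
                    bank.append(_Entry(position, fitness, iteration))
                    return True
        victim = max(bank, key=lambda e: e.fitness)
        if relative_improvement(victim.fitness, fitness) >= IMPROVE_FRAC:
            bank.remove(victim)
            bank.append(_Entry(position, fitness, iteration))
            return True
        return False

    def _insert_diverse(
        self, position: np.ndarray, fitness: float, iteration: int, cap: int
    ) -> bool:
        bank = self.diversity
        if len(bank) < 2:
            # need two members before pairwise distances are defined
            if any(self.distance(position, e.position) == 0.0 for e in bank):
                return False
            bank.append(_Entry(position, fitness, iteration))
            return True
        d_min_new = min(self.distance(position, e.position) for e in bank)
        pairwise = [
            self.distance(bank[i].position, bank[j].position)
            for i in range(len(bank))
            for j in range(i + 1, len(bank))
        ]
        if d_min_new <= DIVERSITY_DIST_FRAC * min(pairwise):
            return False
        if len(bank) >= cap:
            # evict the member closest to the rest, keeping the bank spread out
            crowding = [
                min(self.distance(e.position, o.position) for o in bank if o is not e)
                for e in bank
            ]
            bank.pop(int(np.argmin(crowding)))
        bank.append(_Entry(position, fitness, iteration))
        return True

    # -- retrieval ---------------------------------------------------------

    def sample_reference(self, rng: np.random.Generator) -> np.ndarray | None:
        """Draw a stored position, favouring better fitness; ``None`` if empty."""
        banks = [self.short_term, self.long_term, self.diversity]
        weights = np.array(self.bank_weights, dtype=float)
        avail = np.array([len(b) > 0 for b in banks])
        if not avail.any():
            return None
        weights = np.where(avail, weights, 0.0)
        weights /= weights.sum()
        bank = banks[int(rng.choice(3, p=weights))]
        order = np.argsort([e.fitness for e in bank])  # rank 0 = best
        ranks = np.empty(len(bank))
        ranks[order] = np.arange(len(bank))
        p = np.exp(-ranks)
        p /= p.sum()
        return bank[int(rng.choice(len(bank), p=p))].position.copy()

    def best(self) -> tuple[np.ndarray, float] | None:
        entries = self.short_term + self.long_term + self.diversity
        if not entries:
            return None
        e = min(entries, key=lambda e: e.fitness)
        return e.position.copy(), e.fitness
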