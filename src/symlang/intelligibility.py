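"""Maximum-intelligibility arrangement of symbol cells (MaxIntel).

Symbols that are adjacent in probabilistic rank are the most easily
confused, so intelligibility is improved by placing them far apart in the
input space — the same idea that spreads frequently co-used keys across a
QWERTY keyboard.  The objective maximized here is the probability-weighted
sum of squared spatial distances between consecutively ranked symbols,

    lambda_c = sum_{r=1}^{M-1} psi_r * (pos(r) - pos(r+1))^2,

where pos(r) is the spatial cell index assigned to rank r and psi_r is by
default the ZML probability of rank r.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .zml import ZMLDistribution

__all__ = [
    "IntelligibilityScore",
    "intelligibility_score",
    "brute_force_arrange",
    "maxintel_arrange",
    "intelligibility_curve",
]

_BRUTE_FORCE_LIMIT = 9
_EXACT_LIMIT = 8


@dataclass(frozen=True)
class IntelligibilityScore:
    """An arrangement pos(r): rank -> spatial cell, with its lambda_c score."""

    arrangement: tuple[int, ...]
    score: float
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        M = len(self.arrangement)
        if sorted(self.arrangement) != list(range(1, M + 1)):
            raise ValueError("arrangement must be a bijection on 1..M")
        if self.score < 0:
            raise ValueError("score must be non-negative")
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


def _weights(dist: ZMLDistribution, psi) -> np.ndarray:
    if psi is None:
        return dist.probs
    psi = np.asarray(psi, dtype=float)
    if psi.shape != (dist.alphabet_size,):
        raise ValueError("psi must have one weight per rank")
    return psi


def intelligibility_score(arrangement, dist: ZMLDistribution, psi=None) -> float:
    """lambda_c of an arrangement: sum of psi_r * (pos(r) - pos(r+1))^2."""
    pos = np.asarray(arrangement, dtype=int)
    M = dist.alphabet_size
    if sorted(pos.tolist()) != list(range(1, M + 1)):
        raise ValueError("arrangement must be a permutation of 1..M")
    if M == 1:
        return 0.0
    w = _weights(dist, psi)
    jumps = np.diff(pos).astype(float)
    return float(np.sum(w[:-1] * jumps**2))


def brute_force_arrange(dist: ZMLDistribution, psi=None) -> IntelligibilityScore:
    """Exact global maximizer by exhaustive enumeration (M <= 9 only).

    Ties are broken by the lexicographically smallest permutation, which is
    the first one reached when enumerating in lexicographic order.
    """
    M = dist.alphabet_size
    if M > _BRUTE_FORCE_LIMIT:
        raise ValueError(f"brute force refused for M={M} > {_BRUTE_FORCE_LIMIT} (M! too large)")
    w = _weights(dist, psi)
    best_perm, best_score = None, -1.0
    for perm in itertools.permutations(range(1, M + 1)):
        jumps = np.diff(perm).astype(float)
        s = float(np.sum(w[:-1] * jumps**2)) if M > 1 else 0.0
        if s > best_score:
            best_perm, best_score = perm, s
    return IntelligibilityScore(best_perm, best_score, w)


def _interleave_seed(M: int) -> list[int]:
    # rank 1 -> leftmost cell, rank 2 -> rightmost, rank 3 -> second cell, ...
    pos, lo, hi = [], 1, M
    for r in range(M):
        if r % 2 == 0:
            pos.append(lo)
            lo += 1
        else:
            pos.append(hi)
            hi -= 1
    return pos


def maxintel_arrange(dist: ZMLDistribution, psi=None) -> IntelligibilityScore:
    """Arrangement maximizing lambda_c.

    Exhaustive search for M <= 8 (exact optimum, lexicographic tie-break).
    For larger alphabets: a deterministic end-interleaving seed (ranks placed
    alternately from the two ends of the spatial axis, most probable first)
    refined by best-improvement pairwise-swap hill climbing; the result is
    guaranteed at least as good as the identity arrangement.
    """
    M = dist.alphabet_size
    if M <= _EXACT_LIMIT:
        return brute_force_arrange(dist, psi)
    w = _weights(dist, psi)

    def score(pos: list[int]) -> float:
        jumps = np.diff(pos).astype(float)
        return float(np.sum(w[:-1] * jumps**2))

    pos = _interleave_seed(M)
    best = score(pos)
    improved = True
    while improved:
        improved = False
        best_swap, best_gain = None, 0.0
        for i in range(M):
            for j in range(i + 1, M):
                pos[i], pos[j] = pos[j], pos[i]
                gain = score(pos) - best
                pos[i], pos[j] = pos[j], pos[i]
                if gain > best_gain + 1e-15:
                    best_swap, best_gain = (i, j), gain
        if best_swap is not None:
            i, j = best_swap
            pos[i], pos[j] = pos[j], pos[i]
            best += best_gain
            improved = True
    identity = list(range(1, M + 1))
    if score(identity) > best:  # cannot happen for decreasing psi, but keep the guarantee total
        pos, best = identity, score(identity)
    return IntelligibilityScore(tuple(pos), best, w)


def intelligibility_curve(dist: ZMLDistribution, psi=None):
    """Per-rank intelligibility for the identity and optimized arrangements.

    Rank r < M contributes psi_r * (pos(r) - pos(r+1))^2; the last rank
    repeats its predecessor's term so both curves have length M.  Returns
    ``(identity_curve, optimized_curve)``.
    """
    M = dist.alphabet_size
    if M < 2:
        raise ValueError("intelligibility_curve requires M >= 2")
    w = _weights(dist, psi)

    def curve(pos) -> np.ndarray:
        terms = w[:-1] * np.diff(np.asarray(pos, dtype=float)) ** 2
        return np.concatenate((terms, terms[-1:]))

    identity = np.arange(1, M + 1)
    optimized = maxintel_arrange(dist, psi).arrangement
    return curve(identity), curve(optimized)
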