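"""Zipf-Mandelbrot-Li (ZML) rank-probability model.

The ZML law is the closed-form rank-frequency distribution that emerges from
Li's random-typing analysis: a monkey hitting M letter keys and one space key
uniformly at random produces "words" whose rank-frequency curve follows a
shifted power law

    p(r)  proportional to  (r + beta)^(-alpha),
    alpha = log(M + 1) / log(M),   beta = M / (M + 1).

For a finite symbol alphabet of size M the law is normalized over ranks
1..M by explicit summation (:func:`zml_probabilities`); this is the target
distribution used by every symbolization and learning routine in this
package.  For the unbounded word vocabulary of a random-typing source the
same shifted power law is normalized over all ranks r >= 1 with the Hurwitz
zeta function (:func:`zml_word_law`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import zeta

__all__ = [
    "ZMLDistribution",
    "zml_probabilities",
    "zml_word_law",
    "zml_entropy",
    "rank_divergence",
]


@dataclass(frozen=True)
class ZMLDistribution:
    """Ranked ZML probability vector for a finite alphabet.

    Attributes
    ----------
    alphabet_size : int
        Number of symbols M; probabilities are indexed by rank r = 1..M.
    exponent : float
        ZML exponent alpha = log(M+1)/log(M) (1.0 for the degenerate M=1).
    offset : float
        Mandelbrot shift beta = M/(M+1).
    probs : numpy.ndarray
        Strictly decreasing probabilities summing to 1.
    """

    alphabet_size: int
    exponent: float
    offset: float
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        if p.shape != (self.alphabet_size,):
            raise ValueError("probs length must equal alphabet_size")
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("probs must sum to 1 within 1e-12")
        if np.any(p <= 0):
            raise ValueError("all probabilities must be strictly positive")
        if self.alphabet_size >= 2 and not np.all(np.diff(p) < 0):
            raise ValueError("probs must be strictly decreasing in rank")

    def to_json(self) -> str:
        return json.dumps(
            {
                "M": self.alphabet_size,
                "exponent": self.exponent,
                "offset": self.offset,
                "probs": self.probs.tolist(),
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "ZMLDistribution":
        d = json.loads(doc)
        return cls(
            alphabet_size=d["M"],
            exponent=d["exponent"],
            offset=d["offset"],
            probs=np.asarray(d["probs"], dtype=float),
        )


def zml_probabilities(alphabet_size: int) -> ZMLDistribution:
    """Ranked ZML probabilities for a finite alphabet of ``alphabet_size``.

    p(r) = (r + beta)^(-alpha) / sum_{k=1}^{M} (k + beta)^(-alpha)
    with alpha = log(M+1)/log(M) and beta = M/(M+1).  Deterministic for a
    given M; the single-symbol case returns [1.0].
    """
    M = int(alphabet_size)
    if M < 1:
        raise ValueError(f"alphabet_size must be >= 1, got {alphabet_size}")
    if M == 1:
        # alpha is undefined at M=1 (log 1 = 0); the distribution is the
        # degenerate point mass regardless of exponent.
        return ZMLDistribution(1, 1.0, 0.5, np.array([1.0]))
    alpha = math.log(M + 1) / math.log(M)
    beta = M / (M + 1)
    r = np.arange(1, M + 1, dtype=float)
    w = (r + beta) ** (-alpha)
    return ZMLDistribution(M, alpha, beta, w / w.sum())


def zml_word_law(alphabet_size: int, n_ranks: int) -> np.ndarray:
    """First ``n_ranks`` probabilities of the unbounded-vocabulary ZML law.

    For a random-typing source with M letters the word vocabulary is
    countably infinite; the law is normalized over all ranks r >= 1 via the
    Hurwitz zeta function: sum_{r>=1} (r+beta)^(-alpha) = zeta(alpha, 1+beta)
    (convergent because alpha > 1 for M >= 2).
    """
    M = int(alphabet_size)
    if M < 2:
        raise ValueError("the unbounded word law requires alphabet_size >= 2")
    if n_ranks < 1:
        raise ValueError("n_ranks must be >= 1")
    alpha = math.log(M + 1) / math.log(M)
    beta = M / (M + 1)
    r = np.arange(1, n_ranks + 1, dtype=float)
    return (r + beta) ** (-alpha) / zeta(alpha, 1.0 + beta)


def zml_entropy(dist: ZMLDistribution) -> float:
    """Shannon entropy -sum p(r) log2 p(r) of the ranked distribution, in bits."""
    p = dist.probs
    return float(-np.sum(p * np.log2(p)))


def rank_divergence(p, q) -> float:
    """Total-variation distance 0.5 * sum |p_i - q_i| between two distributions.

    Symmetric, bounded in [0, 1]; used to quantify convergence of empirical
    or fitted ranked probabilities toward a ZML target.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D vectors of equal length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0):
            raise ValueError(f"{name} has negative entries")
        if not math.isclose(v.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"{name} must sum to 1 within 1e-9")
    return float(0.5 * np.abs(p - q).sum())
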