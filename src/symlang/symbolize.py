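"""Partitioning of a continuous input space into symbol cells.

Two schemes are provided.  ``gaussian_partition`` places breakpoints at
equal-mass Gaussian quantiles (plain M-level probabilistic quantization).
``cdf_zml_partition`` is the CDF-ZML linguistic partitioner: breakpoints sit
at empirical quantiles of the *cumulative ZML masses*, so that the emitted
symbol stream follows the Zipf-Mandelbrot-Li law for any continuous input
distribution.  Rank 1 (the most probable symbol) occupies the leftmost cell.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .zml import ZMLDistribution, zml_probabilities

__all__ = [
    "PartitionMap",
    "SymbolSequence",
    "default_alphabet",
    "gaussian_partition",
    "EmpiricalCDF",
    "empirical_cdf",
    "cdf_zml_partition",
    "apply_partition",
    "symbol_frequencies",
]


def default_alphabet(M: int) -> list[str]:
    """Default symbol labels: capital letters for M <= 26, else S1..SM."""
    if M <= 26:
        return list(string.ascii_uppercase[:M])
    return [f"S{i}" for i in range(1, M + 1)]


@dataclass(frozen=True)
class PartitionMap:
    """Ordered breakpoints of the input space plus per-cell ZML ranks.

    ``breakpoints`` has M+1 entries U_0..U_M (outer entries may be +-inf);
    cell i covers the half-open interval [U_i, U_{i+1}) except the last
    cell, which is closed on the right.  ``cell_ranks[i]`` is the
    probabilistic rank assigned to spatial cell i; ``alphabet[i]`` its label.
    """

    breakpoints: np.ndarray
    cell_ranks: np.ndarray
    alphabet: list[str]
    target: ZMLDistribution | None = None

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        ranks = np.asarray(self.cell_ranks, dtype=int)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "cell_ranks", ranks)
        M = len(self.alphabet)
        if bp.shape != (M + 1,):
            raise ValueError("need M+1 breakpoints for M cells")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if sorted(ranks.tolist()) != list(range(1, M + 1)):
            raise ValueError("cell_ranks must be a permutation of 1..M")
        if len(set(self.alphabet)) != M:
            raise ValueError("alphabet labels must be distinct")

    @property
    def n_cells(self) -> int:
        return len(self.alphabet)


@dataclass(frozen=True)
class SymbolSequence:
    """Ordered discrete symbols drawn from a declared finite alphabet."""

    symbols: list[str]
    alphabet: list[str]

    def __post_init__(self) -> None:
        allowed = set(self.alphabet)
        bad = next((s for s in self.symbols if s not in allowed), None)
        if bad is not None:
            raise ValueError(f"symbol {bad!r} not in declared alphabet")

    @property
    def alphabet_size(self) -> int:
        return len(self.alphabet)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "".join(self.symbols)

    @classmethod
    def from_text(cls, text: str, alphabet: Sequence[str] | None = None) -> "SymbolSequence":
        """Parse a one-character-per-symbol stream, ignoring newlines."""
        syms = [c for c in text if c not in "\r\n"]
        if alphabet is None:
            alphabet = sorted(set(syms))
        return cls(syms, list(alphabet))


def gaussian_partition(alphabet_size: int, mu: float = 0.0, sigma: float = 1.0) -> PartitionMap:
    """Equal-mass partition under a Gaussian(mu, sigma) input model.

    Interior breakpoints are the Gaussian quantiles at cumulative mass i/M;
    cell ranks are the identity permutation.
    """
    M = int(alphabet_size)
    if M < 1:
        raise ValueError("alphabet_size must be >= 1")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    interior = stats.norm.ppf(np.arange(1, M) / M, loc=mu, scale=sigma)
    bp = np.concatenate(([-np.inf], interior, [np.inf]))
    return PartitionMap(bp, np.arange(1, M + 1), default_alphabet(M))


class EmpiricalCDF:
    """Right-continuous empirical CDF with interpolated quantile inversion."""

    def __init__(self, samples) -> None:
        x = np.asarray(samples, dtype=float).ravel()
        if x.size < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples must all be finite")
        self._sorted = np.sort(x)
        self._n = x.size

    def __call__(self, x) -> np.ndarray | float:
        v = np.searchsorted(self._sorted, np.asarray(x, dtype=float), side="right") / self._n
        return v if np.ndim(x) else float(v)

    def quantile(self, q) -> np.ndarray | float:
        """Inverse CDF by linear interpolation between order statistics."""
        v = np.quantile(self._sorted, np.asarray(q, dtype=float))
        return v if np.ndim(q) else float(v)


def empirical_cdf(samples) -> EmpiricalCDF:
    """Build the empirical CDF of a finite sample (see :class:`EmpiricalCDF`)."""
    return EmpiricalCDF(samples)


def cdf_zml_partition(samples, alphabet_size: int) -> PartitionMap:
    """CDF-ZML partition: breakpoints at empirical quantiles of ZML masses.

    Interior breakpoint k sits at the empirical quantile of the cumulative
    ZML mass sum_{r<=k} p(r), so the cell with rank r captures probability
    p_ZML(r) of the training distribution.  Ranks run left to right in
    decreasing probability (rank 1 leftmost).
    """
    M = int(alphabet_size)
    if M < 1:
        raise ValueError("alphabet_size must be >= 1")
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 10 * M:
        raise ValueError(f"need at least {10 * M} samples for M={M}, got {x.size}")
    target = zml_probabilities(M)
    ecdf = empirical_cdf(x)
    cum = np.cumsum(target.probs)[:-1]
    interior = np.atleast_1d(ecdf.quantile(cum)) if M > 1 else np.empty(0)
    bp = np.concatenate(([-np.inf], interior, [np.inf]))
    widths = np.diff(bp)
    if np.any(widths <= 0):
        cell = int(np.argmax(widths <= 0))
        raise ValueError(
            f"degenerate partition: cell {cell} has zero width "
            "(training sample has too many ties for this alphabet size)"
        )
    return PartitionMap(bp, np.arange(1, M + 1), default_alphabet(M), target=target)


def apply_partition(pm: PartitionMap, signal) -> SymbolSequence:
    """Emit the label of the cell containing each sample.

    Cells are half-open [U_i, U_{i+1}) with the last cell closed; values on
    an interior breakpoint fall into the right cell.  Values beyond the
    training range land in the first/last cell.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        return SymbolSequence([], list(pm.alphabet))
    bad = ~np.isfinite(x)
    if np.any(bad):
        raise ValueError(f"non-finite sample at index {int(np.argmax(bad))}")
    idx = np.searchsorted(pm.breakpoints[1:-1], x, side="right")
    labels = np.asarray(pm.alphabet, dtype=object)
    return SymbolSequence(list(labels[idx]), list(pm.alphabet))


def symbol_frequencies(seq: SymbolSequence) -> np.ndarray:
    """Relative frequency of each alphabet symbol, in alphabet order."""
    if len(seq) == 0:
        raise ValueError("cannot compute frequencies of an empty sequence")
    index = {s: i for i, s in enumerate(seq.alphabet)}
    counts = np.zeros(seq.alphabet_size)
    for s in seq.symbols:
        counts[index[s]] += 1
    return counts / counts.sum()
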