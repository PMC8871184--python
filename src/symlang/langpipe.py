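"""Synthetic-language analysis: spaces, words, ranks, POS mapping, rendering.

A symbolized behavior stream is treated as text in an unknown language.
The most frequent symbol(s) play the role of inter-word spaces (the
"do-nothing" functional symbols that carry the least surprise), the runs
between them are synthetic words, and the words are ranked by frequency.
Because coarse part-of-speech (POS) category frequencies are broadly stable
across human languages, the ranked synthetic words can be mapped
rank-for-rank onto a ranked table of coarse POS categories, and rendered as
a speculative placeholder-word narrative using the most frequent human word
of each category.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .symbolize import SymbolSequence

__all__ = [
    "POSRankTable",
    "TranslationLexicon",
    "default_pos_table",
    "detect_spaces",
    "tokenize_words",
    "rank_words",
    "map_pos",
    "translate",
]


@dataclass(frozen=True)
class POSRankTable:
    """Coarse POS categories with descending ranked probabilities.

    ``placeholder[i]`` is the representative (most frequent) word of
    category i in the reference corpus.
    """

    categories: list[str]
    probs: np.ndarray
    placeholders: list[str]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        n = len(self.categories)
        if n == 0:
            raise ValueError("POS table must have at least one category")
        if p.shape != (n,) or len(self.placeholders) != n:
            raise ValueError("categories, probs and placeholders must align")
        if np.any(np.diff(p) > 0):
            raise ValueError("probs must be in descending order")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")
        if any(not w for w in self.placeholders):
            raise ValueError("placeholders must be non-empty")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @classmethod
    def from_csv(cls, path) -> "POSRankTable":
        df = pd.read_csv(path)
        return cls(
            list(df["category"]),
            df["probability"].to_numpy(dtype=float),
            list(df["placeholder"]),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "category": self.categories,
                "probability": self.probs,
                "placeholder": self.placeholders,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class TranslationLexicon:
    """Rank-preserving word -> POS-category -> placeholder mapping."""

    word_ranks: list[str]
    pos_assignment: dict[str, str] = field(repr=False)
    rendering: dict[str, str] = field(repr=False)


def default_pos_table() -> POSRankTable:
    """The packaged coarse-POS rank table (a synthetic stand-in corpus profile)."""
    with resources.files("symlang").joinpath("data/pos_table_synthetic.csv").open() as fh:
        return POSRankTable.from_csv(fh)


def detect_spaces(seq: SymbolSequence, n_spaces: int = 1) -> set[str]:
    """The ``n_spaces`` most frequent symbols; ties broken by alphabet order.

    For multi-axis pipelines, run once per axis-direction stream to realize
    a six-direction functional-space rule; the univariate default takes the
    single most frequent symbol.
    """
    if len(seq) == 0:
        raise ValueError("cannot detect spaces in an empty sequence")
    if not 1 <= n_spaces < seq.alphabet_size:
        raise ValueError(f"n_spaces must be in [1, {seq.alphabet_size - 1}]")
    counts = Counter(seq.symbols)
    order = {s: i for i, s in enumerate(seq.alphabet)}
    ranked = sorted(counts, key=lambda s: (-counts[s], order[s]))
    return set(ranked[:n_spaces])


def tokenize_words(seq: SymbolSequence, spaces: set[str]) -> list[str]:
    """Maximal runs of non-space symbols, in stream order."""
    if not spaces:
        raise ValueError("spaces must be non-empty")
    if not spaces < set(seq.alphabet):
        raise ValueError("spaces must be a proper subset of the alphabet")
    words, current = [], []
    for s in seq.symbols:
        if s in spaces:
            if current:
                words.append("".join(current))
                current = []
        else:
            current.append(s)
    if current:
        words.append("".join(current))
    return words


def rank_words(words: list[str]) -> list[tuple[str, int]]:
    """(word, count) pairs by descending count; ties by first occurrence."""
    if not words:
        raise ValueError("cannot rank an empty word list")
    counts = Counter(words)
    first = {}
    for i, w in enumerate(words):
        first.setdefault(w, i)
    return sorted(counts.items(), key=lambda kv: (-kv[1], first[kv[0]]))


def map_pos(ranked_words: list[tuple[str, int]], table: POSRankTable) -> TranslationLexicon:
    """Rank-r synthetic word -> rank-r POS category; surplus words -> last category."""
    if table.n_categories == 0:
        raise ValueError("POS table is empty")
    words = [w for w, _ in ranked_words]
    assignment, rendering = {}, {}
    for r, w in enumerate(words):
        c = min(r, table.n_categories - 1)
        assignment[w] = table.categories[c]
        rendering[w] = table.placeholders[c]
    return TranslationLexicon(words, assignment, rendering)


def translate(seq: SymbolSequence, spaces: set[str], lexicon: TranslationLexicon) -> str:
    """Render the stream as placeholder words separated by single blanks."""
    out = []
    for w in tokenize_words(seq, spaces):
        if w not in lexicon.rendering:
            raise KeyError(f"word {w!r} is not covered by the lexicon")
        out.append(lexicon.rendering[w])
    return " ".join(out)
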