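"""Seeded generators for every study condition the toolkit is tested on.

* ``random_typing_text`` — the Li random-typing source (uniform keys over M
  letters plus a space), whose word rank-frequency law is the ZML law.
* ``two_author_text`` — a long main text interleaved with short inserted
  segments whose word-length distribution differs, emulating a novel with
  passages by a second, stylistically simpler author.
* ``sample_zml_mixture`` — a Gaussian mixture whose mixing weights are
  exactly the ZML probabilities, the recovery benchmark for LCEM.
* ``gen_accelerometer`` — a regime-switching AR(1) signal at 100 Hz with
  hidden behavioral states, structurally emulating triaxial accelerometry
  of a small mammal (no claim of matching any real animal's dynamics).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .zml import zml_probabilities

__all__ = [
    "RegimeSignal",
    "random_typing_text",
    "two_author_text",
    "sample_zml_mixture",
    "gen_accelerometer",
]

#: Midpoint word lengths of the five word-length bins (1-3, 4-6, 7-9, 10-12, >=13).
_BIN_LENGTH_RANGES = [(1, 3), (4, 6), (7, 9), (10, 12), (13, 15)]


@dataclass(frozen=True)
class RegimeSignal:
    """Multi-axis signal with a hidden behavioral state per sample."""

    samples: np.ndarray  # (n, n_axes)
    sample_rate: float  # Hz
    true_states: np.ndarray  # (n,) int labels
    duration: float  # seconds

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_axes(self) -> int:
        return self.samples.shape[1]


def random_typing_text(alphabet_size: int, n_chars: int, seed: int = 0) -> str:
    """Random-typing text: each character uniform over M letters and a space."""
    M = int(alphabet_size)
    if M < 1:
        raise ValueError("alphabet_size must be >= 1")
    if n_chars < 1:
        raise ValueError("n_chars must be >= 1")
    rng = np.random.default_rng(seed)
    keys = np.asarray(list(string.ascii_lowercase[:M]) + [" "], dtype=object)
    return "".join(rng.choice(keys, size=n_chars))


def _draw_words(rng: np.random.Generator, bin_dist: np.ndarray, n_words: int) -> list[str]:
    letters = np.asarray(list(string.ascii_lowercase), dtype="U1")
    bins = rng.choice(5, size=n_words, p=bin_dist)
    words = []
    for b in bins:
        lo, hi = _BIN_LENGTH_RANGES[b]
        length = int(rng.integers(lo, hi + 1))
        words.append("".join(rng.choice(letters, size=length)))
    return words


def two_author_text(
    main_worddist=None,
    insert_worddist=None,
    n_words: int = 105_000,
    n_inserts: int = 10,
    insert_len: int = 1_500,
    seed: int = 0,
) -> tuple[str, list[tuple[int, int]]]:
    """A main text with inserted segments from a second word-length profile.

    ``main_worddist``/``insert_worddist`` are distributions over the five
    word-length bins; the defaults are a uniform main profile and an
    insert profile concentrated on the shortest bin, mirroring a verbose
    novel interleaved with short passages of a deliberately simple
    children's text.  The default sizes — a 105,000-word main corpus (the
    length of a typical story collection) carrying ten 1,500-word inserts —
    keep the inserted fraction near 14%, small enough for inserts to read
    as anomalies of the corpus rather than a second mode.

    Returns the character stream (lowercase words separated by single
    spaces) and the ground-truth list of half-open insert intervals
    ``(start_word, end_word)`` in word indices.
    """
    main_worddist = np.full(5, 0.2) if main_worddist is None else np.asarray(main_worddist, float)
    insert_worddist = (
        np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        if insert_worddist is None
        else np.asarray(insert_worddist, float)
    )
    for name, d in (("main_worddist", main_worddist), ("insert_worddist", insert_worddist)):
        if d.shape != (5,) or abs(d.sum() - 1.0) > 1e-9 or np.any(d < 0):
            raise ValueError(f"{name} must be a normalized distribution over 5 bins")
    total_insert = n_inserts * insert_len
    if total_insert > n_words:
        raise ValueError("inserts do not fit in the requested text length")
    rng = np.random.default_rng(seed)

    intervals: list[tuple[int, int]] = []
    if n_inserts > 0:
        # place inserts in the gaps of a seeded composition of the main text
        n_main = n_words - total_insert
        gaps = rng.multinomial(n_main, np.full(n_inserts + 1, 1.0 / (n_inserts + 1)))
        start = 0
        for g in gaps[:-1]:
            start += int(g)
            intervals.append((start, start + insert_len))
            start += insert_len

    words: list[str] = []
    cursor = 0
    for a, b in intervals:
        words.extend(_draw_words(rng, main_worddist, a - cursor))
        words.extend(_draw_words(rng, insert_worddist, b - a))
        cursor = b
    words.extend(_draw_words(rng, main_worddist, n_words - cursor))
    return " ".join(words), intervals


def sample_zml_mixture(
    M: int, dim: int = 2, separation: float = 8.0, n: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """Samples from a Gaussian mixture with ZML mixing weights.

    Unit-variance components; means are drawn (seeded) from a lattice with
    spacing ``separation``, guaranteeing pairwise distances >= separation.
    Returns ``(data, truth)`` where ``truth`` holds the means, weights and
    per-sample component labels.
    """
    if M < 1 or separation <= 0:
        raise ValueError("need M >= 1 and separation > 0")
    rng = np.random.default_rng(seed)
    weights = zml_probabilities(M).probs
    side = int(np.ceil(M ** (1.0 / dim))) + 1
    grid = np.array(np.meshgrid(*[np.arange(side)] * dim)).reshape(dim, -1).T
    idx = rng.choice(len(grid), size=M, replace=False)
    means = grid[idx].astype(float) * separation
    labels = rng.choice(M, size=n, p=weights)
    data = means[labels] + rng.standard_normal((n, dim))
    return data, {"means": means, "weights": weights, "labels": labels}


def gen_accelerometer(
    duration_s: float = 10.0,
    sample_rate: float = 100.0,
    n_states: int = 3,
    seed: int = 0,
    state_means=None,
    state_stds=None,
    mean_dwell_s: float = 1.0,
    ar_coeff: float = 0.8,
    n_axes: int = 3,
) -> RegimeSignal:
    """Regime-switching accelerometer-like signal.

    A hidden Markov chain with geometric dwell times (mean ``mean_dwell_s``
    seconds, at least 0.2 s) selects a behavioral state; each state drives
    stationary AR(1) emissions per axis with state-specific mean and
    standard deviation.  ``state_means``/``state_stds`` may be given as
    (n_states, n_axes) arrays; by default means are drawn in [-2, 2] and
    stds log-uniform in [0.3, 3].
    """
    if duration_s <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample rate must be positive")
    if n_states < 2:
        raise ValueError("need at least 2 states")
    mean_dwell_s = max(mean_dwell_s, 0.2)
    n = int(duration_s * sample_rate)
    rng = np.random.default_rng(seed)
    if state_means is None:
        state_means = rng.uniform(-2.0, 2.0, size=(n_states, n_axes))
    if state_stds is None:
        state_stds = np.exp(rng.uniform(np.log(0.3), np.log(3.0), size=(n_states, n_axes)))
    state_means = np.broadcast_to(np.asarray(state_means, float), (n_states, n_axes))
    state_stds = np.broadcast_to(np.asarray(state_stds, float), (n_states, n_axes))

    p_switch = 1.0 / (mean_dwell_s * sample_rate)
    states = np.empty(n, dtype=int)
    s = int(rng.integers(n_states))
    for t in range(n):
        states[t] = s
        if rng.random() < p_switch:
            s = int(rng.choice([k for k in range(n_states) if k != s]))

    # standardized AR(1) core z_t (unit marginal variance), scaled and shifted
    # per state so each state has exactly its specified mean and variance
    innov_scale = np.sqrt(1.0 - ar_coeff**2)
    eps = rng.standard_normal((n, n_axes))
    z = np.empty((n, n_axes))
    z[0] = eps[0]
    for t in range(1, n):
        z[t] = ar_coeff * z[t - 1] + innov_scale * eps[t]
    x = state_means[states] + state_stds[states] * z
    return RegimeSignal(x, float(sample_rate), states, float(duration_s))
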