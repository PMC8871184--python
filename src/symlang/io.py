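"""Delimited-text I/O for signals, symbol streams, and entropy traces.

All delimited files are comma-separated UTF-8 with a header row.  Symbol
streams are plain text, one character per symbol, wrapped at 80 symbols per
line.  Artifacts written by the CLI carry a JSON sidecar recording the
configuration and seed that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy_profile import EntropyTrace
from .symbolize import SymbolSequence
from .synth import RegimeSignal

__all__ = [
    "read_signal",
    "write_signal",
    "read_symbols",
    "write_symbols",
    "read_trace",
    "write_trace",
    "write_sidecar",
]

_TIME_NAMES = {"time", "t", "timestamp", "seconds"}


def read_signal(path) -> dict[str, np.ndarray]:
    """Read a delimited signal file into per-axis vectors.

    Expects a header row and 1-4 numeric columns; a column named time/t is
    returned under ``"time"``, every other column under its header name.
    Non-numeric or non-finite cells raise a parse error naming the line.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if not 1 <= df.shape[1] <= 4:
        raise ValueError(f"expected 1-4 columns, found {df.shape[1]} in {path}")
    out: dict[str, np.ndarray] = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            line = int(np.argmax(bad)) + 2  # +1 header, +1 one-based
            raise ValueError(f"non-numeric value in column {col!r} at line {line} of {path}")
        key = "time" if col.strip().lower() in _TIME_NAMES else col
        out[key] = vals
    return out


def write_signal(path, signal: RegimeSignal | dict[str, np.ndarray]) -> None:
    """Write per-axis vectors (or a RegimeSignal with time column) as CSV."""
    if isinstance(signal, RegimeSignal):
        cols = {"time": np.arange(signal.n_samples) / signal.sample_rate}
        for i in range(signal.n_axes):
            cols["xyz"[i] if i < 3 else f"axis{i}"] = signal.samples[:, i]
    else:
        cols = dict(signal)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_symbols(path, seq: SymbolSequence, wrap: int = 80) -> None:
    text = str(seq)
    lines = [text[i : i + wrap] for i in range(0, len(text), wrap)] or [""]
    Path(path).write_text("\n".join(lines) + "\n")


def read_symbols(path, alphabet=None) -> SymbolSequence:
    return SymbolSequence.from_text(Path(path).read_text(), alphabet)


def write_trace(path, trace: EntropyTrace) -> None:
    pd.DataFrame(
        {"window_start": trace.window_starts, "entropy": trace.entropies}
    ).to_csv(path, index=False)


def read_trace(path, window_length: int | None = None, alphabet_size: int | None = None) -> EntropyTrace:
    df = pd.read_csv(path)
    starts = df["window_start"].to_numpy(dtype=int)
    h = df["entropy"].to_numpy(dtype=float)
    if window_length is None:
        window_length = int(starts[1] - starts[0]) if len(starts) > 1 else 1
    if alphabet_size is None:
        # smallest alphabet consistent with the observed entropies
        alphabet_size = max(2, int(np.ceil(2 ** h.max())) if len(h) else 2)
    return EntropyTrace(window_length, h, alphabet_size)


def write_sidecar(artifact_path, config: dict) -> None:
    """Write ``<artifact>.meta.json`` recording config, seed and versions."""
    import sys

    import scipy
    import sklearn

    meta = {
        "config": config,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    Path(str(artifact_path) + ".meta.json").write_text(json.dumps(meta, indent=2))
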