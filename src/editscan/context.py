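"""Sequence context around editing sites: frequency matrices and information.

The computation behind a sequence logo: extract the 100-nt windows centred
on each site (50 nt upstream, the site itself at offset 0, 49 nt downstream),
tabulate per-position base frequencies ignoring pad characters, and score
conservation as information content IC = 2 - H bits against a uniform
background, optionally with the small-sample correction e_n = 3/(2 ln2 n).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RNA_BASES, Transcript
from .calling import EditingSite


@dataclass
class ContextMatrix:
    offsets: np.ndarray  # site-relative positions, site at 0
    base_frequencies: pd.DataFrame  # rows A,C,G,U x columns offsets
    information_content: np.ndarray  # bits, NaN where no informative base
    n_sequences: int
    pattern: str | None = None


def _sequence_of(tx: Transcript | str) -> str:
    return tx.sequence if isinstance(tx, Transcript) else tx


def extract_windows(
    sites: Sequence[EditingSite],
    transcripts: Mapping[str, Transcript | str],
    flank: int = 50,
) -> list[str]:
    """Per site, the window [pos - flank, pos + flank - 1], N-padded at ends."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    windows = []
    for site in sites:
        seq = _sequence_of(transcripts[site.target_id])
        lo = site.position - flank  # 1-based inclusive
        hi = site.position + flank - 1
        left_pad = max(0, 1 - lo)
        right_pad = max(0, hi - len(seq))
        core = seq[max(lo, 1) - 1 : min(hi, len(seq))]
        windows.append("N" * left_pad + core + "N" * right_pad)
    return windows


def position_information(
    windows: Sequence[str], *, correction: bool = False, pattern: str | None = None
) -> ContextMatrix:
    """Column-wise base frequencies and information content of aligned windows."""
    if not windows:
        raise ValueError("no windows")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows have unequal lengths")
    counts = np.zeros((4, width), dtype=float)
    base_idx = {b: i for i, b in enumerate(RNA_BASES)}
    for w in windows:
        for j, b in enumerate(w):
            if b in base_idx:
                counts[base_idx[b], j] += 1
    n_col = counts.sum(axis=0)
    freqs = np.full_like(counts, np.nan)
    ic = np.full(width, np.nan)
    for j in range(width):
        if n_col[j] == 0:
            continue
        p = counts[:, j] / n_col[j]
        freqs[:, j] = p
        h = -sum(pi * math.log2(pi) for pi in p if pi > 0)
        value = 2.0 - h
        if correction:
            value -= 3.0 / (2.0 * math.log(2) * n_col[j])
        ic[j] = max(value, 0.0)
    flank = width // 2
    offsets = np.arange(-flank, width - flank)
    return ContextMatrix(
        offsets=offsets,
        base_frequencies=pd.DataFrame(freqs, index=list(RNA_BASES), columns=offsets),
        information_content=ic,
        n_sequences=len(windows),
        pattern=pattern,
    )


def random_control(
    transcripts: Mapping[str, Transcript | str] | Sequence[Transcript],
    n: int,
    length: int = 100,
    seed: int = 0,
) -> list[str]:
    """n windows drawn uniformly from transcript positions (logo null model)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(transcripts, Mapping):
        seqs = [_sequence_of(t) for _, t in sorted(transcripts.items())]
    else:
        seqs = [_sequence_of(t) for t in transcripts]
    seqs = [s for s in seqs if len(s) >= length]
    if not seqs:
        raise ValueError(f"no transcript reaches window length {length}")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(s) - length + 1 for s in seqs], dtype=float)
    probs = lengths / lengths.sum()
    windows = []
    for _ in range(n):
        i = int(rng.choice(len(seqs), p=probs))
        start = int(rng.integers(0, len(seqs[i]) - length + 1))
        windows.append(seqs[i][start : start + length])
    return windows
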