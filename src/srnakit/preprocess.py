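"""Adapter/quality trimming and library composition statistics.

The trimming policy follows the study conventions for AGO-IP small-RNA
libraries: locate the 3' adapter as the best prefix match at the read's
3' end (<= 10% mismatches, minimum overlap 5, leftmost match wins), then
hard-trim leading/trailing bases whose Phred score is not > 20, then gate
on an 18-26 nt length window bracketing the canonical 21-22 nt mode.

Trimming is iterated to a fixpoint so that preprocessing is idempotent:
running the pipeline on its own output changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import SmallRead
from ._seq import canonical

#: column order of the positional frequency matrix (RNA lettering; the
#: canonical internal T is reported as U)
BASES = ("A", "C", "G", "U")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _find_adapter(seq: str, adapter: str, max_mismatch_frac: float, min_overlap: int) -> int:
    """Leftmost trim point for a 3' adapter, or len(seq) if absent.

    At candidate position ``i`` the adapter prefix is compared against
    ``seq[i:]`` through the end of the read (overlap capped at the adapter
    length); the match is accepted when mismatches <= floor(frac * overlap).
    """
    L = len(seq)
    for i in range(L - min_overlap + 1):
        overlap = min(len(adapter), L - i)
        if overlap < min_overlap:
            break
        budget = int(max_mismatch_frac * overlap)
        mm = 0
        ok = True
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mm += 1
                if mm > budget:
                    ok = False
                    break
        if ok:
            return i
    return L


def _quality_trim(seq: str, quals: Optional[list[int]], cutoff: int) -> tuple[str, Optional[list[int]]]:
    """Strip leading/trailing bases whose Phred score fails "> cutoff"."""
    if quals is None:
        return seq, None
    lo, hi = 0, len(seq)
    while lo < hi and quals[lo] <= cutoff:
        lo += 1
    while hi > lo and quals[hi - 1] <= cutoff:
        hi -= 1
    return seq[lo:hi], quals[lo:hi]


def preprocess_reads(
    reads: Sequence[SmallRead],
    adapter: Optional[str] = None,
    min_len: int = 18,
    max_len: int = 26,
    phred_cutoff: int = 20,
    max_mismatch_frac: float = 0.1,
    min_overlap: int = 5,
) -> list[SmallRead]:
    """Adapter-trim, quality-trim and length-filter a read list.

    The adapter step is skipped when *adapter* is None; the quality step is
    a no-op for reads without qualities.  Counts are preserved through
    trimming; reads ending up outside ``[min_len, max_len]`` are discarded.
    The adapter+quality cycle is repeated until the read stops changing,
    which makes the whole operation idempotent.
    """
    if adapter is not None:
        if not adapter:
            raise ValueError("adapter must be non-empty when trimming is requested")
        adapter = canonical(adapter)
    out: list[SmallRead] = []
    for read in reads:
        seq, quals = read.sequence, read.qualities
        while True:
            prev = seq
            if adapter is not None and seq:
                cut = _find_adapter(seq, adapter, max_mismatch_frac, min_overlap)
                seq = seq[:cut]
                if quals is not None:
                    quals = quals[:cut]
            if seq:
                seq, quals = _quality_trim(seq, quals, phred_cutoff)
            if seq == prev or not seq:
                break
        if min_len <= len(seq) <= max_len:
            out.append(SmallRead(read.read_id, seq, count=read.count, qualities=quals))
    return out


@dataclass
class CompositionSummary:
    """Length histogram and positional nucleotide frequencies of a library.

    ``positional_freq`` rows are positions (0-based from the 5' end) and
    columns A/C/G/U; each row is normalized over the count-weighted reads
    covering that position (ignoring N), so every non-empty row sums to 1.
    """

    length_histogram: dict[int, int] = field(default_factory=dict)
    positional_freq: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(BASES))
    )
    five_prime_freq: dict[str, float] = field(default_factory=dict)
    total_reads: int = 0

    @property
    def length_mode(self) -> Optional[int]:
        if not self.length_histogram:
            return None
        return max(self.length_histogram, key=lambda L: (self.length_histogram[L], -L))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        hist = pd.DataFrame(
            sorted(self.length_histogram.items()), columns=["length", "count"]
        )
        return hist, self.positional_freq


def compute_composition(reads: Sequence[SmallRead]) -> CompositionSummary:
    """Count-weighted composition statistics of a (preprocessed) library."""
    if not reads:
        return CompositionSummary()
    max_len = max(len(r) for r in reads)
    counts = np.zeros((max_len, 4), dtype=np.int64)
    hist: dict[int, int] = {}
    for r in reads:
        hist[len(r)] = hist.get(len(r), 0) + r.count
        for pos, base in enumerate(r.sequence):
            j = _BASE_INDEX.get(base)
            if j is not None:
                counts[pos, j] += r.count
    row_totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(row_totals > 0, counts / row_totals, 0.0)
    pf = pd.DataFrame(freq, columns=list(BASES))
    pf.index.name = "position"
    first_total = counts[0].sum()
    five = {
        b: (counts[0, j] / first_total if first_total else 0.0)
        for b, j in (("A", 0), ("C", 1), ("G", 2), ("U", 3))
    }
    return CompositionSummary(
        length_histogram=hist,
        positional_freq=pf,
        five_prime_freq=five,
        total_reads=sum(hist.values()),
    )
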