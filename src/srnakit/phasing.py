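"""Detection of phased (tasiRNA-like) siRNA loci.

Phased siRNAs are produced in successive p-nt increments (p = 21) from one
locus, so their 5' starts share a residue class ("register") modulo p.  The
detector slides a window of length W (a multiple of p) along each scaffold
and asks whether the occupied 5'-start positions concentrate in one
register far beyond chance.  Both strands contribute: a minus-strand read
belonging to the duplex of a plus-strand cycle read at q has its genomic
leftmost coordinate at q - 2 (the 2-nt 3' overhangs of the processing
duplex), so minus-strand starts are shifted by +2 before register
assignment.

Within a window of length W there are N = 2W candidate (position, strand)
slots of which K = 2W/p lie in any given register.  With n occupied slots
of which k are in-register, the p-value is the hypergeometric upper tail

    P(X >= k),  X ~ Hypergeometric(N, K, n)

evaluated exactly in integer arithmetic.  Because the register of a real
locus is unknown, the detector takes the best of the p possible registers
and Bonferroni-corrects by p; windows are then corrected across the genome
by Benjamini-Hochberg and merged into loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import AlignedRead, GenomicInterval


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed as a ratio of integer binomial sums, so the result is the
    correctly rounded float of an exact rational.
    """
    if k <= 0:
        return 1.0
    if k > min(n, K):
        return 0.0
    num = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    )
    return num / math.comb(N, n)


def phasing_pvalue(
    positions: Iterable[tuple[int, str]],
    window_length: int,
    phase: int = 21,
    register: int = 0,
) -> float:
    """Exact phasing p-value of one window for one register.

    Parameters
    ----------
    positions : iterable of (offset, strand)
        Occupied 5'-start slots, window-relative, minus-strand offsets
        already shifted by +2.  Duplicates are collapsed.
    window_length : int
        W; must be a positive multiple of *phase*.
    phase : int
        Cycle length p (default 21).
    register : int
        Residue class tested, in ``[0, phase)``.

    Returns
    -------
    float
        P(X >= k) under the hypergeometric null; 1.0 for an empty window.
    """
    if window_length <= 0 or window_length % phase != 0:
        raise ValueError("window_length must be a positive multiple of phase")
    if not 0 <= register < phase:
        raise ValueError("register out of range")
    occ = {(int(pos), s) for pos, s in positions}
    for pos, s in occ:
        if not 0 <= pos < window_length:
            raise ValueError(f"position {pos} outside window [0, {window_length})")
        if s not in "+-":
            raise ValueError(f"invalid strand {s!r}")
    n = len(occ)
    if n == 0:
        return 1.0
    k = sum(1 for pos, _ in occ if pos % phase == register)
    assert k <= n
    N = 2 * window_length
    K = 2 * window_length // phase
    return hypergeom_tail(k, N, K, n)


def window_pvalue_best_register(
    positions: Iterable[tuple[int, str]],
    window_length: int,
    phase: int = 21,
) -> tuple[float, int, int, int]:
    """Best-register window test with Bonferroni correction over registers.

    Returns ``(p_value, register, k, n)`` where the p-value is
    ``min(1, phase * tail)`` for the register maximizing k (smallest
    register wins ties).
    """
    occ = {(int(pos), s) for pos, s in positions}
    n = len(occ)
    if n == 0:
        return 1.0, 0, 0, 0
    counts = [0] * phase
    for pos, _ in occ:
        counts[pos % phase] += 1
    k = max(counts)
    register = counts.index(k)
    N = 2 * window_length
    K = 2 * window_length // phase
    p = min(1.0, phase * hypergeom_tail(k, N, K, n))
    return p, register, k, n


@dataclass
class PhasedLocus:
    """A called phased-siRNA locus."""

    interval: GenomicInterval
    phase: int
    register: int           # residue class of in-phase 5' starts, scaffold frame
    n_occupied: int         # distinct occupied (position, strand) slots
    k_in_register: int      # of which in the reported register
    p_value: float          # BH-adjusted p-value of the best window
    n_reads: int            # count-weighted reads contributing


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def _shifted_positions(
    alignments: Iterable[AlignedRead],
    phase: int,
    length_tolerance: int,
) -> dict[str, dict[tuple[int, str], int]]:
    """Per-scaffold {(shifted 5' start, strand): weighted count} maps.

    Only reads of length ``phase +/- length_tolerance`` contribute;
    minus-strand leftmost starts are shifted +2 into the plus frame.
    """
    per_scaffold: dict[str, dict[tuple[int, str], int]] = {}
    for a in alignments:
        if abs(a.length - phase) > length_tolerance:
            continue
        pos = a.start if a.strand == "+" else a.start + 2
        slots = per_scaffold.setdefault(a.scaffold, {})
        key = (pos, a.strand)
        slots[key] = slots.get(key, 0) + a.count
    return per_scaffold


def detect_phased_loci(
    alignments: Sequence[AlignedRead],
    scaffold_lengths: dict[str, int],
    phase: int = 21,
    window_length: int = 189,
    alpha: float = 1e-4,
    min_cycles: int = 4,
    length_tolerance: int = 0,
) -> list[PhasedLocus]:
    """Scan the genome for phased siRNA loci.

    Windows of length W slide by W/3 (rounded down to a multiple of p);
    per-window best-register p-values are BH-corrected genome-wide, and
    overlapping significant windows are merged into loci.  A locus must
    contain at least *min_cycles* distinct in-register occupied slots.
    """
    if window_length % phase != 0:
        raise ValueError("window_length must be a multiple of phase")
    step = max(phase, (window_length // 3) // phase * phase)
    per_scaffold = _shifted_positions(alignments, phase, length_tolerance)

    windows: list[tuple[str, int, float, int, int, int]] = []
    for scaffold, slots in sorted(per_scaffold.items()):
        if not slots:
            continue
        positions = np.array(sorted({p for p, _ in slots}), dtype=np.int64)
        slot_list = sorted(slots)
        pos_arr = np.array([p for p, _ in slot_list], dtype=np.int64)
        length = scaffold_lengths.get(scaffold, int(positions.max()) + phase)
        last_start = max(0, length - window_length)
        starts = range(0, last_start + 1, step)
        for w in starts:
            lo = np.searchsorted(pos_arr, w, side="left")
            hi = np.searchsorted(pos_arr, w + window_length, side="left")
            if hi <= lo:
                continue
            window_slots = [
                (slot_list[i][0] - w, slot_list[i][1]) for i in range(lo, hi)
            ]
            p, reg, k, n = window_pvalue_best_register(
                window_slots, window_length, phase
            )
            # register reported in the scaffold coordinate frame
            windows.append((scaffold, w, p, (reg + w) % phase, k, n))

    if not windows:
        return []
    adj = benjamini_hochberg([w[2] for w in windows])
    significant = [
        (scaffold, w, adj_p, reg)
        for (scaffold, w, _, reg, k, n), adj_p in zip(windows, adj)
        if adj_p <= alpha
    ]
    if not significant:
        return []

    # merge overlapping significant windows per scaffold
    loci: list[PhasedLocus] = []
    significant.sort(key=lambda t: (t[0], t[1]))
    cluster: list[tuple[str, int, float, int]] = []

    def _flush(cluster):
        if not cluster:
            return
        scaffold = cluster[0][0]
        best = min(cluster, key=lambda t: (t[2], t[1]))
        register = best[3]
        span_lo = cluster[0][1]
        span_hi = cluster[-1][1] + window_length
        slots = per_scaffold[scaffold]
        in_span = [
            (pos, s) for (pos, s) in slots if span_lo <= pos < span_hi
        ]
        in_reg = sorted(pos for pos, _ in in_span if pos % phase == register)
        distinct_in_reg = sorted(set(in_reg))
        if len(distinct_in_reg) < min_cycles:
            return
        start = distinct_in_reg[0]
        end = distinct_in_reg[-1] + phase
        n_reads = sum(
            c for (pos, s), c in slots.items() if start <= pos < end
        )
        loci.append(
            PhasedLocus(
                interval=GenomicInterval(scaffold, start, end, ".", "phased"),
                phase=phase,
                register=register,
                n_occupied=len([p for p, _ in in_span if start <= p < end]),
                k_in_register=len(distinct_in_reg),
                p_value=best[2],
                n_reads=n_reads,
            )
        )

    for item in significant:
        if cluster and (
            item[0] != cluster[-1][0] or item[1] > cluster[-1][1] + window_length
        ):
            _flush(cluster)
            cluster = []
        cluster.append(item)
    _flush(cluster)
    loci.sort(key=lambda l: (l.interval.scaffold, l.interval.start))
    return loci
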