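"""miRNA locus calling, family grouping and cross-species conservation.

The caller is an explicit, fully documented structure-based surrogate for
thermodynamic miRNA predictors: candidate precursors are read-dense blocks,
the precursor is folded by exact maximum-base-pairing dynamic programming
(Watson-Crick + G:U, minimum hairpin loop 3), and a candidate is accepted
when the most abundant read ("mature") sits on one arm of a single
stem-loop, pairs predominantly with a contiguous region on the opposite
arm (the "star"), and mature + star reads dominate the locus (precision).
The folding backend is pluggable: any callable returning a
:class:`HairpinFold` can replace :func:`fold_hairpin`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import PAIRABLE, canonical, revcomp
from .core_io import AlignedRead, GenomicInterval

MIN_LOOP = 3  # minimum hairpin loop length (unpaired bases between a pair)


# ---------------------------------------------------------------------------
# folding


@dataclass
class HairpinFold:
    """A nested secondary structure from maximum-pairing folding."""

    sequence: str
    pairs: list[tuple[int, int]]    # (i, j) with i < j, 0-based
    dot_bracket: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def _pair_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    P = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            if (seq[i], seq[j]) in PAIRABLE:
                P[i, j] = True
    return P


def fold_hairpin(sequence: str) -> HairpinFold:
    """Maximum base-pair nested fold of *sequence* (exact DP).

    Nussinov-style recurrence with the k-loop vectorized:

        M[i, j] = max( M[i+1, j],
                       max_k { 1 + M[i+1, k-1] + M[k+1, j] : i pairs k } )

    Traceback tie-break: whenever pairing position i attains the optimum,
    i is paired, with the largest admissible partner k — i.e. prefer the
    pair (i, j) with smallest i, then largest j.
    """
    seq = canonical(sequence)
    n = len(seq)
    if n == 0:
        return HairpinFold(seq, [], "")
    P = _pair_matrix(seq)
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    # M indexed by [i, j] over inclusive i..j ranges; M[i, j] for i > j is 0.
    # Use padded array where entry (i, j) means interval [i, j-1]? Keep it
    # simple: work on an (n, n) table with explicit guards.
    M = np.zeros((n, n), dtype=np.int32)

    def get(i: int, j: int) -> int:
        return int(M[i, j]) if 0 <= i <= j < n else 0

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]
            ks = np.nonzero(P[i, i : j + 1])[0] + i
            if ks.size:
                left = np.where(ks - 1 >= i + 1, M[i + 1, np.maximum(ks - 1, i + 1)], 0)
                right = np.where(ks + 1 <= j, M[np.minimum(ks + 1, j), j], 0)
                cand = 1 + left + right
                best = max(best, int(cand.max()))
            M[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        target = M[i, j]
        paired = False
        for k in range(j, i + MIN_LOOP, -1):  # largest partner first
            if not P[i, k]:
                continue
            inner = get(i + 1, k - 1)
            outer = get(k + 1, j)
            if 1 + inner + outer == target:
                pairs.append((i, k))
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return HairpinFold(seq, pairs, "".join(db))


def max_pairs_alternative(sequence: str) -> int:
    """Independent maximum-pairing count via a structurally different DP.

    Splits on the pairing status of the interval's *last* base:

        F[i][j] = max( F[i][j-1],
                       max_k { 1 + F[i][k-1] + F[k+1][j-1] : k pairs j } )

    Used as a cross-check oracle for :func:`fold_hairpin`.
    """
    seq = canonical(sequence)
    n = len(seq)
    F = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = F[i][j - 1]
            for k in range(i, j - MIN_LOOP):
                if (seq[k], seq[j]) in PAIRABLE:
                    left = F[i][k - 1] if k - 1 >= i else 0
                    mid = F[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = 1 + left + mid
                    if cand > best:
                        best = cand
            F[i][j] = best
    return F[0][n - 1] if n else 0


# ---------------------------------------------------------------------------
# locus calling


@dataclass
class MirnaLocus:
    """A called miRNA locus with read support."""

    precursor: GenomicInterval
    fold: HairpinFold
    mature_sequence: str
    star_sequence: str
    arm: str                    # "5p" or "3p"
    strand: str
    mature_start: int           # genomic, 0-based
    mature_count: int
    star_count: int
    locus_count: int

    @property
    def precision(self) -> float:
        return (self.mature_count + self.star_count) / self.locus_count


@dataclass
class MirnaCallerParams:
    min_locus_reads: int = 10
    max_gap: int = 50
    flank: int = 20
    precursor_max: int = 300
    min_paired_mature_frac: float = 0.6
    max_overhang: int = 4
    min_precision: float = 0.5
    min_star_reads: int = 1     # duplex evidence: star arm must be sequenced
    mature_min_len: int = 20
    mature_max_len: int = 23
    wobble: int = 1             # 5'-end tolerance when tallying mature reads


def _blocks(alignments: Sequence[AlignedRead], max_gap: int):
    """Group position-sorted placements into blocks with gaps <= max_gap."""
    by_scaffold: dict[str, list[AlignedRead]] = {}
    for a in alignments:
        by_scaffold.setdefault(a.scaffold, []).append(a)
    for scaffold in sorted(by_scaffold):
        group = sorted(by_scaffold[scaffold], key=lambda a: (a.start, a.end))
        block: list[AlignedRead] = []
        block_end = -1
        for a in group:
            if block and a.start > block_end + max_gap:
                yield scaffold, block
                block = []
            block.append(a)
            block_end = max(block_end, a.end)
        if block:
            yield scaffold, block


def call_mirna_loci(
    alignments: Sequence[AlignedRead],
    genome: dict[str, str],
    params: MirnaCallerParams | None = None,
    folder: Callable[[str], HairpinFold] = fold_hairpin,
    return_rejected: bool = False,
):
    """Call miRNA loci from read-dense blocks.

    Acceptance requires, in order: a block of >= ``min_locus_reads``
    (count-weighted) whose span + flanks fits ``precursor_max``; a dominant
    read of mature length; a fold in which >= ``min_paired_mature_frac`` of
    mature bases pair, all with a region strictly on one side of the mature
    (single stem-loop through the mature); and mature + star precision >=
    ``min_precision``.  Rejected candidates carry a reason code.
    """
    p = params or MirnaCallerParams()
    loci: list[MirnaLocus] = []
    rejected: list[tuple[GenomicInterval, str]] = []

    def _evaluate(scaffold, block, by_read, total, dominant, flank):
        """Evaluate one precursor window; returns (locus, reason)."""
        span_lo = min(a.start for a in block)
        span_hi = max(a.end for a in block)
        pre_lo = max(0, span_lo - flank)
        pre_hi = min(len(genome[scaffold]), span_hi + flank)
        if pre_hi - pre_lo > p.precursor_max:
            return None, "span"
        strand = dominant.strand
        pre_seq = genome[scaffold][pre_lo:pre_hi]
        if strand == "-":
            pre_seq = revcomp(pre_seq)
        # mature offsets in precursor (read-strand frame)
        if strand == "+":
            m0 = dominant.start - pre_lo
        else:
            m0 = pre_hi - dominant.end
        m1 = m0 + dominant.length
        fold = folder(pre_seq)
        partner = fold.partner()
        partners = sorted(partner[i] for i in range(m0, m1) if i in partner)
        if len(partners) < p.min_paired_mature_frac * dominant.length:
            return None, "pairing"
        # single stem-loop through the mature: its partners must lie on one
        # side of it; up to 2 stray pairs are tolerated as folding noise
        left = [q for q in partners if q < m0]
        right = [q for q in partners if q >= m1]
        internal = len(partners) - len(left) - len(right)
        majority, minority = (right, left) if len(right) >= len(left) else (left, right)
        if (
            internal + len(minority) > 2
            or len(majority) < p.min_paired_mature_frac * dominant.length
        ):
            return None, "structure"
        arm = "5p" if majority is right else "3p"
        star_lo, star_hi = majority[0], majority[-1] + 1
        star_seq = pre_seq[star_lo:star_hi]

        # tally support: mature = reads starting within the 5'-end wobble,
        # star = reads starting within max_overhang of the star arm
        def _offset(a: AlignedRead) -> int:
            return a.start - pre_lo if strand == "+" else pre_hi - a.end

        mature_count = star_count = 0
        for group in by_read.values():
            is_mature = is_star = False
            for a in group:
                if a.strand != strand:
                    continue
                off = _offset(a)
                if abs(off - m0) <= p.wobble:
                    is_mature = True
                elif abs(off - star_lo) <= p.max_overhang:
                    is_star = True
            if is_mature:
                mature_count += group[0].count
            elif is_star:
                star_count += group[0].count
        if star_count < p.min_star_reads:
            return None, "star"
        if mature_count == 0 or (mature_count + star_count) / total < p.min_precision:
            return None, "precision"
        return (
            MirnaLocus(
                precursor=GenomicInterval(scaffold, pre_lo, pre_hi, strand, "miRNA"),
                fold=fold,
                mature_sequence=dominant.sequence,
                star_sequence=star_seq,
                arm=arm,
                strand=strand,
                mature_start=dominant.start,
                mature_count=mature_count,
                star_count=star_count,
                locus_count=total,
            ),
            None,
        )

    for scaffold, block in _blocks(alignments, p.max_gap):
        span_lo = min(a.start for a in block)
        span_hi = max(a.end for a in block)
        interval = GenomicInterval(
            scaffold,
            max(0, span_lo - p.flank),
            min(len(genome[scaffold]), span_hi + p.flank),
            ".",
            "candidate",
        )
        # a read placed several times inside the block (e.g. on a perfect
        # inverted repeat) still counts once
        by_read: dict[str, list[AlignedRead]] = {}
        for a in block:
            by_read.setdefault(a.read_id, []).append(a)
        total = sum(g[0].count for g in by_read.values())
        if span_hi - span_lo > p.precursor_max + 2 * p.flank:
            rejected.append((interval, "span"))
            continue
        if total < p.min_locus_reads:
            rejected.append((interval, "reads"))
            continue
        # dominant read defines mature and strand
        dominant = max(block, key=lambda a: (a.count, -a.start, a.sequence))
        if not (p.mature_min_len <= dominant.length <= p.mature_max_len):
            rejected.append((interval, "mature_length"))
            continue
        # the maximum-pairing fold can be sensitive to the exact window, so
        # precursor boundaries are searched over a few flank extents and the
        # first window satisfying every criterion wins
        locus = None
        first_reason = None
        for flank in (p.flank, max(0, p.flank - 10), p.flank + 10, 0):
            locus, reason = _evaluate(scaffold, block, by_read, total, dominant, flank)
            if first_reason is None:
                first_reason = reason
            if locus is not None:
                break
        if locus is None:
            rejected.append((interval, first_reason))
            continue
        loci.append(locus)

    loci.sort(key=lambda l: (l.precursor.scaffold, l.precursor.start))
    if return_rejected:
        return loci, rejected
    return loci


# ---------------------------------------------------------------------------
# families


@dataclass
class MirnaFamily:
    """miRNAs sharing an identical mature sequence at distinct locations."""

    mature_sequence: str
    members: list[tuple[str, str]]  # (member id, location string)

    @property
    def size(self) -> int:
        return len(self.members)


def group_families(
    records: Sequence[tuple[str, str]] | Sequence[tuple[str, str, str]],
) -> list[MirnaFamily]:
    """Group mature records by identical sequence (U = T, case-insensitive).

    *records* are ``(sequence, location)`` or ``(id, sequence, location)``
    tuples.  Families are returned sorted by descending size, then sequence.
    """
    buckets: dict[str, list[tuple[str, str]]] = {}
    for rec in records:
        if len(rec) == 2:
            seq, loc = rec
            rid = loc
        else:
            rid, seq, loc = rec
        key = canonical(seq)
        buckets.setdefault(key, []).append((rid, loc))
    fams = [MirnaFamily(seq, members) for seq, members in buckets.items()]
    fams.sort(key=lambda f: (-f.size, f.mature_sequence))
    return fams


def family_stats(families: Sequence[MirnaFamily]) -> dict[str, int]:
    """Summary statistics of a family partition."""
    return {
        "n_families": len(families),
        "largest_family": max((f.size for f in families), default=0),
        "n_families_ge2": sum(1 for f in families if f.size >= 2),
        "n_members": sum(f.size for f in families),
    }


# ---------------------------------------------------------------------------
# conservation (pairwise identity)


def global_align_identity(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, float]:
    """Needleman-Wunsch global alignment; returns (score, percent identity).

    Percent identity = matches / alignment columns * 100.  Among co-optimal
    alignments the one with most matches, then fewest columns, is reported
    (additive objectives, so the lexicographic DP is exact).
    """
    a, b = canonical(a), canonical(b)
    n, m = len(a), len(b)
    NEG = float("-inf")
    # cell = (score, matches, -columns), maximized lexicographically
    prev = [(gap * j, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(gap * i, 0, -i)] + [None] * m
        for j in range(1, m + 1):
            diag = prev[j - 1]
            is_match = a[i - 1] == b[j - 1]
            s_diag = (
                diag[0] + (match if is_match else mismatch),
                diag[1] + (1 if is_match else 0),
                diag[2] - 1,
            )
            up = prev[j]
            s_up = (up[0] + gap, up[1], up[2] - 1)
            left = cur[j - 1]
            s_left = (left[0] + gap, left[1], left[2] - 1)
            cur[j] = max(s_diag, s_up, s_left)
        prev = cur
    score, matches, neg_cols = prev[m]
    cols = -neg_cols
    identity = 100.0 * matches / cols if cols else 100.0
    return score, identity


def pairwise_identity_matrix(
    set_a: dict[str, str], set_b: dict[str, str]
) -> pd.DataFrame:
    """Percent-identity matrix between two miRNA sets (rows = set_a)."""
    rows = {}
    for qid in sorted(set_a):
        rows[qid] = {
            sid: global_align_identity(set_a[qid], set_b[sid])[1]
            for sid in sorted(set_b)
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(sorted(set_a), columns=sorted(set_b) if set_b else [])
    df.index.name = "query"
    return df


def max_identity_per_query(matrix: pd.DataFrame) -> pd.Series:
    """Best percent identity of each query against the other set."""
    if matrix.empty or matrix.shape[1] == 0:
        return pd.Series(dtype=float, name="max_identity")
    s = matrix.max(axis=1)
    s.name = "max_identity"
    return s
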