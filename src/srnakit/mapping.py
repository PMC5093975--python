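"""Deterministic placement of small reads on a genome.

Small (18-26 nt) reads are aligned by exact or near-exact matching with
substitutions only — the standard regime for small-RNA data, where indels
are vanishingly rare within a 21-mer.  The implementation uses a k-mer
seed-and-verify index but its output contract is that of a brute-force
scan over every offset and both strands; the test suite enforces this
equivalence against an independent exhaustive oracle.

Externally produced SAM (e.g. bowtie2) can be substituted through
:func:`srnakit.core_io.load_alignments`.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from ._seq import revcomp
from .core_io import AlignedRead, SmallRead

logger = logging.getLogger(__name__)


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c


class GenomeIndex:
    """Exact k-mer index over the forward strand of a genome.

    k-mers are 2-bit encoded into integers and kept in a sorted array with
    parallel position arrays, so lookups are two binary searches and the
    memory footprint stays linear in genome size.  Minus-strand hits are
    found by searching the reverse complement of the query.
    """

    def __init__(self, genome: dict[str, str], k: int = 12) -> None:
        if k < 1 or k > 30:
            raise ValueError("k must be in 1..30")
        self.genome = genome
        self.k = k
        self._names = list(genome)
        keys = []
        scaffold_ids = []
        positions = []
        for sid, name in enumerate(self._names):
            codes = _BASE_CODE[np.frombuffer(genome[name].encode(), dtype=np.uint8)]
            n = len(codes)
            if n < k:
                continue
            valid = codes >= 0
            vals = np.zeros(n - k + 1, dtype=np.int64)
            ok = np.ones(n - k + 1, dtype=bool)
            for j in range(k):
                vals = vals * 4 + np.where(valid[j : n - k + 1 + j], codes[j : n - k + 1 + j], 0)
                ok &= valid[j : n - k + 1 + j]
            keys.append(vals[ok])
            positions.append(np.nonzero(ok)[0])
            scaffold_ids.append(np.full(int(ok.sum()), sid, dtype=np.int32))
        if keys:
            allkeys = np.concatenate(keys)
            order = np.argsort(allkeys, kind="stable")
            self._keys = allkeys[order]
            self._pos = np.concatenate(positions)[order]
            self._sid = np.concatenate(scaffold_ids)[order]
        else:
            self._keys = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
            self._sid = np.empty(0, dtype=np.int32)

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        codes = _BASE_CODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
        if len(codes) != self.k or (codes < 0).any():
            return []
        val = 0
        for c in codes:
            val = val * 4 + int(c)
        lo = np.searchsorted(self._keys, val, side="left")
        hi = np.searchsorted(self._keys, val, side="right")
        return [
            (self._names[self._sid[i]], int(self._pos[i])) for i in range(lo, hi)
        ]


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance, short-circuiting once *limit* is exceeded."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _place_sequence(
    seq: str,
    index: GenomeIndex,
    max_mismatches: int,
) -> list[tuple[str, int, str, int]]:
    """All placements of one sequence: (scaffold, start, strand, mismatches).

    Seeds are ``m + 1`` non-overlapping k-chunks of the query; with ``m``
    allowed substitutions at least one chunk is exact (pigeonhole), so
    seeding on every chunk loses nothing.  Requires ``k * (m+1) <= len``.
    """
    k = index.k
    L = len(seq)
    n_chunks = max_mismatches + 1
    if k * n_chunks > L:
        raise ValueError(
            f"index k={k} too large for {L}-nt reads at "
            f"max_mismatches={max_mismatches}; need k*(m+1) <= read length"
        )
    offsets = [j * k for j in range(n_chunks)]
    hits: dict[tuple[str, int, str], int] = {}
    for strand in "+-":
        query = seq if strand == "+" else revcomp(seq)
        if "N" in query and max_mismatches == 0:
            continue
        seen_starts: set[tuple[str, int]] = set()
        for off in offsets:
            kmer = query[off : off + k]
            if "N" in kmer:
                continue
            for scaffold, pos in index.seed_hits(kmer):
                start = pos - off
                if start < 0:
                    continue
                ref = index.genome[scaffold]
                if start + L > len(ref):
                    continue
                if (scaffold, start) in seen_starts:
                    continue
                seen_starts.add((scaffold, start))
                mm = _mismatches(query, ref[start : start + L], max_mismatches)
                if mm <= max_mismatches:
                    hits[(scaffold, start, strand)] = mm
    return [(sc, st, strand, mm) for (sc, st, strand), mm in hits.items()]


def map_reads(
    reads: Sequence[SmallRead],
    genome: dict[str, str],
    max_mismatches: int = 0,
    max_hits: int = 50,
    index: GenomeIndex | None = None,
) -> list[AlignedRead]:
    """Place reads on the genome, reporting all hits on both strands.

    Reads with more than *max_hits* placements are dropped (and counted in
    the log); every retained placement carries the read's total ``n_hits``.
    Reads containing N are unmapped when ``max_mismatches == 0``.

    Returns placements sorted by (scaffold, start, strand, read_id) for
    deterministic downstream processing.
    """
    if reads and (index is None or index.k * (max_mismatches + 1) > min(len(r) for r in reads)):
        # choose k so the pigeonhole seeding stays complete for the
        # shortest read at the requested mismatch budget
        min_len = min(len(r) for r in reads)
        k = min(12, min_len // (max_mismatches + 1))
        if k < 6:
            raise ValueError(
                f"reads of {min_len} nt cannot be seeded at "
                f"max_mismatches={max_mismatches}"
            )
        if index is not None:
            logger.info("rebuilding genome index with k=%d", k)
        index = GenomeIndex(genome, k=k)
    out: list[AlignedRead] = []
    n_dropped = 0
    cache: dict[str, list[tuple[str, int, str, int]]] = {}
    for read in reads:
        if len(read) > 40:
            raise ValueError(f"read {read.read_id} longer than 40 nt")
        placements = cache.get(read.sequence)
        if placements is None:
            placements = _place_sequence(read.sequence, index, max_mismatches)
            cache[read.sequence] = placements
        if not placements:
            continue
        if len(placements) > max_hits:
            n_dropped += 1
            continue
        n = len(placements)
        for scaffold, start, strand, mm in placements:
            out.append(
                AlignedRead(
                    read_id=read.read_id,
                    scaffold=scaffold,
                    start=start,
                    strand=strand,
                    length=len(read),
                    mismatch_count=mm,
                    n_hits=n,
                    count=read.count,
                    sequence=read.sequence,
                )
            )
    if n_dropped:
        logger.info("dropped %d reads exceeding max_hits=%d", n_dropped, max_hits)
    out.sort(key=lambda a: (a.scaffold, a.start, a.strand, a.read_id))
    return out


def brute_force_map(
    reads: Iterable[SmallRead],
    genome: dict[str, str],
    max_mismatches: int = 0,
) -> set[tuple[str, str, int, str, int]]:
    """Exhaustive reference scan: every offset, both strands.

    Returns tuples ``(read_id, scaffold, start, strand, mismatches)``.
    Quadratic; intended as the correctness oracle for :func:`map_reads`
    at test scale, not for production use.
    """
    result = set()
    for read in reads:
        L = len(read)
        for strand in "+-":
            query = read.sequence if strand == "+" else revcomp(read.sequence)
            for scaffold, ref in genome.items():
                for start in range(len(ref) - L + 1):
                    mm = _mismatches(query, ref[start : start + L], max_mismatches)
                    if mm <= max_mismatches:
                        result.add((read.read_id, scaffold, start, strand, mm))
    return result
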