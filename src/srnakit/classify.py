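"""Hierarchical read categorization, strand correction, hotspot detection.

Every mapped read gets exactly one functional class.  When a read has
several genomic placements (or one placement under several features), the
highest-precedence class among all of them wins.  The default precedence
puts the rRNA/tRNA contaminant screen first and keeps miRNA ahead of
repeat, so miRNAs encoded inside transposons are reported as miRNAs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core_io import AlignedRead, AnnotationSet, GenomicInterval

CLASSES = (
    "rRNA_tRNA",
    "miRNA",
    "phased",
    "repeat",
    "mRNA_sense",
    "mRNA_antisense",
    "intergenic",
)

DEFAULT_PRECEDENCE = CLASSES  # ordered highest first


class _IntervalLookup:
    """Sorted-interval overlap queries per scaffold (reads are tiny, so a
    bisect over start-sorted intervals with a max-end cursor suffices)."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_scaffold: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
        tmp: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            tmp.setdefault(iv.scaffold, []).append(iv)
        for scaffold, ivs in tmp.items():
            ivs.sort(key=lambda x: (x.start, x.end))
            self._by_scaffold[scaffold] = ([iv.start for iv in ivs], ivs)
        self._max_len = {
            sc: max((len(iv) for iv in ivs[1]), default=0)
            for sc, ivs in self._by_scaffold.items()
        }

    def overlapping(self, scaffold: str, start: int, end: int) -> list[GenomicInterval]:
        entry = self._by_scaffold.get(scaffold)
        if entry is None:
            return []
        starts, ivs = entry
        lo = bisect.bisect_left(starts, start - self._max_len[scaffold])
        hi = bisect.bisect_left(starts, end)
        return [iv for iv in ivs[lo:hi] if iv.start < end and start < iv.end]


@dataclass
class CategoryReport:
    """Per-class counts/fractions plus the per-read assignment table."""

    counts: dict[str, int]
    fractions_all: dict[str, float]          # over all mapped reads
    fractions_assigned: dict[str, float]     # over reads with a known class
    assignments: pd.DataFrame                # read_id, class, count
    total_reads: int


def assign_categories(
    alignments: Sequence[AlignedRead],
    annotations: AnnotationSet,
    mirna_loci: Sequence[GenomicInterval] = (),
    phased_loci: Sequence[GenomicInterval] = (),
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> CategoryReport:
    """Assign every mapped read its highest-precedence class.

    mRNA reads are split by strand agreement with the exon; reads
    overlapping nothing are intergenic.  Counts are weighted by collapsed
    multiplicity; a multi-placement read contributes once.
    """
    if sorted(precedence) != sorted(CLASSES):
        raise ValueError(f"precedence must be a permutation of {CLASSES}")
    rank = {c: i for i, c in enumerate(precedence)}

    lookups = {
        "rRNA_tRNA": _IntervalLookup(annotations.by_class("rRNA_tRNA_ref")),
        "repeat": _IntervalLookup(annotations.by_class("repeat")),
        "mRNA": _IntervalLookup(annotations.by_class("mRNA_exon")),
        "miRNA": _IntervalLookup(mirna_loci),
        "phased": _IntervalLookup(phased_loci),
    }

    best: dict[str, tuple[int, int]] = {}  # read_id -> (rank, count)
    for a in alignments:
        cls = "intergenic"
        r = rank[cls]

        def consider(c: str) -> None:
            nonlocal cls, r
            if rank[c] < r:
                cls, r = c, rank[c]

        if lookups["rRNA_tRNA"].overlapping(a.scaffold, a.start, a.end):
            consider("rRNA_tRNA")
        if lookups["miRNA"].overlapping(a.scaffold, a.start, a.end):
            consider("miRNA")
        if lookups["phased"].overlapping(a.scaffold, a.start, a.end):
            consider("phased")
        if lookups["repeat"].overlapping(a.scaffold, a.start, a.end):
            consider("repeat")
        exons = lookups["mRNA"].overlapping(a.scaffold, a.start, a.end)
        if exons:
            if any(e.strand == a.strand or e.strand == "." for e in exons):
                consider("mRNA_sense")
            else:
                consider("mRNA_antisense")
        prev = best.get(a.read_id)
        if prev is None or r < prev[0]:
            best[a.read_id] = (r, a.count)

    counts = {c: 0 for c in CLASSES}
    rows = []
    inv_rank = {i: c for c, i in rank.items()}
    for read_id, (r, count) in best.items():
        cls = inv_rank[r]
        counts[cls] += count
        rows.append((read_id, cls, count))
    total = sum(counts.values())
    assigned_total = total - counts["intergenic"]
    fractions_all = {c: (counts[c] / total if total else 0.0) for c in CLASSES}
    fractions_assigned = {
        c: (counts[c] / assigned_total if assigned_total else 0.0)
        for c in CLASSES
        if c != "intergenic"
    }
    table = pd.DataFrame(rows, columns=["read_id", "class", "count"]).sort_values(
        "read_id", kind="stable", ignore_index=True
    )
    return CategoryReport(counts, fractions_all, fractions_assigned, table, total)


def correct_transcript_strand(plus_reads: int, minus_reads: int) -> str:
    """Orient a transcript when one strand has at least twice the reads.

    Returns ``"plus"``, ``"minus"`` or ``"unassigned"`` (no correction
    possible).  The ratio boundary is inclusive: (10, 5) -> plus.
    """
    if plus_reads < 0 or minus_reads < 0:
        raise ValueError("read counts must be non-negative")
    if plus_reads > 0 and plus_reads >= 2 * minus_reads:
        return "plus"
    if minus_reads > 0 and minus_reads >= 2 * plus_reads:
        return "minus"
    return "unassigned"


@dataclass
class HotspotBin:
    """One fixed-width genomic bin of intergenic read density."""

    scaffold: str
    bin_start: int              # offset within the scaffold
    bin_end: int
    concat_offset: int          # offset in the concatenated-genome frame
    read_count: int
    fraction_of_intergenic: float
    fraction_of_total: float


def detect_hotspots(
    intergenic_alignments: Sequence[AlignedRead],
    scaffold_lengths: dict[str, int],
    bin_width: int = 50_000,
    top_n: Optional[int] = None,
    min_count: Optional[int] = None,
    total_reads: Optional[int] = None,
) -> list[HotspotBin]:
    """Bin intergenic reads into fixed-width windows and rank the bins.

    Scaffolds are processed in *scaffold_lengths* order (the concatenated
    frame of the genome file); bins never span scaffold boundaries, so
    terminal bins may be short.  A read falls in the bin containing its 5'
    start, weighted by collapsed multiplicity.  The hotspot set is the
    *top_n* highest bins, or all bins with >= *min_count* reads; with
    neither given, all non-empty bins are returned ranked.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    multi_seen: set[str] = set()
    bin_counts: dict[tuple[str, int], int] = {}
    intergenic_total = 0
    for a in intergenic_alignments:
        # one contribution per read: first placement in input order
        if a.read_id in multi_seen:
            continue
        multi_seen.add(a.read_id)
        b = a.five_prime // bin_width
        bin_counts[(a.scaffold, b)] = bin_counts.get((a.scaffold, b), 0) + a.count
        intergenic_total += a.count

    offsets: dict[str, int] = {}
    running = 0
    for scaffold, length in scaffold_lengths.items():
        offsets[scaffold] = running
        running += length

    bins = []
    denom_total = total_reads if total_reads else intergenic_total
    for (scaffold, b), count in bin_counts.items():
        start = b * bin_width
        end = min(start + bin_width, scaffold_lengths.get(scaffold, start + bin_width))
        bins.append(
            HotspotBin(
                scaffold=scaffold,
                bin_start=start,
                bin_end=end,
                concat_offset=offsets.get(scaffold, 0) + start,
                read_count=count,
                fraction_of_intergenic=(
                    count / intergenic_total if intergenic_total else 0.0
                ),
                fraction_of_total=count / denom_total if denom_total else 0.0,
            )
        )
    bins.sort(key=lambda h: (-h.read_count, h.scaffold, h.bin_start))
    if min_count is not None:
        bins = [h for h in bins if h.read_count >= min_count]
    if top_n is not None:
        bins = bins[:top_n]
    return bins
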