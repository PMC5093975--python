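"""Core record types and readers/writers for the standard formats.

Every module in the package exchanges data through the types defined here:

* :class:`SmallRead` — a (possibly count-collapsed) small-RNA sequence,
* :class:`GenomicInterval` — a strand-aware 0-based half-open interval,
* :class:`AnnotationSet` — intervals grouped by feature class,
* :class:`AlignedRead` — one genomic placement of a read.

Coordinates are 0-based half-open *everywhere* inside the package;
conversions (GFF3 is 1-based inclusive) happen only in this module, at the
I/O boundary.  Sequences are stored in a canonical uppercase DNA alphabet
(U = T); writers choose the output lettering.
"""

from __future__ import annotations

import collections
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO

from ._seq import canonical, to_rna

#: feature classes an AnnotationSet distinguishes
ANNOTATION_CLASSES = ("mRNA_exon", "rRNA_tRNA_ref", "repeat", "other")

#: default mapping from GFF3/BED feature types to annotation classes
DEFAULT_CLASS_TABLE = {
    "exon": "mRNA_exon",
    "mRNA_exon": "mRNA_exon",
    "mRNA": "mRNA_exon",
    "rRNA": "rRNA_tRNA_ref",
    "tRNA": "rRNA_tRNA_ref",
    "rRNA_tRNA_ref": "rRNA_tRNA_ref",
    "repeat": "repeat",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
    "transposable_element": "repeat",
}

_COLLAPSED_RE = re.compile(r"_x(\d+)$")


class ParseError(ValueError):
    """Raised when an input file is syntactically invalid."""


@dataclass
class SmallRead:
    """A small-RNA sequence with collapsed multiplicity.

    Parameters
    ----------
    read_id : str
        Record identifier.
    sequence : str
        Read sequence; stored canonically (uppercase DNA, U -> T).
    count : int
        Collapsed multiplicity (>= 1).
    qualities : list of int, optional
        Phred scores, same length as ``sequence``.
    """

    read_id: str
    sequence: str
    count: int = 1
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.sequence = canonical(self.sequence)
        if self.count < 1:
            raise ValueError(f"read {self.read_id}: count must be >= 1")
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: qualities length != sequence length"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def rna(self) -> str:
        """The sequence with RNA lettering."""
        return to_rna(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware 0-based half-open genomic interval."""

    scaffold: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    name: str = ""  # e.g. repeat family or feature id

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, scaffold: str, start: int, end: int) -> bool:
        return (
            scaffold == self.scaffold and start < self.end and self.start < end
        )


class AnnotationSet:
    """Genomic intervals grouped by feature class.

    Classes are ``mRNA_exon``, ``rRNA_tRNA_ref``, ``repeat`` and ``other``;
    repeat intervals carry their family in :attr:`GenomicInterval.name`.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._by_class: dict[str, list[GenomicInterval]] = {
            c: [] for c in ANNOTATION_CLASSES
        }
        for iv in intervals:
            self.add(iv)

    def add(self, interval: GenomicInterval) -> None:
        cls = interval.label if interval.label in self._by_class else "other"
        self._by_class[cls].append(interval)

    def by_class(self, cls: str) -> list[GenomicInterval]:
        return list(self._by_class[cls])

    def __iter__(self):
        for cls in ANNOTATION_CLASSES:
            yield from self._by_class[cls]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_class.values())

    def scaffolds(self) -> set[str]:
        return {iv.scaffold for iv in self}

    def validate_against(self, genome: dict[str, str]) -> None:
        """Check that every interval fits on a scaffold of *genome*."""
        for iv in self:
            if iv.scaffold not in genome:
                raise ValueError(f"unknown scaffold {iv.scaffold!r}")
            if iv.end > len(genome[iv.scaffold]):
                raise ValueError(
                    f"interval {iv.scaffold}:{iv.start}-{iv.end} exceeds "
                    f"scaffold length {len(genome[iv.scaffold])}"
                )


@dataclass(frozen=True)
class AlignedRead:
    """One genomic placement of a small read.

    ``start`` is the 0-based leftmost genomic coordinate on the forward
    strand regardless of the read's strand (SAM convention).  ``count``
    carries the collapsed multiplicity of the underlying read so that
    downstream tallies can weight placements.
    """

    read_id: str
    scaffold: str
    start: int
    strand: str
    length: int
    mismatch_count: int = 0
    n_hits: int = 1
    count: int = 1
    sequence: str = ""

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# sequence I/O


def load_sequences(path, format: str = "fasta") -> list[SmallRead]:
    """Load reads from FASTA, FASTQ (Phred+33) or collapsed FASTA.

    Collapsed FASTA encodes the multiplicity in the header as ``id_xCOUNT``.
    T and U are equivalent on input.  An empty file yields an empty list.
    """
    path = Path(path)
    if format not in {"fasta", "fastq", "collapsed_fasta"}:
        raise ValueError(f"unknown sequence format {format!r}")
    bioformat = "fastq" if format == "fastq" else "fasta"
    reads: list[SmallRead] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), bioformat)):
            count = 1
            if format == "collapsed_fasta":
                m = _COLLAPSED_RE.search(rec.id)
                if m:
                    count = int(m.group(1))
            quals = None
            if format == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            try:
                reads.append(
                    SmallRead(rec.id, str(rec.seq), count=count, qualities=quals)
                )
            except ValueError as exc:
                raise ParseError(f"{path}, record {i + 1}: {exc}") from exc
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_sequences(
    reads: Sequence[SmallRead],
    path,
    format: str = "fasta",
    alphabet: str = "dna",
) -> None:
    """Write reads as FASTA, collapsed FASTA or FASTQ (Phred+33)."""
    letter = (lambda s: s) if alphabet == "dna" else to_rna
    with open(path, "w") as fh:
        for r in reads:
            if format == "fasta":
                fh.write(f">{r.read_id}\n{letter(r.sequence)}\n")
            elif format == "collapsed_fasta":
                rid = r.read_id
                if not _COLLAPSED_RE.search(rid):
                    rid = f"{rid}_x{r.count}"
                fh.write(f">{rid}\n{letter(r.sequence)}\n")
            elif format == "fastq":
                quals = r.qualities or [40] * len(r)
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{r.read_id}\n{letter(r.sequence)}\n+\n{qstr}\n")
            else:
                raise ValueError(f"unknown sequence format {format!r}")


def load_fasta(path) -> dict[str, str]:
    """Load a multi-FASTA (e.g. a genome) as an ordered name -> sequence dict."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = canonical(str(rec.seq))
    return genome


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation I/O


def load_annotations(
    path,
    format: str = "gff3",
    class_table: Optional[dict[str, str]] = None,
) -> AnnotationSet:
    """Load a GFF3 (1-based inclusive) or BED (0-based half-open) file.

    Feature types are mapped to annotation classes through *class_table*
    (defaults to :data:`DEFAULT_CLASS_TABLE`); unmapped types become
    ``other``.  All intervals are normalized to 0-based half-open.
    """
    table = DEFAULT_CLASS_TABLE if class_table is None else class_table
    annset = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if format == "gff3":
                    if len(cols) < 8:
                        raise ParseError("expected >= 8 GFF3 columns")
                    scaffold, _, ftype = cols[0], cols[1], cols[2]
                    start = int(cols[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(cols[4])
                    strand = cols[6] if cols[6] in "+-" else "."
                    name = ""
                    if len(cols) > 8:
                        for kv in cols[8].split(";"):
                            if kv.startswith(("Name=", "ID=", "family=")):
                                name = kv.split("=", 1)[1]
                                break
                elif format == "bed":
                    if len(cols) < 3:
                        raise ParseError("expected >= 3 BED columns")
                    scaffold = cols[0]
                    start, end = int(cols[1]), int(cols[2])
                    name = cols[3] if len(cols) > 3 else ""
                    strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
                    ftype = cols[6] if len(cols) > 6 else name
                else:
                    raise ValueError(f"unknown annotation format {format!r}")
                if end <= start:
                    raise ParseError(f"end <= start after normalization ({start},{end})")
                label = table.get(ftype, table.get(name, "other"))
                annset.add(
                    GenomicInterval(scaffold, start, end, strand, label, name)
                )
            except (ParseError, ValueError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return annset


def write_annotations(annset: AnnotationSet, path, format: str = "bed") -> None:
    """Write an AnnotationSet as BED6(+1 feature type) or GFF3."""
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
        for iv in annset:
            if format == "bed":
                fh.write(
                    "\t".join(
                        [
                            iv.scaffold,
                            str(iv.start),
                            str(iv.end),
                            iv.name or iv.label,
                            "0",
                            iv.strand,
                            iv.label,
                        ]
                    )
                    + "\n"
                )
            elif format == "gff3":
                attrs = f"Name={iv.name}" if iv.name else "."
                fh.write(
                    "\t".join(
                        [
                            iv.scaffold,
                            "srnakit",
                            iv.label or "region",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
            else:
                raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# alignment I/O


def load_alignments(path, logger=None) -> list[AlignedRead]:
    """Load placements from a SAM/BAM file.

    Unmapped records are skipped.  ``n_hits`` is taken from the NH tag when
    present, otherwise recomputed by grouping records on read id.  Records
    whose CIGAR contains operations a short ungapped read cannot produce
    (N, P) are skipped with a warning.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    placements: list[AlignedRead] = []
    needs_nh: list[int] = []
    with pysam.AlignmentFile(str(path), mode) as sam:
        if not sam.header.references:
            raise ParseError(f"{path}: SAM header names no reference scaffolds")
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.cigartuples and any(op in (3, 6) for op, _ in rec.cigartuples):
                if logger is not None:
                    logger.warning("skipping %s: unsupported CIGAR", rec.query_name)
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            seq = rec.query_sequence or ""
            count = 1
            m = _COLLAPSED_RE.search(rec.query_name or "")
            if m:
                count = int(m.group(1))
            if nh is None:
                needs_nh.append(len(placements))
            placements.append(
                AlignedRead(
                    read_id=rec.query_name,
                    scaffold=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    length=rec.query_length or len(seq),
                    mismatch_count=int(nm),
                    n_hits=int(nh) if nh is not None else 1,
                    count=count,
                    sequence=canonical(seq) if seq else "",
                )
            )
    if needs_nh:
        tally = collections.Counter(placements[i].read_id for i in needs_nh)
        for i in needs_nh:
            p = placements[i]
            placements[i] = AlignedRead(
                p.read_id, p.scaffold, p.start, p.strand, p.length,
                p.mismatch_count, tally[p.read_id], p.count, p.sequence,
            )
    return placements


def write_sam(
    alignments: Sequence[AlignedRead], genome: dict[str, str], path
) -> None:
    """Export placements as a minimal SAM file (sequence-level only)."""
    from ._seq import revcomp

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            seq = a.sequence or genome[a.scaffold][a.start : a.end]
            if a.strand == "-" and not a.sequence:
                seq = revcomp(seq)
            fh.write(
                "\t".join(
                    [
                        a.read_id,
                        str(flag),
                        a.scaffold,
                        str(a.start + 1),
                        "255",
                        f"{a.length}M",
                        "*",
                        "0",
                        "0",
                        seq,
                        "*",
                        f"NH:i:{a.n_hits}",
                        f"NM:i:{a.mismatch_count}",
                    ]
                )
                + "\n"
            )


def collapse_reads(reads: Iterable[SmallRead]) -> list[SmallRead]:
    """Collapse identical sequences, summing counts (qualities dropped).

    Output ids follow the ``seqN_xCOUNT`` convention, ordered by
    descending count then sequence for determinism.
    """
    tally: collections.Counter[str] = collections.Counter()
    for r in reads:
        tally[r.sequence] += r.count
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        SmallRead(f"seq{i + 1}_x{count}", seq, count=count)
        for i, (seq, count) in enumerate(ordered)
    ]
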