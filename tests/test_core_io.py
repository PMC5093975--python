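"""Record types, format readers/writers and coordinate conventions."""

import pytest
from hypothesis import given, settings, strategies as st

from srnakit import core_io
from srnakit.core_io import (
    AlignedRead,
    AnnotationSet,
    GenomicInterval,
    ParseError,
    SmallRead,
    collapse_reads,
    load_alignments,
    load_annotations,
    load_sequences,
    write_annotations,
    write_sequences,
)


class TestSmallRead:
    def test_rna_input_is_canonicalized(self):
        r = SmallRead("r1", "UUAGUGAGAGUCCAAUUAAUU")
        assert len(r) == 21 and r.count == 1
        assert r.sequence == "TTAGTGAGAGTCCAATTAATT"
        assert r.rna == "UUAGUGAGAGUCCAAUUAAUU"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(read_id="r", sequence="ACGT", count=0),
            dict(read_id="r", sequence=""),
            dict(read_id="r", sequence="ACGT", qualities=[40, 40]),
            dict(read_id="r", sequence="ACXT"),
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SmallRead(**kwargs)


class TestSequenceIO:
    def test_fasta_and_collapsed_and_fastq(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">r1\nUUAGUGAGAGUCCAAUUAAUU\n>s7_x42\nACGTACGTACGTACGTACGT\n")
        plain = load_sequences(p, "fasta")
        assert [r.count for r in plain] == [1, 1]
        collapsed = load_sequences(p, "collapsed_fasta")
        assert collapsed[1].count == 42
        q = tmp_path / "in.fq"
        q.write_text("@r1\nACGT\n+\nIIII\n")
        fq = load_sequences(q, "fastq")
        assert fq[0].qualities == [40, 40, 40, 40]

    def test_empty_file_is_empty_list(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert load_sequences(p, "fasta") == []

    def test_malformed_record_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.fq"
        p.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(ParseError):
            load_sequences(p, "fastq")

    def test_write_read_round_trip(self, tmp_path):
        reads = [SmallRead("a_x3", "ACGTACGTACGTACGTAC", count=3),
                 SmallRead("b_x1", "TTTTGGGGCCCCAAAATT", count=1)]
        p = tmp_path / "rt.fa"
        write_sequences(reads, p, "collapsed_fasta")
        back = load_sequences(p, "collapsed_fasta")
        assert [(r.read_id, r.sequence, r.count) for r in back] == [
            (r.read_id, r.sequence, r.count) for r in reads
        ]

    def test_collapse_sums_counts(self):
        reads = [SmallRead("a", "ACGTACGTACGTACGTAC"),
                 SmallRead("b", "ACGTACGTACGTACGTAC", count=2),
                 SmallRead("c", "TTTTGGGGCCCCAAAATT")]
        col = collapse_reads(reads)
        assert sum(r.count for r in col) == 4
        assert col[0].count == 3  # most abundant first


class TestAnnotations:
    def test_gff3_coordinates_are_decremented(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\tsrc\texon\t1\t10\t.\t+\t.\tID=x\n")
        annset = load_annotations(p, "gff3")
        iv = annset.by_class("mRNA_exon")[0]
        assert (iv.start, iv.end) == (0, 10)

    def test_class_table_lookup(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\tsrc\texon\t5\t30\t.\t-\t.\t.\n")
        annset = load_annotations(p, "gff3", class_table={"exon": "mRNA_exon"})
        assert len(annset.by_class("mRNA_exon")) == 1

    def test_invalid_interval_raises(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t10\tx\t0\t+\n")
        with pytest.raises(ParseError):
            load_annotations(p, "bed")

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 5000),
                st.integers(1, 300),
                st.sampled_from("+-."),
                st.sampled_from(["mRNA_exon", "repeat", "rRNA_tRNA_ref", "other"]),
            ),
            max_size=20,
        )
    )
    def test_bed_and_gff3_round_trip(self, tmp_path_factory, raw):
        """Randomized write -> read identity through both formats."""
        intervals = [
            GenomicInterval(sc, s, s + ln, strand, label, name=label)
            for sc, s, ln, strand, label in raw
        ]
        annset = AnnotationSet(intervals)
        tmp = tmp_path_factory.mktemp("rt")
        table = {c: c for c in ("mRNA_exon", "repeat", "rRNA_tRNA_ref", "other")}
        for fmt in ("bed", "gff3"):
            path = tmp / f"x.{fmt}"
            write_annotations(annset, path, fmt)
            back = load_annotations(path, fmt, class_table=table)
            key = lambda iv: (iv.scaffold, iv.start, iv.end, iv.strand, iv.label)
            assert sorted(map(key, back)) == sorted(map(key, annset))


class TestAlignments:
    SAM = (
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t51\t255\t21M\t*\t0\t0\tACGTACGTACGTACGTACGTA\t*\n"
        "r2\t16\tchr1\t101\t255\t21M\t*\t0\t0\tACGTACGTACGTACGTACGTA\t*\n"
        "r2\t0\tchr1\t301\t255\t21M\t*\t0\t0\tTACGTTACGTACGTACGTACG\t*\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTACGTACGTACGTA\t*\n"
    )

    def test_sam_conventions(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(self.SAM)
        alns = load_alignments(p)
        by_id = {}
        for a in alns:
            by_id.setdefault(a.read_id, []).append(a)
        assert "r3" not in by_id  # unmapped skipped
        (r1,) = by_id["r1"]
        assert (r1.start, r1.strand) == (50, "+")
        minus = [a for a in by_id["r2"] if a.strand == "-"][0]
        assert minus.start == 100
        assert all(a.n_hits == 2 for a in by_id["r2"])  # grouped without NH

    def test_sam_round_trip(self, tmp_path):
        genome = {"chr1": "ACGT" * 300}
        alns = [
            AlignedRead("x", "chr1", 100, "+", 20, 0, 1, 1, genome["chr1"][100:120]),
            AlignedRead("y", "chr1", 60, "-", 20, 0, 1, 1, "A" * 20),
        ]
        p = tmp_path / "rt.sam"
        core_io.write_sam(alns, genome, p)
        back = load_alignments(p)
        assert [(a.read_id, a.start, a.strand) for a in back] == [
            ("x", 100, "+"), ("y", 60, "-"),
        ]
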