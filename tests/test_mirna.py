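"""Hairpin folding, the miRNA locus caller, families and conservation."""

import itertools

import numpy as np
import pytest

from srnakit._seq import PAIRABLE, revcomp
from srnakit.mirna import (
    MIN_LOOP,
    MirnaCallerParams,
    call_mirna_loci,
    family_stats,
    fold_hairpin,
    global_align_identity,
    group_families,
    max_pairs_alternative,
    pairwise_identity_matrix,
)
from srnakit.synthetic import synthetic_mirna_catalogue


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFolding:
    def test_perfect_inverted_repeat(self):
        fold = fold_hairpin("GGGGAAAACCCC")
        assert fold.n_pairs == 4
        assert fold.dot_bracket == "((((....))))"

    def test_no_complementarity(self):
        assert fold_hairpin("A" * 40).n_pairs == 0

    def test_non_alphabet_rejected(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGU#ACGU")

    def test_structures_are_nested_and_legal(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = _random_seq(rng, int(rng.integers(20, 61)))
            fold = fold_hairpin(seq)
            seen = set()
            for i, j in fold.pairs:
                assert j - i > MIN_LOOP
                assert (seq[i], seq[j]) in PAIRABLE
                assert i not in seen and j not in seen
                seen |= {i, j}
            # nestedness: dot-bracket is balanced
            depth = 0
            for ch in fold.dot_bracket:
                depth += ch == "("
                depth -= ch == ")"
                assert depth >= 0
            assert depth == 0

    def test_pair_count_matches_alternative_dp(self):
        """Two structurally different recurrences agree on max pairing."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            seq = _random_seq(rng, int(rng.integers(10, 61)))
            assert fold_hairpin(seq).n_pairs == max_pairs_alternative(seq)

    def test_pair_count_matches_exhaustive_enumeration(self):
        """Tiny instances against brute-force enumeration of all nested
        structures."""

        def best(seq, i, j):
            if j - i <= MIN_LOOP:
                return 0
            score = best(seq, i + 1, j)
            for k in range(i + MIN_LOOP + 1, j + 1):
                if (seq[i], seq[k]) in PAIRABLE:
                    score = max(
                        score, 1 + best(seq, i + 1, k - 1) + best(seq, k + 1, j)
                    )
            return score

        rng = np.random.default_rng(8)
        for _ in range(15):
            seq = _random_seq(rng, int(rng.integers(8, 19)))
            assert fold_hairpin(seq).n_pairs == best(seq, 0, len(seq) - 1)


class TestCaller:
    def test_planted_loci_recovered_with_mature_sequence(
        self, small_bundle, small_alignments
    ):
        cfg, genome, annotations, truth, reads, table = small_bundle
        loci = call_mirna_loci(small_alignments, genome)
        planted = {
            (m.precursor.scaffold, m.mature_start): m.mature_sequence
            for m in truth.mirna_loci
        }
        recovered = 0
        for locus in loci:
            key = (locus.precursor.scaffold, locus.mature_start)
            assert key in planted, f"false locus at {key}"
            assert planted[key] == locus.mature_sequence
            recovered += 1
        assert recovered >= 0.8 * len(truth.mirna_loci)
        assert all(0 < l.precision <= 1 for l in loci)

    def test_tir_hairpin_called_inside_repeat(self, small_bundle, small_alignments):
        """A TIR transposon folding into a qualifying hairpin yields a
        miRNA call inside the repeat interval."""
        cfg, genome, annotations, truth, *_ = small_bundle
        loci = call_mirna_loci(small_alignments, genome)
        tirs = [m for m in truth.mirna_loci if m.in_repeat]
        called = {(l.precursor.scaffold, l.mature_start) for l in loci}
        assert any((t.precursor.scaffold, t.mature_start) in called for t in tirs)

    def test_scattered_reads_rejected_for_precision(self):
        rng = np.random.default_rng(0)
        genome = {"c": _random_seq(rng, 2000)}
        from srnakit.core_io import AlignedRead

        alns = [
            AlignedRead(f"r{i}", "c", 900 + 7 * i, "+", 21, 0, 1, 2)
            for i in range(20)
        ]
        loci, rejected = call_mirna_loci(alns, genome, return_rejected=True)
        assert loci == []
        assert rejected and all(
            reason in {"precision", "pairing", "structure", "star", "span"}
            for _, reason in rejected
        )


class TestFamilies:
    def test_catalogue_census(self):
        """Grouping the reference-shaped catalogue reproduces its census:
        490 records, 324 families, largest 48, 67 with >= 2 members."""
        fams = group_families(synthetic_mirna_catalogue())
        stats = family_stats(fams)
        assert stats == {
            "n_families": 324,
            "largest_family": 48,
            "n_families_ge2": 67,
            "n_members": 490,
        }

    def test_all_distinct_yields_singletons(self):
        rng = np.random.default_rng(1)
        recs = [(_random_seq(rng, 21), f"loc{i}") for i in range(30)]
        fams = group_families(recs)
        assert len(fams) == 30 and all(f.size == 1 for f in fams)

    def test_same_sequence_three_locations(self):
        recs = [("ACGUACGUACGUACGUACGUA", f"loc{i}") for i in range(3)]
        (fam,) = group_families(recs)
        assert fam.size == 3

    def test_u_t_equivalence_and_partition(self):
        recs = [("acguACGU" * 2, "a"), ("ACGTACGT" * 2, "b"), ("GGGGCCCC" * 2, "c")]
        fams = group_families(recs)
        assert family_stats(fams)["n_members"] == 3
        assert len(fams) == 2


class TestIdentity:
    def test_identical_sequences(self):
        _, ident = global_align_identity("ACGUACGUACGUACGUACGUA", "ACGTACGTACGTACGTACGTA")
        assert ident == pytest.approx(100.0)

    def test_disjoint_sequences(self):
        _, ident = global_align_identity("A" * 21, "C" * 21)
        assert ident == pytest.approx(0.0)

    def test_matrix_shape_and_bounds(self):
        a = {"m1": "ACGUACGUACGUACGUACGUA", "m2": "UUUUGGGGCCCCAAAAUUUUG"}
        b = {"x": "ACGUACGUACGUACGUACGUA"}
        m = pairwise_identity_matrix(a, b)
        assert m.shape == (2, 1)
        assert m.loc["m1", "x"] == pytest.approx(100.0)
        assert ((m >= 0) & (m <= 100)).all().all()

    def test_score_matches_biopython(self):
        """Independent cross-check of the alignment score against
        Bio.Align.PairwiseAligner with the same scoring scheme."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = _random_seq(rng, int(rng.integers(8, 25)))
            b = _random_seq(rng, int(rng.integers(8, 25)))
            score, _ = global_align_identity(a, b)
            assert score == aligner.score(a, b)

    def test_identity_matches_exhaustive_enumeration(self):
        """On short sequences, identity equals the value from brute-force
        enumeration of every global alignment (same tie-break)."""

        def enumerate_alignments(a, b):
            # returns best (score, matches, -cols) over all alignments
            best = [None]

            def go(i, j, score, matches, cols):
                if i == len(a) and j == len(b):
                    cand = (score, matches, -cols)
                    if best[0] is None or cand > best[0]:
                        best[0] = cand
                    return
                if i < len(a) and j < len(b):
                    m = a[i] == b[j]
                    go(i + 1, j + 1, score + (1 if m else -1), matches + m, cols + 1)
                if i < len(a):
                    go(i + 1, j, score - 2, matches, cols + 1)
                if j < len(b):
                    go(i, j + 1, score - 2, matches, cols + 1)

            go(0, 0, 0, 0, 0)
            return best[0]

        rng = np.random.default_rng(9)
        for _ in range(8):
            a = _random_seq(rng, int(rng.integers(4, 9)))
            b = _random_seq(rng, int(rng.integers(4, 9)))
            score, matches, neg_cols = enumerate_alignments(a, b)
            got_score, got_ident = global_align_identity(a, b)
            assert got_score == score
            assert got_ident == pytest.approx(100.0 * matches / -neg_cols)
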