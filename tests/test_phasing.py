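"""The 21-nt register statistic and phased-locus detection."""

import itertools
import math

import numpy as np
import pytest

from srnakit.core_io import AlignedRead
from srnakit.phasing import (
    benjamini_hochberg,
    detect_phased_loci,
    hypergeom_tail,
    phasing_pvalue,
    window_pvalue_best_register,
)


class TestPvalue:
    def test_empty_window_is_one(self):
        assert phasing_pvalue([], 189, 21) == 1.0

    def test_nine_perfect_cycles_closed_form(self):
        """All nine occupied slots in register: the tail collapses to
        C(18,9)/C(378,9)."""
        positions = [(21 * i, "+") for i in range(9)]
        expected = math.comb(18, 9) / math.comb(378, 9)
        assert phasing_pvalue(positions, 189, 21, register=0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_monotone_decreasing_in_k(self):
        N, K, n = 378, 18, 12
        tails = [hypergeom_tail(k, N, K, n) for k in range(0, 13)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_matches_exhaustive_subset_enumeration(self):
        """Exact tail equals enumeration over all occupied-slot subsets."""
        phase = 5
        for W, max_n in ((5, 6), (10, 5)):
            N = 2 * W
            slots = [(pos, s) for s in "+-" for pos in range(W)]
            for n in range(1, max_n + 1):
                tallies = {}
                total = 0
                for subset in itertools.combinations(slots, n):
                    k = sum(1 for pos, _ in subset if pos % phase == 0)
                    tallies[k] = tallies.get(k, 0) + 1
                    total += 1
                for k in range(0, n + 1):
                    expected = sum(c for kk, c in tallies.items() if kk >= k) / total
                    got = hypergeom_tail(k, N, 2 * W // phase, n)
                    assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            phasing_pvalue([(0, "+")], 100, 21)  # W not a multiple of p
        with pytest.raises(ValueError):
            phasing_pvalue([(200, "+")], 189, 21)  # outside window

    def test_minus_strand_slots_are_distinct(self):
        both = phasing_pvalue([(0, "+"), (0, "-")], 21, 21, register=0)
        one = phasing_pvalue([(0, "+")], 21, 21, register=0)
        assert both < one


class TestBH:
    def test_adjustment_is_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.02, 0.9, 0.5]
        adj = benjamini_hochberg(p)
        assert (adj >= np.array(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


def _phased_alignments(scaffold, q0, cycles, phase=21, count=10):
    alns = []
    for c in range(cycles):
        q = q0 + c * phase
        alns.append(AlignedRead(f"p{c}", scaffold, q, "+", phase, 0, 1, count))
        alns.append(AlignedRead(f"m{c}", scaffold, q - 2, "-", phase, 0, 1, count))
    return alns


class TestDetection:
    def test_planted_register_recovered_exactly(self):
        q0 = 1013
        alns = _phased_alignments("c1", q0, cycles=8)
        (locus,) = detect_phased_loci(alns, {"c1": 50_000})
        assert locus.register == q0 % 21
        assert locus.interval.start <= q0 < locus.interval.end
        assert locus.k_in_register >= 8

    def test_planted_loci_in_synthetic_bundle(self, small_bundle, small_alignments):
        cfg, genome, annotations, truth, *_ = small_bundle
        lengths = {k: len(v) for k, v in genome.items()}
        detected = detect_phased_loci(small_alignments, lengths)
        for planted in truth.phased_loci:
            match = [
                d
                for d in detected
                if d.interval.scaffold == planted.interval.scaffold
                and d.interval.start < planted.interval.end
                and planted.interval.start < d.interval.end
            ]
            assert match, f"{planted.feature_id} not detected"
            assert any(d.register == planted.register for d in match)
        # every detection corresponds to a planted locus
        for d in detected:
            assert any(
                d.interval.scaffold == p.interval.scaffold
                and d.interval.start < p.interval.end + 21
                and p.interval.start - 21 < d.interval.end
                for p in truth.phased_loci
            )

    def test_uniform_reads_yield_no_locus(self):
        rng = np.random.default_rng(17)
        starts = rng.integers(0, 100_000, size=2000)
        alns = [
            AlignedRead(f"r{i}", "c1", int(s), "+" if i % 2 else "-", 21, 0, 1, 1)
            for i, s in enumerate(starts)
        ]
        assert detect_phased_loci(alns, {"c1": 100_000}) == []

    def test_off_length_reads_ignored(self):
        alns = [
            AlignedRead(f"r{c}", "c1", 1000 + 21 * c, "+", 24, 0, 1, 50)
            for c in range(9)
        ]
        assert detect_phased_loci(alns, {"c1": 50_000}) == []

    def test_min_cycles_gate(self):
        alns = _phased_alignments("c1", 2100, cycles=3)
        assert detect_phased_loci(alns, {"c1": 50_000}, min_cycles=4) == []


class TestTypeIError:
    def test_windowed_test_is_conservative_under_null(self):
        """Best-register windows on uniform occupancy stay below alpha."""
        rng = np.random.default_rng(23)
        alpha = 1e-3
        n_windows = 2000
        hits = 0
        for _ in range(n_windows):
            n = int(rng.integers(4, 30))
            pos = rng.choice(189, size=n, replace=False)
            strands = rng.choice(list("+-"), size=n)
            p, *_ = window_pvalue_best_register(list(zip(pos, strands)), 189, 21)
            hits += p <= alpha
        assert hits / n_windows <= alpha
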