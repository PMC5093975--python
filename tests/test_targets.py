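"""Target-site rules a-e against an independent brute-force checker."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnakit._seq import revcomp
from srnakit.targets import scan_targets, score_duplex

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def site_for(mirna, mismatch_positions=()):
    """Build a site complementary to *mirna* except at given 1-based
    miRNA positions (mismatch = transversion that is not G:U either)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    bad = {"A": "A", "C": "C", "G": "G", "T": "C"}  # never pairs, never wobbles
    L = len(mirna)
    site = [None] * L
    for i in range(1, L + 1):
        base = mirna[i - 1]
        site[L - i] = bad[base] if i in mismatch_positions else comp[base]
    return "".join(site)


MIRNA = "TGAAGCTGCCAGCATGATCTA"  # arbitrary 21-mer


class TestRules:
    def test_perfect_complement_accepted(self):
        v = score_duplex(MIRNA, site_for(MIRNA))
        assert v.accepted and v.n_mismatches == 0

    @pytest.mark.parametrize(
        "positions,reason",
        [
            ((10,), "b"),                  # cleavage-site mismatch
            ((11,), "b"),
            ((3, 4), "c"),                 # adjacent in 2-12
            ((12, 13), "c"),               # run straddling position 12
            ((2, 6, 9, 14, 18), "a"),      # five mismatches, none adjacent
            ((14, 15, 16), "d"),           # three adjacent beyond 12
        ],
    )
    def test_rejection_reasons(self, positions, reason):
        v = score_duplex(MIRNA, site_for(MIRNA, positions))
        assert not v.accepted and v.reject_reason == reason
        assert v.mismatch_positions == sorted(positions)

    @pytest.mark.parametrize("positions", [(2,), (4, 6), (14, 15), (1, 21), (13,)])
    def test_tolerated_mismatch_patterns(self, positions):
        assert score_duplex(MIRNA, site_for(MIRNA, positions)).accepted

    def test_wobble_counts_as_mismatch_unless_allowed(self):
        # mirna G at position 5 over site T: G:U wobble
        mirna = "AAAAGAAAATAAAAAAAAAAA"
        site = list(site_for(mirna))
        site[len(mirna) - 5] = "T"
        site = "".join(site)
        strict = score_duplex(mirna, site)
        assert strict.mismatch_positions == [5]
        relaxed = score_duplex(mirna, site, allow_wobble=True)
        assert relaxed.n_mismatches == 0

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            score_duplex("ACGU", "ACGUA")


def brute_force_verdict(mirna, site, allow_wobble=False):
    """Independent re-derivation of rules a-d for one ungapped duplex."""
    L = len(mirna)
    mm = []
    for i in range(1, L + 1):
        pair = (mirna[i - 1], site[L - i])
        ok = pair in WC or (allow_wobble and pair in {("G", "T"), ("T", "G")})
        if not ok:
            mm.append(i)
    mmset = set(mm)
    if len(mm) > 4:
        return False, "a"
    if mmset & {10, 11}:
        return False, "b"
    for i in range(2, 13):
        if i in mmset and i + 1 in mmset:
            return False, "c"
    for i in range(13, L - 1):
        if i in mmset and i + 1 in mmset and i + 2 in mmset:
            return False, "d"
    return True, None


class TestOracle:
    @settings(max_examples=300, derandomize=True)
    @given(
        st.text(alphabet="ACGT", min_size=21, max_size=21),
        st.text(alphabet="ACGT", min_size=21, max_size=21),
        st.booleans(),
    )
    def test_verdicts_match_brute_force(self, mirna, site, wobble):
        got = score_duplex(mirna, site, allow_wobble=wobble)
        accepted, reason = brute_force_verdict(mirna, site, wobble)
        assert got.accepted == accepted
        assert got.reject_reason == reason

    def test_zero_mismatch_always_accepted_five_never(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            mirna = "".join(rng.choice(list("ACGT"), size=21))
            assert score_duplex(mirna, site_for(mirna)).accepted
            bad = rng.choice(np.arange(1, 22), size=5, replace=False)
            assert not score_duplex(mirna, site_for(mirna, set(bad))).accepted

    def test_acceptance_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            mirna = "".join(rng.choice(list("ACGT"), size=21))
            positions = set(
                int(x) for x in rng.choice(np.arange(1, 22), size=3, replace=False)
            )
            site = site_for(mirna, positions)
            a = score_duplex(mirna, site)
            # reverse-complementing both partners swaps the duplex ends:
            # the same pairs remain, mirrored to positions L+1-i
            b = score_duplex(revcomp(site), revcomp(mirna))
            assert a.n_mismatches == b.n_mismatches


class TestScan:
    def test_planted_complement_found_at_offset(self):
        rng = np.random.default_rng(10)
        target = list(rng.choice(list("ACGT"), size=500))
        target[100:121] = list(site_for(MIRNA))
        sites = scan_targets({"m": MIRNA}, {"t": "".join(target)})
        assert any(s.start == 100 and s.strand == "+" for s in sites)

    def test_scan_matches_naive_scan(self):
        """Site set equals brute-force rule checking at every offset and
        orientation of a random 2-kb target."""
        rng = np.random.default_rng(12)
        target = "".join(rng.choice(list("ACGT"), size=2000))
        # seed two real sites so the test is not vacuous
        target = target[:300] + site_for(MIRNA, (5,)) + target[321:1200] + \
            revcomp(site_for(MIRNA)) + target[1221:]
        got = {
            (s.start, s.strand)
            for s in scan_targets({"m": MIRNA}, {"t": target})
        }
        L = len(MIRNA)
        rc = revcomp(target)
        expected = set()
        for j in range(len(target) - L + 1):
            if brute_force_verdict(MIRNA, target[j : j + L])[0]:
                expected.add((j, "+"))
            if brute_force_verdict(MIRNA, rc[j : j + L])[0]:
                expected.add((len(target) - L - j, "-"))
        assert got == expected and len(expected) >= 2
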