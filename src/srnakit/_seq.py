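"""Small alphabet helpers shared across modules.

The internal canonical alphabet is uppercase DNA (U is stored as T); the
output layer decides whether to print T or U.  Keeping a single alphabet
internally means reads (RNA) and the genome (DNA) compare directly.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base pairs accepted when folding RNA: Watson-Crick plus the G:U wobble
PAIRABLE = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

#: strict Watson-Crick pairs (used by the target-site rules, where G:U
#: counts as a mismatch unless explicitly allowed)
WATSON_CRICK = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})


def canonical(seq: str) -> str:
    """Uppercase a sequence and map U to T (canonical internal alphabet)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-alphabet characters in sequence: {sorted(bad)}")
    return s


def to_rna(seq: str) -> str:
    """Render a canonical sequence with RNA lettering (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a canonical DNA sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence (N bases excluded from the denominator)."""
    s = canonical(seq)
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt
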