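"""Rule-based miRNA target-site prediction.

A candidate site is an ungapped antiparallel duplex between a miRNA and an
equally long window of the target.  miRNA positions are numbered 1..L from
the miRNA 5' end; position i pairs with site position L - i (0-based on
the site written 5'->3').  A pair that is not Watson-Crick counts as a
mismatch (G:U wobble is a mismatch by default; ``allow_wobble`` relaxes
this).  A site is accepted when all of the following hold:

a. at most four mismatches in total;
b. no mismatch at miRNA positions 10 or 11 (the slicer cleavage site);
c. no adjacent mismatch pair starting at positions 2-12 (so a run
   straddling position 12 also fails here);
d. no run of more than two adjacent mismatches wholly within positions > 12;
e. no bulges — enforced by construction, since only ungapped equal-length
   duplexes are scored.

The reject reason reported is the first violated rule in the order a-d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._seq import WATSON_CRICK, canonical, revcomp

#: rules evaluated, in reporting order
RULES = ("a", "b", "c", "d")


@dataclass
class TargetSite:
    """Verdict for one miRNA/site duplex (and its location, when scanned)."""

    mirna_id: str
    target_id: str
    start: int                      # 0-based on the target's forward strand
    strand: str                     # orientation of the site on the target
    mismatch_positions: list[int] = field(default_factory=list)  # 1-based, miRNA frame
    accepted: bool = False
    reject_reason: Optional[str] = None

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def _mismatch_profile(mirna: str, site: str, allow_wobble: bool) -> list[int]:
    """1-based miRNA positions that fail to pair with the antiparallel site."""
    L = len(mirna)
    mm: list[int] = []
    for i in range(1, L + 1):
        pair = (mirna[i - 1], site[L - i])
        if pair in WATSON_CRICK:
            continue
        if allow_wobble and pair in {("G", "T"), ("T", "G")}:
            continue
        mm.append(i)
    return mm


def _first_violation(mismatches: list[int], length: int, max_mismatches: int) -> Optional[str]:
    mmset = set(mismatches)
    if len(mismatches) > max_mismatches:
        return "a"
    if 10 in mmset or 11 in mmset:
        return "b"
    if any(i in mmset and i + 1 in mmset for i in range(2, 13)):
        return "c"
    # runs of >2 adjacent mismatches wholly within positions 13..L
    run = 0
    for i in range(13, length + 1):
        run = run + 1 if i in mmset else 0
        if run > 2:
            return "d"
    return None


def score_duplex(
    mirna: str,
    site: str,
    allow_wobble: bool = False,
    max_mismatches: int = 4,
    mirna_id: str = "mirna",
    target_id: str = "site",
    start: int = 0,
    strand: str = "+",
) -> TargetSite:
    """Score one ungapped duplex against rules a-e.

    *site* is the target window written 5'->3' on its own strand; it is
    read antiparallel to the miRNA.  Unequal lengths are an error (bulged
    duplexes are outside this model).
    """
    m = canonical(mirna)
    s = canonical(site)
    if len(m) != len(s):
        raise ValueError("miRNA and site must have equal length (ungapped duplex)")
    mismatches = _mismatch_profile(m, s, allow_wobble)
    reason = _first_violation(mismatches, len(m), max_mismatches)
    return TargetSite(
        mirna_id=mirna_id,
        target_id=target_id,
        start=start,
        strand=strand,
        mismatch_positions=mismatches,
        accepted=reason is None,
        reject_reason=reason,
    )


def scan_targets(
    mirnas: dict[str, str],
    targets: dict[str, str],
    allow_wobble: bool = False,
    max_mismatches: int = 4,
) -> list[TargetSite]:
    """Slide every miRNA over every target window in both orientations.

    A plus-strand site means the miRNA pairs with the forward strand of
    the target at that window; a minus-strand site means it pairs with the
    reverse complement.  Coordinates always refer to the target's forward
    strand.  Only accepted sites are returned, ordered by
    (target, start, strand, miRNA) for determinism.
    """
    sites: list[TargetSite] = []
    for target_id in sorted(targets):
        tseq = canonical(targets[target_id])
        T = len(tseq)
        rc = revcomp(tseq)
        for mirna_id in sorted(mirnas):
            mseq = canonical(mirnas[mirna_id])
            L = len(mseq)
            if T < L:
                continue
            for j in range(T - L + 1):
                verdict = score_duplex(
                    mseq, tseq[j : j + L], allow_wobble, max_mismatches,
                    mirna_id, target_id, start=j, strand="+",
                )
                if verdict.accepted:
                    sites.append(verdict)
                # site on the reverse strand; forward-strand coordinate of
                # the rc window [j, j+L) is [T-L-j, T-j)
                verdict = score_duplex(
                    mseq, rc[j : j + L], allow_wobble, max_mismatches,
                    mirna_id, target_id, start=T - L - j, strand="-",
                )
                if verdict.accepted:
                    sites.append(verdict)
    sites.sort(key=lambda s: (s.target_id, s.start, s.strand, s.mirna_id))
    return sites


def sites_to_rows(sites: Sequence[TargetSite], site_length: dict[str, int] | None = None):
    """Flatten verdicts into TSV-ready dict rows."""
    rows = []
    for s in sites:
        rows.append(
            {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "start": s.start,
                "strand": s.strand,
                "n_mismatch": s.n_mismatches,
                "mismatch_positions": ",".join(map(str, s.mismatch_positions)),
                "verdict": "accepted" if s.accepted else f"rejected_{s.reject_reason}",
            }
        )
    return rows
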