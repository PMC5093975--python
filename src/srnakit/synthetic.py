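"""Synthetic genome and AGO-IP-like small-RNA library with planted truth.

The generator plants every feature class the pipeline is meant to recover
on a toy multi-scaffold genome, then simulates a read library whose
statistical structure emulates an AGO-associated small-RNA sequencing
experiment: a 21-22 nt length mode, a strong 5'-U bias (AGO loading
preference), reads concentrated on miRNA mature/star arms, exact 21-nt
phased loci with duplex 2-nt overhang geometry, diverged repeat-family
copies, mRNA fragments, a handful of intergenic hotspots emitting one
identical sequence each, and uniform background from unannotated space.

Every simulated read is recorded in a per-read truth table, so planted
composition, loci and hotspot bins serve as the acceptance oracle for the
analysis modules.  All randomness flows from one integer seed; output is
byte-identical across runs and platforms for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import revcomp
from .core_io import AnnotationSet, GenomicInterval, SmallRead

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    The defaults are the conditions the test-suite and acceptance checks
    run under; see docs/methods.md for the rationale behind each value.
    """

    n_scaffolds: int = 8
    scaffold_length: int = 800_000
    gc_content: float = 0.60

    n_mirna_loci: int = 30
    mirna_flank: int = 8
    mirna_loop: int = 15
    mature_length: int = 21

    n_tir_transposons: int = 2
    tir_length: int = 70
    tir_element_length: int = 200

    n_phased_loci: int = 6
    phase_length: int = 21
    phase_cycles: int = 8

    repeat_families: tuple[str, ...] = ("kangaroo_like", "gypsy_like", "jordan_like")
    repeat_family_weights: tuple[float, ...] = (0.55, 0.25, 0.20)
    repeat_copies: int = 2
    repeat_consensus_length: int = 1500
    repeat_divergence: float = 0.03
    #: families whose reads come only from the 5' 500 nt of the element
    five_prime_biased_families: tuple[str, ...] = ("jordan_like",)
    five_prime_bias_window: int = 500

    #: substitutions planted in each standalone star arm (imperfect duplex,
    #: as in real precursors; keeps mature/star mappings unambiguous)
    star_mismatches: int = 2

    n_hotspots: int = 8
    n_mrna_genes: int = 20
    mrna_length: int = 1000
    n_rrna_trna_loci: int = 3
    rrna_length: int = 120

    library_size: int = 100_000
    class_fractions: dict = field(
        default_factory=lambda: {
            "rRNA_tRNA": 0.05,
            "miRNA": 0.20,
            "phased": 0.08,
            "repeat": 0.30,
            "mRNA_sense": 0.15,
            "mRNA_antisense": 0.05,
            "hotspot": 0.07,
            "noise": 0.10,
        }
    )
    length_distribution: dict = field(
        default_factory=lambda: {19: 0.05, 20: 0.13, 21: 0.38, 22: 0.26, 23: 0.12, 24: 0.06}
    )
    five_prime_u_fraction: float = 0.8
    mature_read_frac: float = 0.8
    star_read_frac: float = 0.1
    wobble_prob: float = 0.2    # total probability of a +/-1 nt mature 5' shift
    substitution_rate: float = 0.0

    min_feature_gap: int = 2500
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        for name, frac in self.class_fractions.items():
            if frac < 0:
                raise ValueError(f"negative class fraction for {name}")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if abs(sum(self.length_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("length_distribution must sum to 1")
        if not 0.0 <= self.five_prime_u_fraction <= 1.0:
            raise ValueError("five_prime_u_fraction must be in [0, 1]")


@dataclass
class PlantedMirna:
    feature_id: str
    precursor: GenomicInterval
    mature_sequence: str
    star_sequence: str
    arm: str
    mature_start: int
    star_start: int
    in_repeat: bool = False


@dataclass
class PlantedPhased:
    feature_id: str
    interval: GenomicInterval
    register: int               # genomic residue class mod phase
    cycle_starts: list[int]     # plus-strand 5' starts


@dataclass
class PlantedHotspot:
    feature_id: str
    scaffold: str
    position: int
    sequence: str
    bin_start: int              # for the default 50-kb binning


@dataclass
class SyntheticTruth:
    """Planted features and expected composition of the simulated library."""

    mirna_loci: list[PlantedMirna] = field(default_factory=list)
    phased_loci: list[PlantedPhased] = field(default_factory=list)
    repeat_consensus: dict = field(default_factory=dict)
    repeat_intervals: list = field(default_factory=list)
    hotspots: list[PlantedHotspot] = field(default_factory=list)
    mrna_genes: list = field(default_factory=list)
    rrna_loci: list = field(default_factory=list)
    class_fractions: dict = field(default_factory=dict)
    intergenic_space: list = field(default_factory=list)  # (scaffold, lo, hi)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(
        np.array(list("ACGT")), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    )


def _u_flags(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Deterministically rounded boolean assignment: exactly round(f*n) True."""
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags

def _force_base(arr, pos, base, rng, forbid=False):
    """Set arr[pos] to *base*, or to anything but it when *forbid*."""
    if forbid:
        choices = [b for b in "ACGT" if b != base]
        arr[pos] = rng.choice(choices)
    else:
        arr[pos] = base


def generate_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, str], AnnotationSet, SyntheticTruth]:
    """Build the planted genome, its annotation set and the truth record.

    Deterministic for a fixed config (one RNG stream seeded by
    ``config.seed``).  Raises if the features do not pack into the genome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scaffolds = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    arrays = {
        name: _random_bases(rng, config.scaffold_length, config.gc_content)
        for name in scaffolds
    }

    # ---- feature manifest ------------------------------------------------
    pre_len = 2 * config.mature_length + config.mirna_loop + 2 * config.mirna_flank
    phased_len = 2 + config.phase_cycles * config.phase_length
    features: list[tuple[str, int, int]] = []       # (kind, index, length)
    for i in range(config.n_mirna_loci):
        features.append(("mirna", i, pre_len))
    for i in range(config.n_tir_transposons):
        features.append(("tir", i, config.tir_element_length))
    for i in range(config.n_phased_loci):
        features.append(("phased", i, phased_len))
    for fi, fam in enumerate(config.repeat_families):
        for c in range(config.repeat_copies):
            features.append(("repeat", fi * config.repeat_copies + c,
                             config.repeat_consensus_length))
    for i in range(config.n_mrna_genes):
        features.append(("mrna", i, config.mrna_length))
    for i in range(config.n_rrna_trna_loci):
        features.append(("rrna", i, config.rrna_length))

    order = rng.permutation(len(features))
    features = [features[i] for i in order]

    # round-robin scaffold assignment; hotspots get one scaffold each so
    # their 50-kb bins are necessarily distinct
    per_scaffold: dict[str, list[tuple[str, int, int]]] = {s: [] for s in scaffolds}
    for i, feat in enumerate(features):
        per_scaffold[scaffolds[i % len(scaffolds)]].append(feat)
    for i in range(config.n_hotspots):
        per_scaffold[scaffolds[i % len(scaffolds)]].append(("hotspot", i, 21))

    placements: dict[tuple[str, int], tuple[str, int]] = {}  # (kind, idx) -> (scaffold, start)
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    for scaffold in scaffolds:
        cursor = int(rng.integers(config.min_feature_gap // 2, config.min_feature_gap))
        for kind, idx, length in per_scaffold[scaffold]:
            start = cursor
            end = start + length
            if end > config.scaffold_length - config.min_feature_gap:
                raise ValueError(
                    "planted features do not fit; increase scaffold_length "
                    "or n_scaffolds"
                )
            placements[(kind, idx)] = (scaffold, start)
            occupied[scaffold].append((start, end))
            cursor = end + config.min_feature_gap + int(rng.integers(0, 2000))

    annotations = AnnotationSet()
    truth = SyntheticTruth(class_fractions=dict(config.class_fractions))

    # ---- miRNA hairpins (standalone and TIR-embedded) --------------------
    # Real precursors are selected for folding into clean stem-loops; the
    # generator emulates that by redrawing any candidate whose maximum-
    # pairing fold (in genomic context, as the caller will see it) does not
    # route >= 16 mature bases into the star arm.
    from .mirna import fold_hairpin

    n_mat = config.n_mirna_loci + config.n_tir_transposons
    mat_u = _u_flags(rng, n_mat, config.five_prime_u_fraction)
    star_u = _u_flags(rng, n_mat, config.five_prime_u_fraction)
    L = config.mature_length

    def _make_mature(j: int) -> np.ndarray:
        mature = _random_bases(rng, L, config.gc_content)
        # 5'-U bias, kept under the +/-1 wobble by also pinning base 2
        _force_base(mature, 0, "T", rng, forbid=not mat_u[j])
        _force_base(mature, 1, "T", rng, forbid=not mat_u[j])
        # star 5' base is the complement of the mature 3' base
        _force_base(mature, L - 1, "A", rng, forbid=not star_u[j])
        return mature

    def _stem_wins(context: str, m0: int, s0: int, min_pairs: int = 16) -> bool:
        fold = fold_hairpin(context)
        partner = fold.partner()
        partners = sorted(partner[i] for i in range(m0, m0 + L) if i in partner)
        if len(partners) < min_pairs:
            return False
        majority = [q for q in partners if s0 - 3 <= q < s0 + L + 3]
        if len(majority) < min_pairs or len(partners) - len(majority) > 2:
            return False
        return abs(majority[0] - s0) <= 3 if s0 > m0 else abs(majority[-1] - (s0 + L - 1)) <= 3

    def _hairpin_ok(context: str, m0: int, s0: int) -> bool:
        """The mature-star stem must dominate the maximum-pairing fold, and
        keep dominating under small jitters of the folded window (the
        caller's window depends on the stochastic read block extent)."""
        for d_left, d_right in ((0, 0), (5, 0), (0, 5), (10, 10)):
            sub = context[d_left : len(context) - d_right if d_right else None]
            if not _stem_wins(sub, m0 - d_left, s0 - d_left):
                return False
        return True

    ctx = 20  # flanking genomic context folded along with the candidate

    for i in range(config.n_mirna_loci):
        scaffold, start = placements[("mirna", i)]
        arm = "5p" if i % 2 == 0 else "3p"
        arr = arrays[scaffold]
        for _attempt in range(60):
            mature = _make_mature(i)
            star = np.array(list(revcomp("".join(mature))))
            # imperfect duplex: substitutions away from the star 5' end
            if config.star_mismatches:
                for pos in np.linspace(5, L - 6, config.star_mismatches).astype(int):
                    star[pos] = rng.choice([b for b in "ACGT" if b != star[pos]])
            loop = _random_bases(rng, config.mirna_loop, config.gc_content)
            flank5 = _random_bases(rng, config.mirna_flank, config.gc_content)
            flank3 = _random_bases(rng, config.mirna_flank, config.gc_content)
            if arm == "5p":
                _force_base(flank5, -1, "T", rng, forbid=not mat_u[i])
                parts = [flank5, mature, loop, star, flank3]
                m_off = config.mirna_flank
                s_off = config.mirna_flank + L + config.mirna_loop
            else:
                _force_base(loop, -1, "T", rng, forbid=not mat_u[i])
                parts = [flank5, star, loop, mature, flank3]
                s_off = config.mirna_flank
                m_off = config.mirna_flank + L + config.mirna_loop
            seq = np.concatenate(parts)
            arr[start : start + len(seq)] = seq
            context = "".join(arr[start - ctx : start + pre_len + ctx])
            if _hairpin_ok(context, m_off + ctx, s_off + ctx):
                break
        else:
            raise RuntimeError(f"could not plant a foldable hairpin for locus {i}")
        truth.mirna_loci.append(
            PlantedMirna(
                feature_id=f"mir_{i + 1}",
                precursor=GenomicInterval(scaffold, start, start + pre_len, "+", "miRNA"),
                mature_sequence="".join(mature),
                star_sequence="".join(star),
                arm=arm,
                mature_start=start + m_off,
                star_start=start + s_off,
            )
        )

    for i in range(config.n_tir_transposons):
        scaffold, start = placements[("tir", i)]
        j = config.n_mirna_loci + i
        arr = arrays[scaffold]
        m_off_tir = 20
        star_off = config.tir_element_length - (m_off_tir + L)
        spacer_len = config.tir_element_length - 2 * config.tir_length
        for _attempt in range(60):
            mature = _make_mature(j)
            tir = _random_bases(rng, config.tir_length, config.gc_content)
            tir[m_off_tir : m_off_tir + L] = mature
            _force_base(tir, m_off_tir - 1, "T", rng, forbid=not mat_u[j])
            spacer = _random_bases(rng, spacer_len, config.gc_content)
            element = np.concatenate(
                [tir, spacer, np.array(list(revcomp("".join(tir))))]
            )
            arr[start : start + len(element)] = element
            context = "".join(
                arr[start - ctx : start + config.tir_element_length + ctx]
            )
            if _hairpin_ok(context, m_off_tir + ctx, star_off + ctx):
                break
        else:
            raise RuntimeError(f"could not plant a foldable TIR element {i}")
        iv = GenomicInterval(
            scaffold, start, start + config.tir_element_length, "+",
            "repeat", "tir_cacta_like",
        )
        annotations.add(iv)
        truth.repeat_intervals.append(iv)
        truth.mirna_loci.append(
            PlantedMirna(
                feature_id=f"mir_tir_{i + 1}",
                precursor=GenomicInterval(
                    scaffold, start, start + config.tir_element_length, "+", "miRNA"
                ),
                mature_sequence="".join(mature),
                star_sequence=revcomp("".join(mature)),
                arm="5p",
                mature_start=start + m_off_tir,
                star_start=start + star_off,
                in_repeat=True,
            )
        )

    # ---- phased loci ------------------------------------------------------
    p = config.phase_length
    for i in range(config.n_phased_loci):
        scaffold, start = placements[("phased", i)]
        plus_u = _u_flags(rng, config.phase_cycles, config.five_prime_u_fraction)
        minus_u = _u_flags(rng, config.phase_cycles, config.five_prime_u_fraction)
        q0 = start + 2
        cycle_starts = [q0 + c * p for c in range(config.phase_cycles)]
        arr = arrays[scaffold]
        for c, q in enumerate(cycle_starts):
            _force_base(arr, q, "T", rng, forbid=not plus_u[c])
            # minus-strand duplex partner 5' end sits at q + 18
            _force_base(arr, q + p - 3, "A", rng, forbid=not minus_u[c])
        truth.phased_loci.append(
            PlantedPhased(
                feature_id=f"phas_{i + 1}",
                interval=GenomicInterval(
                    scaffold, start, start + phased_len, ".", "phased"
                ),
                register=q0 % p,
                cycle_starts=cycle_starts,
            )
        )

    # ---- repeat families ---------------------------------------------------
    for fi, fam in enumerate(config.repeat_families):
        consensus = _random_bases(rng, config.repeat_consensus_length, config.gc_content)
        truth.repeat_consensus[fam] = "".join(consensus)
        for c in range(config.repeat_copies):
            scaffold, start = placements[("repeat", fi * config.repeat_copies + c)]
            copy = consensus.copy()
            muts = rng.random(len(copy)) < config.repeat_divergence
            for pos in np.nonzero(muts)[0]:
                copy[pos] = rng.choice([b for b in "ACGT" if b != copy[pos]])
            arrays[scaffold][start : start + len(copy)] = copy
            iv = GenomicInterval(
                scaffold, start, start + len(copy), "+", "repeat", fam
            )
            annotations.add(iv)
            truth.repeat_intervals.append(iv)

    # ---- mRNA / rRNA-tRNA / hotspots ---------------------------------------
    for i in range(config.n_mrna_genes):
        scaffold, start = placements[("mrna", i)]
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(
            scaffold, start, start + config.mrna_length, strand,
            "mRNA_exon", f"gene_{i + 1}",
        )
        annotations.add(iv)
        truth.mrna_genes.append(iv)
    for i in range(config.n_rrna_trna_loci):
        scaffold, start = placements[("rrna", i)]
        iv = GenomicInterval(
            scaffold, start, start + config.rrna_length, "+",
            "rRNA_tRNA_ref", f"rrna_{i + 1}",
        )
        annotations.add(iv)
        truth.rrna_loci.append(iv)

    hot_u = _u_flags(rng, config.n_hotspots, config.five_prime_u_fraction)
    for i in range(config.n_hotspots):
        scaffold, start = placements[("hotspot", i)]
        arr = arrays[scaffold]
        _force_base(arr, start, "T", rng, forbid=not hot_u[i])
        seq = "".join(arr[start : start + 21])
        truth.hotspots.append(
            PlantedHotspot(
                feature_id=f"hot_{i + 1}",
                scaffold=scaffold,
                position=start,
                sequence=seq,
                bin_start=(start // 50_000) * 50_000,
            )
        )

    # ---- intergenic space (for background sampling) ------------------------
    # margin larger than the caller's block-merge gap, so background reads
    # can never bridge into a planted feature's read block
    margin = 100
    for scaffold in scaffolds:
        spans = sorted(occupied[scaffold])
        cursor = 0
        for lo, hi in spans:
            if lo - margin - cursor >= 50:
                truth.intergenic_space.append((scaffold, cursor, lo - margin))
            cursor = hi + margin
        if config.scaffold_length - cursor >= 50:
            truth.intergenic_space.append((scaffold, cursor, config.scaffold_length))

    genome = {name: "".join(arrays[name]) for name in scaffolds}
    return genome, annotations, truth


# ---------------------------------------------------------------------------
# read simulation


def _read_from(genome, scaffold, start, length, strand) -> str:
    s = genome[scaffold][start : start + length]
    return revcomp(s) if strand == "-" else s


def simulate_reads(
    genome: dict[str, str],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed: Optional[int] = None,
) -> tuple[list[SmallRead], pd.DataFrame]:
    """Simulate the AGO-IP-like library; returns reads + per-read truth.

    Each read is drawn from one planted class according to
    ``config.class_fractions``; the truth table records its class, origin
    feature and placement.  Constant Q40 qualities (no error model unless
    ``substitution_rate`` > 0).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    classes = sorted(config.class_fractions)
    probs = [config.class_fractions[c] for c in classes]
    lengths = sorted(config.length_distribution)
    length_probs = [config.length_distribution[L] for L in lengths]
    draw = rng.choice(len(classes), size=config.library_size, p=probs)

    inter = truth.intergenic_space
    inter_weights = np.array([hi - lo for _, lo, hi in inter], dtype=float)
    inter_probs = inter_weights / inter_weights.sum() if len(inter) else None

    fam_names = list(config.repeat_families)
    fam_probs = np.asarray(config.repeat_family_weights, dtype=float)
    fam_probs = fam_probs / fam_probs.sum()
    fam_intervals = {
        fam: [iv for iv in truth.repeat_intervals if iv.name == fam]
        for fam in fam_names
    }

    def _conditioned_position(sample_fn, length, want_u, tries=100):
        """Rejection-sample a placement until the 5' base matches want_u."""
        for _ in range(tries):
            scaffold, start, strand = sample_fn()
            if strand == "+":
                base = genome[scaffold][start]
            else:
                base = _COMP[genome[scaffold][start + length - 1]]
            if (base == "T") == want_u:
                return scaffold, start, strand
        return scaffold, start, strand

    reads: list[SmallRead] = []
    rows = []
    for i in range(config.library_size):
        cls = classes[draw[i]]
        rid = f"r{i + 1}"
        want_u = rng.random() < config.five_prime_u_fraction
        feature_id = ""
        if cls == "miRNA":
            locus = truth.mirna_loci[rng.integers(len(truth.mirna_loci))]
            feature_id = locus.feature_id
            roll = rng.random()
            strand = "+"
            if roll < config.mature_read_frac:
                delta = 0
                w = rng.random()
                if w < config.wobble_prob / 2:
                    delta = -1
                elif w < config.wobble_prob:
                    delta = 1
                start, length = locus.mature_start + delta, config.mature_length
            elif roll < config.mature_read_frac + config.star_read_frac:
                start, length = locus.star_start, config.mature_length
            else:
                length = int(rng.choice(lengths, p=length_probs))
                lo, hi = locus.precursor.start, locus.precursor.end - length

                def _sample(lo=lo, hi=hi, sc=locus.precursor.scaffold, L=length):
                    return sc, int(rng.integers(lo, hi + 1)), "+"

                sc, start, strand = _conditioned_position(_sample, length, want_u)
            scaffold = locus.precursor.scaffold
        elif cls == "phased":
            locus = truth.phased_loci[rng.integers(len(truth.phased_loci))]
            feature_id = locus.feature_id
            q = locus.cycle_starts[rng.integers(len(locus.cycle_starts))]
            length = config.phase_length
            if rng.random() < 0.5:
                start, strand = q, "+"
            else:
                start, strand = q - 2, "-"
            scaffold = locus.interval.scaffold
        elif cls == "repeat":
            fam = fam_names[int(rng.choice(len(fam_names), p=fam_probs))]
            ivs = fam_intervals[fam]
            iv = ivs[rng.integers(len(ivs))]
            feature_id = fam
            length = int(rng.choice(lengths, p=length_probs))
            window = len(iv)
            if fam in config.five_prime_biased_families:
                window = min(window, config.five_prime_bias_window)

            def _sample(iv=iv, window=window, L=length):
                s = int(rng.integers(iv.start, iv.start + window - L + 1))
                return iv.scaffold, s, "+" if rng.random() < 0.5 else "-"

            scaffold, start, strand = _conditioned_position(_sample, length, want_u)
        elif cls in ("mRNA_sense", "mRNA_antisense"):
            gene = truth.mrna_genes[rng.integers(len(truth.mrna_genes))]
            feature_id = gene.name
            length = int(rng.choice(lengths, p=length_probs))
            strand_of_read = (
                gene.strand
                if cls == "mRNA_sense"
                else ("-" if gene.strand == "+" else "+")
            )

            def _sample(gene=gene, L=length, st=strand_of_read):
                return gene.scaffold, int(rng.integers(gene.start, gene.end - L + 1)), st

            scaffold, start, strand = _conditioned_position(_sample, length, want_u)
        elif cls == "rRNA_tRNA":
            iv = truth.rrna_loci[rng.integers(len(truth.rrna_loci))]
            feature_id = iv.name
            length = int(rng.choice(lengths, p=length_probs))

            def _sample(iv=iv, L=length):
                return iv.scaffold, int(rng.integers(iv.start, iv.end - L + 1)), "+"

            scaffold, start, strand = _conditioned_position(_sample, length, want_u)
        elif cls == "hotspot":
            hot = truth.hotspots[rng.integers(len(truth.hotspots))]
            feature_id = hot.feature_id
            scaffold, start, strand, length = hot.scaffold, hot.position, "+", 21
        elif cls == "noise":
            length = int(rng.choice(lengths, p=length_probs))

            def _sample(L=length):
                j = int(rng.choice(len(inter), p=inter_probs))
                sc, lo, hi = inter[j]
                return sc, int(rng.integers(lo, hi - L + 1)), (
                    "+" if rng.random() < 0.5 else "-"
                )

            scaffold, start, strand = _conditioned_position(_sample, length, want_u)
        else:  # pragma: no cover
            raise AssertionError(cls)

        seq = _read_from(genome, scaffold, start, length, strand)
        if config.substitution_rate > 0:
            chars = list(seq)
            for pos in np.nonzero(rng.random(length) < config.substitution_rate)[0]:
                chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
            seq = "".join(chars)
        reads.append(SmallRead(rid, seq, qualities=[40] * length))
        rows.append((rid, cls, scaffold, start, strand, length, feature_id))

    table = pd.DataFrame(
        rows,
        columns=["read_id", "class", "scaffold", "start", "strand", "length", "feature_id"],
    )
    return reads, table


# ---------------------------------------------------------------------------
# reference-shaped miRNA catalogue (synthetic stand-in)


def synthetic_mirna_catalogue(seed: int = 0) -> list[tuple[str, str, str]]:
    """Synthetic stand-in for the V. carteri predicted-miRNA catalogue.

    The real catalogue of 490 predicted miRNAs is not redistributable here;
    this generator emits 490 synthetic (id, mature sequence, location)
    records whose family-size profile matches the published census of that
    catalogue: 324 distinct mature sequences, the largest family with 48
    members and 67 families of two or more.  Use it to exercise family
    grouping, not as biological sequence data.
    """
    sizes = [48, 16, 12, 8, 5, 4, 4] + [3] * 16 + [2] * 44 + [1] * 257
    assert sum(sizes) == 490 and len(sizes) == 324
    rng = np.random.default_rng(seed)
    seqs: set[str] = set()
    records: list[tuple[str, str, str]] = []
    member = 0
    for fam_idx, size in enumerate(sizes):
        while True:
            seq = "".join(rng.choice(list("ACGU"), size=21))
            if seq not in seqs:
                seqs.add(seq)
                break
        for m in range(size):
            member += 1
            records.append(
                (
                    f"vca-syn-mir-{fam_idx + 1}{chr(ord('a') + (m % 26))}",
                    seq,
                    f"scaffold_{(member % 40) + 1}:{member * 1013}",
                )
            )
    return records
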