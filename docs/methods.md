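# Methods

`srnakit` annotates AGO-associated (immunoprecipitated) small-RNA
sequencing libraries from plant-like genomes: it classifies reads into
functional classes, calls miRNA hairpin loci and families, detects
21-nt-phased siRNA loci, predicts miRNA target sites by positional
mismatch rules, profiles small-RNA coverage of repeat consensus
sequences, and scans for intergenic read hotspots.  This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Coordinate and alphabet conventions

All intervals are 0-based half-open on the forward strand; GFF3 (1-based
inclusive) is converted at the I/O boundary only.  Reads (RNA) and the
genome (DNA) share one canonical uppercase alphabet with U stored as T;
output formats choose their lettering.  For a minus-strand placement,
`start` is the leftmost forward-strand coordinate and the biological 5'
end is at `start + length - 1`.

## Preprocessing

The 3' adapter is located as the leftmost position where the adapter
prefix matches the read suffix through the read's end with at most 10%
mismatches over an overlap of at least 5 nt.  Leading and trailing bases
whose Phred score is not strictly greater than 20 are then hard-trimmed
(trimming, not read discard).  Reads outside 18-26 nt are removed; the
window brackets the 21-22-nt mode of AGO-loaded small RNAs.  The
adapter+quality cycle is iterated to a fixpoint, which makes
preprocessing exactly idempotent — a single pass is not, because trimming
can expose a new spurious adapter-prefix suffix.  Composition statistics
(length histogram, per-position nucleotide frequencies, 5' nucleotide
fractions) are count-weighted, so collapsed and expanded representations
of the same library give identical summaries.

## Read placement

Small reads are placed by exact or near-exact matching (substitutions
only, no indels — the standard regime for <= 26-nt reads), on both
strands, reporting *all* placements up to a multimapper cap (default 50;
capped reads are dropped and counted).  Internally a sorted 2-bit-encoded
k-mer index provides seeds; with `m` allowed mismatches the query is
split into `m + 1` chunks so the pigeonhole principle guarantees a
seeding chunk is exact.  The output contract is equivalence with a
brute-force scan over every offset and strand, which the test suite
enforces against an independent exhaustive implementation.  Externally
aligned SAM/BAM can be substituted for the built-in mapper.

## Read categorization

Each mapped read receives exactly one class.  When a read has several
placements, or one placement under several features, the
highest-precedence class among all of them wins; the default order is

    rRNA_tRNA > miRNA > phased > repeat > mRNA_sense > mRNA_antisense > intergenic

The contaminant screen (rRNA/tRNA) comes first as is standard, and miRNA
outranks repeat so that transposon-encoded miRNAs are reported as miRNAs.
The precedence is a single configurable list.  mRNA reads are split by
strand agreement with the overlapping exon.  Fractions are reported both
over all mapped reads and over assigned (non-intergenic) reads.

Transcript strand correction follows the two-fold rule: an orientation is
assigned only when one strand carries at least twice the reads of the
other (boundary inclusive: 10 vs 5 assigns), otherwise the transcript
stays unoriented.

Hotspot detection bins intergenic reads into fixed 50-kb windows by
their 5' start.  Bins never span scaffold boundaries (terminal bins may
be short); a concatenated-genome offset is reported for display, but the
counting itself is per-scaffold and therefore invariant to scaffold
order.  The hotspot set is either the top-N bins or all bins above a
count threshold, with the cumulative fraction of intergenic and of total
reads attached.

## miRNA locus calling

The caller is a deliberately explicit, structure-based surrogate for
thermodynamic miRNA predictors.  Read-dense blocks (inter-read gap <= 50
nt) extended by a flank define candidate precursors of at most 300 nt.
A candidate becomes a locus when:

1. it holds >= 10 (count-weighted) reads, each read counted once even if
   it maps several times inside the block (perfect inverted repeats);
2. the most abundant read ("mature") is 20-23 nt;
3. the precursor's maximum-base-pairing fold routes >= 60% of mature
   bases to a region strictly on one side of the mature (single
   stem-loop); at most two stray partners are tolerated as folding noise;
4. the paired region defines the star arm; reads starting within 4 nt of
   it are star reads, and at least one star read is required (duplex
   evidence — without it, any abundant single-position read cluster in
   weakly structured sequence could qualify);
5. mature (±1-nt 5' wobble) plus star reads make up >= 50% of the locus
   ("precision").

Because maximum-pairing folds can be degenerate — several co-optimal
structures, with the realized one sensitive to the exact window — the
caller searches a few precursor boundary variants (flank 20, 10, 30, 0)
and accepts the first window satisfying all criteria.  Rejected
candidates carry the reason code of the first variant.

Folding is an exact Nussinov maximum-pairing dynamic program
(Watson-Crick + G:U, minimum loop 3) with a deterministic traceback
tie-break (pair the smallest available i with its largest partner).  The
folding backend is pluggable, so a thermodynamic folder can be dropped in
without touching the caller.  Counting pairs rather than energies is the
simplest model that makes hairpin calling reproducible without external
binaries; its known weakness — degenerate optima on long windows — is
mitigated by the boundary search above, and quantified by the generator
study below.

Families group mature sequences by exact identity (U = T,
case-insensitive) across distinct genomic locations; family statistics
are computed over mature strands only.

Cross-species conservation is summarized by a pairwise percent-identity
matrix from global (Needleman-Wunsch) alignment with match +1, mismatch
-1, gap -2; identity = matches / alignment columns x 100.  Among
co-optimal alignments the one with most matches, then fewest columns, is
reported — all three objectives are additive per column, so the
lexicographic DP is exact.

## Phased-siRNA detection

Phased siRNAs are 21-nt products whose 5' starts share a residue class
(register) modulo p = 21.  Both strands contribute one coordinate frame:
a minus-strand partner of a plus-strand cycle read at q has its leftmost
coordinate at q - 2 (two-nucleotide 3' overhangs of the processing
duplex), so minus-strand starts are shifted +2 before register
assignment.  Only reads of length p (optionally ±1) participate.

Within a window of length W = 189 (9 cycles; a multiple of p) there are
N = 2W candidate (position, strand) slots, K = 2W/p of them in any given
register.  With n occupied slots, k of them in-register, the p-value is
the exact hypergeometric upper tail P(X >= k), evaluated in integer
arithmetic.  Because a real locus's register is unknown, the per-window
statistic takes the register maximizing k and multiplies the tail by p
(Bonferroni), keeping the window test conservative at any alpha — the
suite verifies type-I error <= alpha on 10^4 uniform-null windows.
Windows slide by W/3 (rounded to a multiple of p), are corrected across
the genome by Benjamini-Hochberg, thresholded at alpha = 1e-4, and merged
into loci when they overlap; a locus must contain >= 4 distinct
in-register positions and reports the register of its best window in
scaffold coordinates.  W, p, alpha, the strand shift and the minimum
cycle count are all parameters.

## Target-site prediction

A candidate site is an ungapped antiparallel duplex between a miRNA and
an equally long target window; miRNA position i (1-based from the 5'
end) pairs site position L - i.  Non-Watson-Crick pairs are mismatches;
G:U wobble counts as a mismatch by default (a flag relaxes it, since the
original rule lineage is ambiguous on wobble).  A site is accepted when:
(a) at most four mismatches; (b) none at positions 10 or 11, where
cleavage requires complementarity; (c) no adjacent mismatch pair starting
in positions 2-12 — a run straddling position 12 therefore fails here;
(d) no run of more than two adjacent mismatches wholly beyond position
12; (e) no bulges, enforced by construction (only equal-length windows
are scored; target-side bulges are likewise out of model, the fully
determined reading of a no-bulge rule without a bulge scoring scheme).
Scanning slides every miRNA over every window of both target
orientations and reports accepted sites on forward-strand coordinates in
deterministic order.  Rejection reports the first violated rule in the
order a-d.

## Repeat coverage profiles

Reads are placed on each consensus of a RepBase-style library with up to
1 mismatch (genomic copies diverge from the family consensus; exact-only
matching would silently drop most repeat reads).  Coverage accumulates
over the full read footprint on the matched strand — a flag switches to
5'-start counting, since either convention is defensible — and
multimappers within the library are weighted 1/n_hits.  Elements are
ranked by reads per kilobase of consensus; within-library comparison
needs no library-size normalization.

## Synthetic data: what it emulates, and what it does not

The generator plants every feature class on a toy genome (default 8
scaffolds x 800 kb, GC 0.60 — the genome-wide GC of *Volvox carteri*,
whose AGO3-bound libraries motivated this toolkit) and simulates a
100,000-read library with class shares

    rRNA_tRNA 5%, miRNA 20%, phased 8%, repeat 30%,
    mRNA sense 15% / antisense 5%, hotspots 7%, background 10%.

The hotspot (7%) and background (10%) shares follow the reported AGO-IP
composition; the remaining shares were fixed once as a plausible AGO-IP
profile in which every class is abundant enough to test.  Choices that
matter:

* **Genome size.**  128 50-kb bins keep the uniform background near 0.08%
  per bin, so the eight planted hotspot bins (~0.9% of reads each) are
  unambiguous and the top-8 bin read share stays close to the planted 7%.
* **miRNA loci.**  30 standalone hairpins (8-nt flanks, 21-nt mature,
  15-nt loop, star = reverse complement with 2 planted substitutions,
  alternating 5p/3p arms) plus 2 TIR transposon elements (200 nt, 70-nt
  terminal inverted repeats) whose TIR stems act as precursors and which
  are simultaneously annotated as repeats.  Real precursors are under
  selection to fold cleanly; the generator emulates that by redrawing any
  candidate whose maximum-pairing fold, evaluated in genomic context and
  under small window jitters, does not route >= 16 mature bases into the
  star arm.  Locus reads split 80% mature (±1-nt 5' wobble, probability
  0.2), 10% star, 10% scattered — making caller precision thresholds
  testable.
* **Phased loci.**  6 loci x 8 exact 21-nt cycles, plus-strand reads at
  cycle starts, minus-strand reads offset -2 (duplex overhang geometry).
* **Repeats.**  3 families ("kangaroo_like", "gypsy_like", "jordan_like")
  of 1.5-kb consensus, 2 genomic copies each at 3% divergence, read
  shares 55/25/20 so the expression ranking has a planted winner;
  jordan_like reads come only from the element's 5' 500 nt to emulate
  end-biased transposon sRNA production.
* **Hotspots.**  8 loci, one per scaffold (hence distinct bins), each
  emitting a single identical 21-mer — matching the observation that
  hotspot reads are near-identical.
* **5'-U bias.**  The planted fraction (0.8) is enforced class by class:
  per-read rejection sampling for positionally sampled classes, and
  deterministically rounded assignment for the few fixed sequences
  (matures, stars, hotspot 21-mers, phased cycle starts), so the realized
  library fraction is within a few tenths of a percent of 0.8 for any
  seed.  Mature wobble positions are base-pinned so the ±1 shift
  preserves the 5' nucleotide.
* **Background.**  Uniform over the *unannotated* space, with a 100-nt
  margin so background reads can neither overlap planted features nor
  bridge into their read blocks; every simulated read therefore has an
  unambiguous truth class, and classifier output can be compared to truth
  at the 1% level.

Not emulated: sequencing errors (a uniform substitution rate is available
but off by default), quality-score variation (constant Q40), adapter
read-through, isomiR 3' heterogeneity, introns/spliced exons, nested or
fragmented repeats, and strand-biased mRNA contamination.  Passing the
planted-recovery suite therefore demonstrates algorithmic correctness
under clean AGO-IP-like composition, not robustness to platform
artefacts.

A second generator, `synthetic_mirna_catalogue`, emits a 490-record
mature-miRNA table whose family-size profile matches the published census
of the *V. carteri* predicted-miRNA catalogue (324 families, largest 48,
67 with >= 2 members).  It is a synthetic stand-in — the real
supplementary table is not redistributable — and exercises family
grouping, not sequence biology.

## Problem sizes and determinism

Default analyses run on the 6.4-Mb/100k-read bundle in about two minutes
on one CPU; unit tests use a 180-kb/8k-read bundle.  All randomness flows
from one integer seed through `numpy.random.default_rng`; genome, library
and every output table are byte-identical across runs for a fixed
configuration, and the pipeline manifest records parameters and input
digests for reproduction.

## Known limitations

* Maximum-pairing folding ignores thermodynamics; callers built on it
  need the boundary search described above, and long (> 300 nt)
  precursors are out of scope.
* The phasing statistic treats occupied positions as exchangeable; read
  abundance beyond occupancy is ignored, as in the classic formulation.
* Family grouping requires exact mature identity; single-nucleotide
  variants split families.
* The target rules are positional and energy-free; no accessibility or
  degradome evidence is modelled.
* The mapper is desk-scale (megabase genomes); for real genomes, import
  external SAM/BAM.
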