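import pytest

from srnakit.core_io import collapse_reads
from srnakit.mapping import map_reads
from srnakit.synthetic import SyntheticConfig, generate_genome, simulate_reads


def small_config(**overrides) -> SyntheticConfig:
    """A scaled-down synthetic bundle for unit tests (seconds, not minutes)."""
    defaults = dict(
        n_scaffolds=3,
        scaffold_length=60_000,
        n_mirna_loci=6,
        n_tir_transposons=1,
        n_phased_loci=2,
        repeat_copies=2,
        repeat_consensus_length=600,
        n_mrna_genes=4,
        mrna_length=500,
        n_hotspots=3,
        n_rrna_trna_loci=2,
        library_size=8_000,
        min_feature_gap=1_200,
        seed=42,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    cfg = small_config()
    genome, annotations, truth = generate_genome(cfg)
    reads, table = simulate_reads(genome, truth, cfg)
    return cfg, genome, annotations, truth, reads, table


@pytest.fixture(scope="session")
def small_alignments(small_bundle):
    cfg, genome, annotations, truth, reads, table = small_bundle
    collapsed = collapse_reads(reads)
    return map_reads(collapsed, genome)
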