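"""End-to-end orchestration: preprocess -> map -> call -> classify -> report.

`run_pipeline` is the library entry point the CLI wraps.  Every stage
parameter lives in :class:`PipelineConfig` (loadable from YAML), outputs
are plain TSV/GFF3/FASTA, and a JSON manifest records parameters and input
digests so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import core_io, preprocess, mapping, classify, mirna, phasing, repeats, targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reads: str = ""
    reads_format: str = "fastq"
    genome: str = ""
    annotations: str = ""
    annotations_format: str = "gff3"
    repeat_library: str = ""            # optional consensus multi-FASTA
    mirna_set_b: str = ""               # optional second-species miRNA FASTA
    output_dir: str = "srna_out"

    adapter: Optional[str] = None
    min_len: int = 18
    max_len: int = 26
    phred_cutoff: int = 20

    max_mismatches: int = 0
    max_hits: int = 50

    phase_length: int = 21
    phase_window: int = 189
    phase_alpha: float = 1e-4
    phase_min_cycles: int = 4

    hotspot_bin_width: int = 50_000
    hotspot_top_n: int = 8

    target_allow_wobble: bool = False
    repeat_max_mismatches: int = 1

    seed: int = 0

    mirna_params: mirna.MirnaCallerParams = field(default_factory=mirna.MirnaCallerParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mp = raw.pop("mirna_params", None)
        cfg = cls(**raw)
        if mp:
            cfg.mirna_params = mirna.MirnaCallerParams(**mp)
        return cfg


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of result objects.

    Emits, under ``config.output_dir``: composition tables, the category
    report, miRNA loci (GFF3 + mature FASTA) and family table, phased-locus
    GFF3, hotspot table, target-site table, repeat profiles and ranking,
    the optional conservation matrix, and a manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    genome = core_io.load_fasta(config.genome)
    scaffold_lengths = {name: len(seq) for name, seq in genome.items()}
    annotations = (
        core_io.load_annotations(config.annotations, config.annotations_format)
        if config.annotations
        else core_io.AnnotationSet()
    )

    raw = core_io.load_sequences(config.reads, config.reads_format)
    clean = preprocess.preprocess_reads(
        raw,
        adapter=config.adapter,
        min_len=config.min_len,
        max_len=config.max_len,
        phred_cutoff=config.phred_cutoff,
    )
    collapsed = core_io.collapse_reads(clean)
    results["n_raw"], results["n_clean"] = len(raw), len(clean)

    comp = preprocess.compute_composition(clean)
    results["composition"] = comp
    hist, posfreq = comp.to_frames()
    _write_tsv(hist, out / "length_histogram.tsv")
    posfreq.reset_index().to_csv(out / "positional_frequencies.tsv", sep="\t", index=False)

    alignments = mapping.map_reads(
        collapsed, genome, max_mismatches=config.max_mismatches, max_hits=config.max_hits
    )
    results["alignments"] = alignments

    loci = mirna.call_mirna_loci(alignments, genome, config.mirna_params)
    results["mirna_loci"] = loci
    mir_ann = core_io.AnnotationSet()
    mature_records = []
    with open(out / "mirna_mature.fasta", "w") as fh:
        for i, locus in enumerate(loci):
            name = f"mir_called_{i + 1}"
            mir_ann.add(
                core_io.GenomicInterval(
                    locus.precursor.scaffold, locus.precursor.start,
                    locus.precursor.end, locus.strand, "other", name,
                )
            )
            loc_str = f"{locus.precursor.scaffold}:{locus.mature_start}"
            mature_records.append((name, locus.mature_sequence, loc_str))
            fh.write(f">{name} {loc_str}\n{locus.mature_sequence}\n")
    core_io.write_annotations(mir_ann, out / "mirna_loci.gff3", "gff3")

    families = mirna.group_families(mature_records)
    results["families"] = families
    fam_df = pd.DataFrame(
        [
            {"mature_sequence": f.mature_sequence, "size": f.size,
             "members": ";".join(m[0] for m in f.members)}
            for f in families
        ]
    )
    _write_tsv(fam_df, out / "mirna_families.tsv")

    phased = phasing.detect_phased_loci(
        alignments, scaffold_lengths,
        phase=config.phase_length, window_length=config.phase_window,
        alpha=config.phase_alpha, min_cycles=config.phase_min_cycles,
    )
    results["phased_loci"] = phased
    ph_ann = core_io.AnnotationSet()
    for i, pl in enumerate(phased):
        ph_ann.add(
            core_io.GenomicInterval(
                pl.interval.scaffold, pl.interval.start, pl.interval.end,
                ".", "other", f"phased_{i + 1};register={pl.register};p={pl.p_value:.3g}",
            )
        )
    core_io.write_annotations(ph_ann, out / "phased_loci.gff3", "gff3")

    report = classify.assign_categories(
        alignments,
        annotations,
        mirna_loci=[l.precursor for l in loci],
        phased_loci=[pl.interval for pl in phased],
    )
    results["category_report"] = report
    cat_df = pd.DataFrame(
        [
            {
                "class": c,
                "count": report.counts[c],
                "fraction_all": report.fractions_all[c],
                "fraction_assigned": report.fractions_assigned.get(c, float("nan")),
            }
            for c in classify.CLASSES
        ]
    )
    _write_tsv(cat_df, out / "categories.tsv")

    intergenic_ids = set(
        report.assignments.loc[report.assignments["class"] == "intergenic", "read_id"]
    )
    intergenic_alignments = [a for a in alignments if a.read_id in intergenic_ids]
    hotspots = classify.detect_hotspots(
        intergenic_alignments, scaffold_lengths,
        bin_width=config.hotspot_bin_width, top_n=config.hotspot_top_n,
        total_reads=report.total_reads,
    )
    results["hotspots"] = hotspots
    hot_df = pd.DataFrame([asdict(h) for h in hotspots])
    _write_tsv(hot_df, out / "hotspots.tsv")

    if config.repeat_library:
        library = core_io.load_fasta(config.repeat_library)
        profiles = repeats.profile_repeat_coverage(
            collapsed, library, max_mismatches=config.repeat_max_mismatches
        )
        results["repeat_profiles"] = profiles
        _write_tsv(rank := repeats.rank_repeat_expression(profiles), out / "repeat_ranking.tsv")
        for p in profiles:
            _write_tsv(repeats.profile_to_frame(p), out / f"repeat_profile_{p.element}.tsv")
        site_list = targets.scan_targets(
            {rid: seq for rid, seq, _ in mature_records},
            library,
            allow_wobble=config.target_allow_wobble,
        )
        results["target_sites"] = site_list
        _write_tsv(pd.DataFrame(targets.sites_to_rows(site_list)), out / "target_sites.tsv")

    if config.mirna_set_b:
        set_b = core_io.load_fasta(config.mirna_set_b)
        set_a = {rid: seq for rid, seq, _ in mature_records}
        matrix = mirna.pairwise_identity_matrix(set_a, set_b)
        results["identity_matrix"] = matrix
        matrix.reset_index().to_csv(out / "identity_matrix.tsv", sep="\t", index=False)

    manifest = {
        "srnakit_version": __version__,
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(config).items()
        },
        "inputs": {
            name: _digest(path)
            for name, path in [
                ("reads", config.reads),
                ("genome", config.genome),
                ("annotations", config.annotations),
                ("repeat_library", config.repeat_library),
            ]
            if path
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
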