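"""Stage orchestration: simulate → variants → insertions → coverage →
repeats → validate → assembly-eval → report.

Each stage reads its inputs from the run directory (or from paths given in
the config), writes its outputs there, and can therefore be re-run or
resumed independently.  Every TSV carries a provenance header with the
thresholds and seed actually used.  All stage logic lives in the analysis
modules; this file only wires files to functions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    assembly_eval,
    coverage_length,
    insertion_recovery,
    io_formats,
    repeat_analysis,
    synthetic_data,
    validation,
    variant_profile,
)

STAGES = [
    "simulate",
    "variants",
    "insertions",
    "coverage",
    "repeats",
    "validate",
    "assembly-eval",
    "report",
]


@dataclass
class PipelineConfig:
    outdir: str = "longread_audit_run"
    seed: int = 0
    # inputs; defaults point at the simulate stage's own outputs
    reference: str | None = None
    sam: str | None = None
    reads: str | None = None
    repeats_bed: str | None = None
    genes_gff: str | None = None
    blocks_tsv: str | None = None
    contigs_fasta: str | None = None
    # thresholds, all surfaced
    min_read_length: int = 1500
    long_indel_cutoff: int = 9
    min_frac: float = 0.5
    blocker_threshold: int = 500
    confirm_depth: int = 10
    exon_depth: int = 2
    flank: int = 2500
    relocation_gap: int = 1000
    coverage_levels: list = field(default_factory=lambda: [3, 6, 12, 24])
    validation_short_depth: float = 30.0
    sim: synthetic_data.SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            cfg.sim = _sim_from_dict(sim_raw)
        return cfg

    def resolved_sim(self) -> synthetic_data.SimulationConfig:
        if self.sim is not None:
            sim = self.sim
        else:
            sim = _default_demo_sim()
        sim.seed = self.seed
        return sim

    def provenance(self) -> list[str]:
        keys = [
            "seed",
            "min_read_length",
            "long_indel_cutoff",
            "min_frac",
            "blocker_threshold",
            "confirm_depth",
            "exon_depth",
            "flank",
            "relocation_gap",
            "coverage_levels",
        ]
        return [f"# {k}={getattr(self, k)}" for k in keys]


def _sim_from_dict(d: dict) -> synthetic_data.SimulationConfig:
    d = dict(d)
    for key, cls in [
        ("variants", synthetic_data.VariantSpec),
        ("reads", synthetic_data.ReadSpec),
        ("errors", synthetic_data.ErrorSpec),
        ("aligner", synthetic_data.AlignerSpec),
        ("collapsed", synthetic_data.CollapsedRepeatSpec),
    ]:
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    if "tandem_clusters" in d:
        d["tandem_clusters"] = [
            synthetic_data.TandemClusterSpec(**t) if isinstance(t, dict) else t
            for t in d["tandem_clusters"]
        ]
    if "interspersed" in d:
        d["interspersed"] = [
            synthetic_data.InterspersedRepeatSpec(**t) if isinstance(t, dict) else t
            for t in d["interspersed"]
        ]
    return synthetic_data.SimulationConfig(**d)


def _default_demo_sim() -> synthetic_data.SimulationConfig:
    """A compact end-to-end demonstration genome exercising every stage."""
    return synthetic_data.SimulationConfig(
        chromosomes={"chrI": 1_000_000},
        tandem_clusters=[
            synthetic_data.TandemClusterSpec("TGATA", 400),
            synthetic_data.TandemClusterSpec("TGATA", 60),
        ],
        interspersed=[
            synthetic_data.InterspersedRepeatSpec("DNA", 400, 8),
            synthetic_data.InterspersedRepeatSpec("LINE", 700, 5),
            synthetic_data.InterspersedRepeatSpec("SINE", 250, 8),
            synthetic_data.InterspersedRepeatSpec("LTR", 500, 4),
        ],
        collapsed=synthetic_data.CollapsedRepeatSpec(unit_length=7200, donor_copies=20),
        variants=synthetic_data.VariantSpec(
            snv_rate=2e-5, n_insertions=12, n_deletions=4
        ),
        reads=synthetic_data.ReadSpec(depth=24.0),
        errors=synthetic_data.ErrorSpec(snv_rate=1e-4, ins_rate=2e-4, del_rate=1e-3),
        n_genes=25,
    )


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        for line in config.provenance():
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _path(config: PipelineConfig, attr: str, default_name: str) -> Path:
    given = getattr(config, attr)
    if given:
        return Path(given)
    return Path(config.outdir) / default_name


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.resolved_sim()
    bundle = synthetic_data.run_simulation(sim_cfg)
    io_formats.write_fasta(bundle.reference.genome, out / "reference.fa")
    io_formats.write_fasta(bundle.donor.genome, out / "donor.fa")
    io_formats.write_bed_repeats(bundle.reference.repeats, out / "repeats.bed")
    io_formats.write_gff_genes(bundle.reference.genes, out / "genes.gff3")
    synthetic_data.write_reads_fastq(bundle.reads, out / "reads.fastq")
    chrom_lengths = {c: len(s) for c, s in bundle.reference.genome.items()}
    io_formats.write_sam(bundle.records, chrom_lengths, out / "alignments.sam")
    _write_tsv(bundle.donor.truth_frame(), out / "truth_variants.tsv", config)
    _write_tsv(synthetic_data.reads_truth_frame(bundle.reads), out / "truth_reads.tsv", config)
    meta = {
        "collapsed_region": bundle.reference.collapsed_region,
        "n_unmapped": bundle.n_unmapped,
        "n_blocked_dropped": bundle.reads.n_blocked_dropped,
        "sim": sim_cfg.to_dict(),
    }
    with open(out / "simulation.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def _load_inputs(config: PipelineConfig):
    genome = io_formats.read_fasta(_path(config, "reference", "reference.fa"))
    records = io_formats.read_sam(_path(config, "sam", "alignments.sam"))
    return genome, records


def stage_variants(config: PipelineConfig) -> None:
    out = Path(config.outdir)
    genome, records = _load_inputs(config)
    events = variant_profile.extract_read_variants(records)
    track = coverage_length.depth_track(records, genome)
    calls = variant_profile.aggregate_sites(events, track, genome, min_frac=config.min_frac)
    summary = variant_profile.error_summary(events, records, config.long_indel_cutoff)
    _write_tsv(variant_profile.events_frame(events), out / "per_read_events.tsv", config)
    _write_tsv(summary.frame(), out / "error_summary.tsv", config)
    _write_tsv(summary.windows.reset_index(), out / "positional_profile.tsv", config)
    called = variant_profile.called_sites(calls, config.min_frac)
    rows = [
        {
            "type": c.vtype,
            "chrom": c.chrom,
            "pos": c.ref_pos,
            "size": c.size,
            "ref": c.ref_allele,
            "alt": c.alt,
            "support": len(c.support),
            "depth": c.depth,
        }
        for c in called
    ]
    _write_tsv(
        pd.DataFrame(rows, columns=["type", "chrom", "pos", "size", "ref", "alt", "support", "depth"]),
        out / "variants.tsv",
        config,
    )


def stage_insertions(config: PipelineConfig) -> None:
    out = Path(config.outdir)
    genome, records = _load_inputs(config)
    genes = io_formats.read_gff_genes(_path(config, "genes_gff", "genes.gff3"))
    events = variant_profile.extract_read_variants(records)
    track = coverage_length.depth_track(records, genome)
    calls = variant_profile.aggregate_sites(events, track, genome, min_frac=config.min_frac)
    called = variant_profile.called_sites(calls, config.min_frac)
    params = insertion_recovery.RecoveryParams(min_insertion_size=config.long_indel_cutoff)
    merged = insertion_recovery.recover_insertions(records, genome, called, genes, params)
    rows = [
        {
            "chrom": c.chrom,
            "breakpoint": c.breakpoint,
            "category": c.category,
            "size": c.size,
            "context": c.context,
            "support": len(c.support),
            "gapped": int(c.gapped),
        }
        for c in merged
    ]
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=["chrom", "breakpoint", "category", "size", "context", "support", "gapped"],
        ),
        out / "insertions.tsv",
        config,
    )
    io_formats.write_insertions_vcf(merged, genome, out / "insertions.vcf")
    with open(out / "insertions.json", "w") as fh:
        json.dump(
            [dataclasses.asdict(c) for c in merged],
            fh,
            indent=1,
        )


def stage_coverage(config: PipelineConfig) -> None:
    out = Path(config.outdir)
    genome, records = _load_inputs(config)
    genes = io_formats.read_gff_genes(_path(config, "genes_gff", "genes.gff3"))
    repeats = io_formats.read_bed_repeats(_path(config, "repeats_bed", "repeats.bed"))
    track = coverage_length.depth_track(records, genome)
    gaps = coverage_length.extract_gaps(track)
    with open(out / "depth.bedgraph", "w") as fh:
        for chrom, arr in track.depth.items():
            change = np.nonzero(np.diff(arr))[0] + 1
            bounds = [0, *change.tolist(), len(arr)]
            for s, e in zip(bounds, bounds[1:]):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(arr[s])}\n")
    with open(out / "gaps.bed", "w") as fh:
        for g in gaps:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\n")
    lengths = [len(r.read_sequence) for r in records if not r.is_supplementary]
    median, n50_val, strata = coverage_length.length_stats(lengths)
    _write_tsv(strata.frame(), out / "length_hist.tsv", config)
    masks = coverage_length.target_masks(genome, genes, repeats)
    curves = coverage_length.accumulative_coverage(records, genome, masks)
    _write_tsv(curves, out / "accumulative_curves.tsv", config)
    profile = coverage_length.per_chromosome_profile(records, genome)
    _write_tsv(profile, out / "chromosome_profile.tsv", config)
    ip = coverage_length.intersection_point(curves, "genome")
    summary = pd.DataFrame(
        [
            {"metric": "median_read_length", "value": median},
            {"metric": "read_n50", "value": n50_val},
            {"metric": "mean_depth", "value": track.mean},
            {"metric": "n_gaps", "value": len(gaps)},
            {"metric": "longest_gap", "value": gaps[0].length if gaps else 0},
            {"metric": "intersection_L_genome", "value": ip.L},
            {"metric": "intersection_frac_genome", "value": ip.frac_shorter},
        ]
    )
    _write_tsv(summary, out / "coverage_summary.tsv", config)


def stage_repeats(config: PipelineConfig) -> None:
    out = Path(config.outdir)
    genome, records = _load_inputs(config)
    repeats = io_formats.read_bed_repeats(_path(config, "repeats_bed", "repeats.bed"))
    genes = io_formats.read_gff_genes(_path(config, "genes_gff", "genes.gff3"))
    track = coverage_length.depth_track(records, genome)
    gaps = coverage_length.extract_gaps(track)
    levels = [l for l in config.coverage_levels if l <= track.mean + 0.5]
    report = repeat_analysis.recovery_rates(
        records, genome, repeats, genes, levels, config.seed
    )
    _write_tsv(report.rates, out / "recovery_rates.tsv", config)
    _write_tsv(report.gene_rates, out / "gene_recovery_rates.tsv", config)
    _write_tsv(repeat_analysis.gap_enrichment(gaps, repeats, genome), out / "gap_enrichment.tsv", config)
    clusters = repeat_analysis.flag_blockers(
        repeat_analysis.find_tandem_clusters(genome), config.blocker_threshold
    )
    with open(out / "tandem_clusters.bed", "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.unit}\t{c.copies:.1f}\t"
                f"{'blocker' if c.blocker else '.'}\n"
            )
    rows = []
    sim_meta = Path(config.outdir) / "simulation.json"
    if sim_meta.exists():
        with open(sim_meta) as fh:
            meta = json.load(fh)
        region = meta.get("collapsed_region")
        if region:
            chrom, s, e = region[0], int(region[1]), int(region[2])
            track_supp = coverage_length.depth_track(
                io_formats.read_sam(_path(config, "sam", "alignments.sam"), keep_supplementary=True),
                genome,
                include_supplementary=True,
            )
            est = repeat_analysis.copy_number(track_supp, chrom, s, e)
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "copy_number": est.value,
                    "copy_number_naive": est.value_naive,
                    "region_mean_depth": est.region_mean,
                    "genome_mean_depth": est.genome_mean,
                }
            )
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "start",
                "end",
                "copy_number",
                "copy_number_naive",
                "region_mean_depth",
                "genome_mean_depth",
            ],
        ),
        out / "copy_number.tsv",
        config,
    )


def stage_validate(config: PipelineConfig) -> None:
    out = Path(config.outdir)
    genome = io_formats.read_fasta(_path(config, "reference", "reference.fa"))
    ins_json = out / "insertions.json"
    if not ins_json.exists():
        raise FileNotFoundError(
            "insertions.json missing; run the 'insertions' stage first"
        )
    with open(ins_json) as fh:
        raw = json.load(fh)
    calls = [
        insertion_recovery.InsertionCall(
            c["category"], c["chrom"], c["breakpoint"], c["sequence"], c["size"], c["support"], c["context"]
        )
        for c in raw
    ]
    contigs = validation.build_validation_reference(calls, genome, config.flank)
    io_formats.write_fasta(
        {c.name: c.sequence for c in contigs}, out / "validation_ref.fa"
    )
    # synthetic short-read confirmation set over each contig
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    short_records = []
    for c in contigs:
        short_records.extend(
            synthetic_data.simulate_contig_reads(
                c.name, c.sequence, config.validation_short_depth, rng
            )
        )
    status = validation.confirm_genomic(contigs, short_records, config.confirm_depth)
    _write_tsv(status, out / "validation.tsv", config)


def stage_assembly(config: PipelineConfig) -> None:
    out = Path(config.outdir)
    genome = io_formats.read_fasta(_path(config, "reference", "reference.fa"))
    if config.blocks_tsv and config.contigs_fasta:
        blocks = assembly_eval.read_blocks_tsv(config.blocks_tsv)
        contigs = dict(io_formats.read_fasta(config.contigs_fasta))
    else:
        contigs, blocks, _ = assembly_eval.make_synthetic_assembly(genome, config.seed)
        io_formats.write_fasta(contigs, out / "contigs.fa")
        _write_tsv(assembly_eval.blocks_frame(blocks), out / "contig_blocks.tsv", config)
    report = assembly_eval.alignment_metrics(
        blocks, contigs, genome, config.relocation_gap
    )
    _write_tsv(report.frame(), out / "assembly_report.tsv", config)


def stage_report(config: PipelineConfig) -> None:
    out = Path(config.outdir)
    rows = []
    for name in [
        "error_summary.tsv",
        "coverage_summary.tsv",
        "assembly_report.tsv",
        "validation.tsv",
        "insertions.tsv",
    ]:
        p = out / name
        if not p.exists():
            continue
        df = _read_tsv(p)
        rows.append({"artifact": name, "rows": len(df)})
    _write_tsv(pd.DataFrame(rows), out / "report_index.tsv", config)


_STAGE_FN = {
    "simulate": stage_simulate,
    "variants": stage_variants,
    "insertions": stage_insertions,
    "coverage": stage_coverage,
    "repeats": stage_repeats,
    "validate": stage_validate,
    "assembly-eval": stage_assembly,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None, skip: list[str] = ()) -> None:
    """Run the requested stages (default: all) in dependency order."""
    todo = [s for s in STAGES if (stages is None or s in stages) and s not in skip]
    for s in todo:
        _STAGE_FN[s](config)
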