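"""Generator contracts: determinism, conservation, truth-table consistency,
length mixture, error model and the aligner-emulator regimes."""

import dataclasses

import numpy as np
import pytest

from longread_audit import synthetic_data as sd
from longread_audit.io_formats import read_fasta, revcomp


def small_config(**kw):
    defaults = dict(
        seed=42,
        chromosomes={"chrI": 120_000},
        errors=sd.ErrorSpec(snv_rate=0.0, ins_rate=0.0, del_rate=0.0),
        reads=sd.ReadSpec(depth=8.0),
        n_genes=6,
    )
    defaults.update(kw)
    return sd.SimulationConfig(**defaults)


class TestReference:
    def test_tandem_cluster_construction(self):
        cfg = small_config(tandem_clusters=[sd.TandemClusterSpec("TGATA", 120)])
        bundle = sd.build_reference(cfg)
        clusters = [r for r in bundle.repeats if r.unit_sequence == "TGATA"]
        assert len(clusters) == 1
        c = clusters[0]
        assert c.length == 600 and c.repeat_class == "Simple"
        assert bundle.genome[c.chrom][c.start : c.start + 10] == "TGATATGATA"

    def test_zero_repeats_gives_background_only(self):
        bundle = sd.build_reference(small_config(n_genes=0))
        assert bundle.repeats == []
        assert set(bundle.genome["chrI"]) <= set("ACGT")

    def test_collapsed_unit_single_copy_in_reference(self):
        cfg = small_config(collapsed=sd.CollapsedRepeatSpec(unit_length=3000, donor_copies=5))
        bundle = sd.build_reference(cfg)
        chrom, s, e = bundle.collapsed_region
        assert e - s == 3000
        donor = sd.make_donor(bundle, cfg)
        blocks = [b for b in donor.blocks[chrom] if b.kind == "COLLAPSED"]
        assert len(blocks) == 1
        b = blocks[0]
        assert b.donor_end - b.donor_start == 5 * 3000
        unit = bundle.genome[chrom][s:e]
        assert donor.genome[chrom][b.donor_start : b.donor_start + 6000] == unit * 2

    def test_content_overflow_raises(self):
        cfg = small_config(
            chromosomes={"chrI": 20_000},
            tandem_clusters=[sd.TandemClusterSpec("TGATA", 1000, count=10)],
        )
        with pytest.raises(ValueError, match="exceeds"):
            sd.build_reference(cfg)


class TestDonor:
    def test_zero_variants_donor_equals_reference(self):
        cfg = small_config()
        bundle = sd.build_reference(cfg)
        donor = sd.make_donor(bundle, cfg)
        assert donor.genome == bundle.genome
        assert donor.truth == []

    def test_snv_recorded_with_changed_base(self):
        cfg = small_config(variants=sd.VariantSpec(snv_rate=1e-4))
        bundle = sd.build_reference(cfg)
        donor = sd.make_donor(bundle, cfg)
        snvs = [t for t in donor.truth if t.vtype == "SNV"]
        assert len(snvs) == round(1e-4 * 120_000)
        for t in snvs:
            assert bundle.genome[t.chrom][t.ref_pos] == t.ref_allele
            assert t.alt_seq != t.ref_allele

    def test_insertion_truth_and_exon_context(self):
        cfg = small_config(
            chromosomes={"chrI": 400_000},
            variants=sd.VariantSpec(
                n_insertions=6,
                insertion_size_range=(400, 500),
                exon_insertion_fraction=1.0,
                min_event_spacing=15000,
            ),
            n_genes=30,
        )
        bundle = sd.build_reference(cfg)
        donor = sd.make_donor(bundle, cfg)
        ins = [t for t in donor.truth if t.vtype == "INS"]
        assert len(ins) == 6
        assert all(t.context == "coding_exon" for t in ins)
        # the donor genuinely contains the inserted sequence at the breakpoint
        for t in ins:
            block = next(
                b
                for b in donor.blocks[t.chrom]
                if b.kind == "INS" and b.ref_start == t.ref_pos
            )
            assert donor.genome[t.chrom][block.donor_start : block.donor_end] == t.alt_seq

    def test_deletion_removes_reference_interval(self):
        cfg = small_config(
            chromosomes={"chrI": 300_000},
            variants=sd.VariantSpec(n_deletions=3, deletion_size_range=(50, 80)),
        )
        bundle = sd.build_reference(cfg)
        donor = sd.make_donor(bundle, cfg)
        dels = [t for t in donor.truth if t.vtype == "DEL"]
        assert len(dels) == 3
        total_del = sum(t.size for t in dels)
        assert len(donor.genome["chrI"]) == 300_000 - total_del


class TestReads:
    def test_lengths_respect_minimum_and_bimodality(self, rng):
        spec = sd.ReadSpec()
        lengths = sd.sample_read_lengths(spec, 4000, rng)
        assert lengths.min() >= 1500
        short = np.mean((lengths >= 1500) & (lengths < 4000))
        long = np.mean(lengths > 8000)
        assert short > 0.1 and long > 0.4  # both modes populated

    def test_read_count_matches_analytic_expectation(self, error_sim):
        cfg = error_sim.config
        total = error_sim.donor.genome.total_length
        expected = cfg.reads.depth * total / sd.truncated_mixture_mean(cfg.reads)
        assert abs(error_sim.reads.n_sampled - expected) <= 0.01 * expected

    def test_error_free_reads_are_exact_donor_substrings(self, null_sim):
        donor = null_sim.donor.genome
        for read in null_sim.reads.reads[:200]:
            assert read.sequence == donor[read.chrom][read.donor_start : read.donor_end]

    def test_realized_error_rates_within_three_se(self, error_sim):
        cfg = error_sim.config.errors
        bases = sum(len(r.sequence) for r in error_sim.reads.reads)
        for kind, rate in [("SNV", cfg.snv_rate), ("INS", cfg.ins_rate), ("DEL", cfg.del_rate)]:
            n = sum(
                sum(e.kind == kind for e in r.edits) for r in error_sim.reads.reads
            )
            se = np.sqrt(rate * (1 - rate) / bases)
            assert abs(n / bases - rate) <= 3 * se, kind

    def test_fastq_orientation(self, null_sim, tmp_path):
        read = next(r for r in null_sim.reads.reads if r.strand == "-")
        assert read.fastq_sequence == revcomp(read.sequence)


class TestEmulator:
    def test_conservation_cigar_vs_fastq_length(self, error_sim):
        for rec in error_sim.records[:500]:
            assert rec.read_length == len(rec.read_sequence)

    def test_small_insertion_with_anchored_flanks_is_cigar_i_op(self):
        cfg = small_config(
            chromosomes={"chrI": 200_000},
            variants=sd.VariantSpec(n_insertions=1, insertion_size_range=(20, 20)),
            reads=sd.ReadSpec(depth=15.0),
        )
        b = sd.run_simulation(cfg)
        (truth,) = [t for t in b.donor.truth if t.vtype == "INS"]
        assert truth.expected_regime == "cigar"
        hits = [
            r
            for r in b.records
            if any(op == "I" and n == 20 for op, n in r.cigar)
        ]
        assert hits, "no I-op records over the injected insertion"

    def test_large_insertion_becomes_soft_clip(self):
        cfg = small_config(
            chromosomes={"chrI": 200_000},
            variants=sd.VariantSpec(n_insertions=1, insertion_size_range=(800, 800)),
            reads=sd.ReadSpec(depth=15.0),
        )
        b = sd.run_simulation(cfg)
        (truth,) = [t for t in b.donor.truth if t.vtype == "INS"]
        assert truth.expected_regime == "clip"
        assert not any(op == "I" and n >= 800 for r in b.records for op, n in r.cigar)
        clips = [
            r
            for r in b.records
            if any(op == "S" and n >= 800 for op, n in r.cigar)
            and (r.ref_start == truth.ref_pos or r.ref_end == truth.ref_pos)
        ]
        assert clips, "no unaligned ends at the insertion breakpoint"

    def test_blocked_read_is_withheld(self, null_sim):
        cfg = null_sim.config
        read = dataclasses.replace(null_sim.reads.reads[0], blocked=True)
        sim = sd.SimulatedReads([read], 0, 1)
        records, _ = sd.emulate_alignment(sim, null_sim.reference, null_sim.donor, cfg)
        assert records == []

    def test_no_read_covers_blocked_cluster(self, tandem_sim):
        blocked = sd.blocked_clusters(tandem_sim.reference, 500)
        assert blocked
        for cl in blocked:
            for rec in tandem_sim.records:
                assert rec.ref_end <= cl.start or rec.ref_start >= cl.end

    def test_md_tags_consistent_with_reference(self, error_sim):
        from longread_audit.io_formats import build_md

        ref = error_sim.reference.genome
        for rec in error_sim.records[:100]:
            assert rec.md == build_md(rec.cigar, rec.read_sequence, ref[rec.chrom], rec.ref_start)


class TestDeterminism:
    def test_identical_config_gives_identical_outputs(self, tmp_path):
        cfg1 = small_config(variants=sd.VariantSpec(snv_rate=5e-5, n_insertions=1))
        cfg1.errors = sd.ErrorSpec()  # default nonzero error rates
        cfg2 = small_config(variants=sd.VariantSpec(snv_rate=5e-5, n_insertions=1))
        cfg2.errors = sd.ErrorSpec()
        out = []
        for i, cfg in enumerate([cfg1, cfg2]):
            b = sd.run_simulation(cfg)
            fq = tmp_path / f"r{i}.fastq"
            sd.write_reads_fastq(b.reads, fq)
            out.append(
                (
                    fq.read_bytes(),
                    b.donor.genome["chrI"],
                    [(r.read_id, r.ref_start, tuple(r.cigar), r.md) for r in b.records],
                )
            )
        assert out[0] == out[1]
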