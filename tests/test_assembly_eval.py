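"""Contig metrics, misassembly classification, NA50 and the PAF converter."""

import numpy as np
import pytest

from longread_audit import assembly_eval as ae
from longread_audit.io_formats import GenomeSequences


def block(contig, cs, ce, chrom="chrI", rs=0, re_=None, strand="+"):
    return ae.AlignmentBlock(contig, cs, ce, chrom, rs, re_ if re_ is not None else rs + (ce - cs), strand)


class TestContigStats:
    def test_by_definition(self):
        r = ae.contig_stats({f"c{i}": "A" * 10 for i in range(4)})
        assert r.n50 == 10 and r.l50 == 2

    def test_single_contig(self):
        r = ae.contig_stats({"c": "ACGT" * 25})
        assert r.n50 == 100 and r.l50 == 1 and r.gc_percent == 50.0

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            lengths = rng.integers(100, 50_000, size=int(rng.integers(1, 40)))
            contigs = {f"c{i}": "A" * int(n) for i, n in enumerate(lengths)}
            r = ae.contig_stats(contigs)
            desc = sorted(lengths, reverse=True)
            total = sum(desc)
            acc = 0
            for rank, x in enumerate(desc, start=1):
                acc += x
                if acc >= total / 2:
                    assert r.n50 == x and r.l50 == rank
                    break

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ae.contig_stats({})


MISASSEMBLY_CASES = [
    # (description, block2 kwargs, expected kind or None)
    ("different chromosomes", dict(chrom="chrV", rs=0), "translocation"),
    ("opposite strands", dict(rs=10_000, strand="-"), "inversion"),
    ("contiguous same strand", dict(rs=10_000), None),
    ("forward jump 40 kb", dict(rs=50_000), "relocation"),
    ("jump 999 below threshold", dict(rs=10_999), None),
    ("jump exactly 1000", dict(rs=11_000), "relocation"),
    ("backward overlap 1000", dict(rs=9_000), "relocation"),
    ("backward overlap 999", dict(rs=9_001), None),
    ("reverse pair contiguous", dict(rs=10_000), None),  # handled below with -/-
    ("reverse pair jump", dict(rs=50_000), "relocation"),
    ("translocation opposite strand", dict(chrom="chrV", rs=0, strand="-"), "translocation"),
    ("inversion far away", dict(rs=90_000, strand="-"), "inversion"),
]


class TestMisassemblies:
    @pytest.mark.parametrize(
        "desc,kw,expected", MISASSEMBLY_CASES, ids=[c[0] for c in MISASSEMBLY_CASES]
    )
    def test_twelve_case_suite(self, desc, kw, expected):
        if "reverse pair" in desc:
            # both blocks on "−": the contig walks the reference backwards,
            # so block1 sits at higher reference coordinates
            b2_rs = kw["rs"]
            b1 = ae.AlignmentBlock("c", 0, 10_000, "chrI", b2_rs + 10_000, b2_rs + 20_000, "-")
            jump = 0 if expected is None else 40_000
            b2 = ae.AlignmentBlock("c", 10_000, 20_000, "chrI", b1.r_start - 10_000 - jump, b1.r_start - jump, "-")
            events = ae.classify_misassemblies([b1, b2])
        else:
            b1 = block("c", 0, 10_000, rs=0)
            b2 = block("c", 10_000, 20_000, **kw)
            events = ae.classify_misassemblies([b1, b2])
        kinds = [e.kind for e in events]
        assert kinds == ([] if expected is None else [expected]), desc

    def test_single_block_contig_no_events(self):
        assert ae.classify_misassemblies([block("c", 0, 5000)]) == []


class TestAlignmentMetrics:
    def test_coverage_and_duplication(self):
        genome = GenomeSequences(chrI="A" * 100_000)
        contigs = {"c0": "A" * 10_000}
        blocks = [block("c0", 0, 10_000, rs=0)]
        r = ae.alignment_metrics(blocks, contigs, genome)
        assert r.genome_coverage_percent == pytest.approx(10.0)
        assert r.duplication_ratio == pytest.approx(1.0)

    def test_double_coverage_doubles_ratio(self):
        genome = GenomeSequences(chrI="A" * 100_000)
        contigs = {"c0": "A" * 10_000, "c1": "A" * 10_000}
        blocks = [block("c0", 0, 10_000, rs=0), block("c1", 0, 10_000, rs=0)]
        r = ae.alignment_metrics(blocks, contigs, genome)
        assert r.duplication_ratio == pytest.approx(2.0)

    def test_na50_on_hand_broken_contig(self):
        genome = GenomeSequences(chrI="A" * 1_000_000)
        contigs = {"c0": "A" * 20_000}
        blocks = [
            block("c0", 0, 10_000, rs=0),
            block("c0", 10_000, 20_000, rs=500_000),  # relocation at the midpoint
        ]
        r = ae.alignment_metrics(blocks, contigs, genome)
        assert r.relocations == 1
        assert r.n50 == 20_000
        assert r.na50 == 10_000  # the two hand-broken halves
        assert r.na50 <= r.n50

    def test_na50_never_exceeds_n50_on_random_sets(self, rng):
        genome = GenomeSequences(chrI="A" * 2_000_000, chrII="A" * 1_000_000)
        for seed in range(20):
            contigs, blocks, _ = ae.make_synthetic_assembly(
                genome,
                seed=seed,
                n_contigs=12,
                n_relocations=int(rng.integers(0, 3)),
                n_translocations=int(rng.integers(0, 2)),
                n_inversions=int(rng.integers(0, 2)),
            )
            r = ae.alignment_metrics(blocks, contigs, genome)
            assert r.na50 <= r.n50

    def test_unaligned_counts(self):
        genome = GenomeSequences(chrI="A" * 100_000)
        contigs = {"c0": "A" * 10_000, "c1": "A" * 10_000, "c2": "A" * 10_000}
        blocks = [
            block("c0", 0, 10_000, rs=0),
            block("c1", 0, 2_000, rs=20_000),  # 20% aligned → partially unaligned
        ]
        r = ae.alignment_metrics(blocks, contigs, genome)
        assert r.fully_unaligned == 1 and r.partially_unaligned == 1


class TestSyntheticAssembly:
    def test_expected_events_recovered(self):
        genome = GenomeSequences(chrI="A" * 2_000_000, chrII="A" * 1_000_000)
        contigs, blocks, expected = ae.make_synthetic_assembly(
            genome, seed=4, n_contigs=20, n_relocations=2, n_translocations=1, n_inversions=1
        )
        events = ae.classify_misassemblies(blocks)
        kinds = sorted(e.kind for e in events)
        assert kinds == sorted(expected)


class TestPaf:
    def test_converter(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(
            "c0\t5000\t0\t4800\t+\tchrI\t100000\t1000\t5800\t4700\t4800\t60\n"
        )
        (b,) = ae.paf_to_blocks(p)
        assert (b.contig, b.c_start, b.c_end) == ("c0", 0, 4800)
        assert (b.chrom, b.r_start, b.r_end, b.strand) == ("chrI", 1000, 5800, "+")
        assert b.identity == pytest.approx(4700 / 4800)
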