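"""The four missing-sequence recovery routes, merging and context."""

import numpy as np
import pytest

from longread_audit import insertion_recovery as ir
from longread_audit import variant_profile as vp
from longread_audit.io_formats import GAP_MARKER, GeneModel, GenomeSequences


@pytest.fixture(scope="module")
def ref_genome():
    rng = np.random.default_rng(7)
    return GenomeSequences(c1="".join(rng.choice(list("ACGT"), size=20_000)))


def make_call(vtype, size, pos=5000, support=("r1", "r2")):
    return vp.VariantCall(vtype, "c1", pos, size, "", "G" * size, list(support), 3)


class TestWithinRead:
    def test_size_threshold(self):
        calls = [make_call("INS", 12), make_call("INS", 5), make_call("DEL", 30)]
        out = ir.find_within_read(calls)
        assert len(out) == 1
        assert out[0].category == "within_read" and out[0].size == 12


class TestSelfMapped:
    def test_spanning_clip_recovers_exact_insertion(self, ref_genome, rng):
        bp = 8000
        ins = "".join(rng.choice(list("ACGT"), size=300))
        clip = ins + ref_genome["c1"][bp : bp + 600]
        end = ir.UnalignedEnd("r1", "right", "c1", bp, clip, (6000, bp))
        calls, leftovers = ir.find_self_mapped([end], ref_genome)
        assert leftovers == []
        (c,) = calls
        assert c.sequence == ins and c.breakpoint == bp and c.category == "self_mapped"

    def test_pure_novel_clip_left_for_pairing(self, ref_genome, rng):
        ins = "".join(rng.choice(list("ACGT"), size=400))
        end = ir.UnalignedEnd("r1", "right", "c1", 8000, ins, (6000, 8000))
        calls, leftovers = ir.find_self_mapped([end], ref_genome)
        assert calls == [] and leftovers == [end]

    def test_short_second_anchor_rejected(self, ref_genome, rng):
        bp = 8000
        ins = "".join(rng.choice(list("ACGT"), size=300))
        clip = ins + ref_genome["c1"][bp : bp + 100]  # anchor < relax_min_anchor
        end = ir.UnalignedEnd("r1", "right", "c1", bp, clip, (6000, bp))
        calls, leftovers = ir.find_self_mapped([end], ref_genome)
        assert calls == []


class TestPairing:
    def test_overlapping_clips_merge(self, ref_genome, rng):
        ins = "".join(rng.choice(list("ACGT"), size=1000))
        a = ir.UnalignedEnd("rA", "right", "c1", 5000, ins[:700], (3000, 5000))
        b = ir.UnalignedEnd("rB", "left", "c1", 5000, ins[400:], (5000, 7000))
        cross, close = ir.pair_ends([a, b])
        assert close == []
        (c,) = cross
        assert c.sequence == ins and c.size == 1000

    def test_non_overlapping_clips_gapped_call(self, ref_genome, rng):
        ins = "".join(rng.choice(list("ACGT"), size=1000))
        a = ir.UnalignedEnd("rA", "right", "c1", 5000, ins[:400], (3000, 5000))
        b = ir.UnalignedEnd("rB", "left", "c1", 5000, ins[600:], (5000, 7000))
        cross, close = ir.pair_ends([a, b])
        assert cross == []
        (c,) = close
        assert c.gapped and c.size == 800 and c.sequence.count(GAP_MARKER) == 1

    def test_distant_breakpoints_not_paired(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        a = ir.UnalignedEnd("rA", "right", "c1", 5000, seq, (3000, 5000))
        b = ir.UnalignedEnd("rB", "left", "c1", 55_000, seq, (55_000, 57_000))
        cross, close = ir.pair_ends([a, b])
        assert cross == [] and close == []

    def test_same_read_never_self_paired(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        a = ir.UnalignedEnd("rX", "right", "c1", 5000, seq, (3000, 5000))
        b = ir.UnalignedEnd("rX", "left", "c1", 5000, seq, (5000, 7000))
        cross, close = ir.pair_ends([a, b])
        assert cross == [] and close == []


class TestMerging:
    def test_precedence_and_support_union(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=439))
        a = ir.InsertionCall("within_read", "c1", 1000, seq, 439, ["r1", "r2"])
        b = ir.InsertionCall("self_mapped", "c1", 1003, seq, 439, ["r3"])
        merged = ir.merge_calls([a, b])
        assert len(merged) == 1
        m = merged[0]
        assert m.category == "within_read"
        assert m.support == ["r1", "r2", "r3"]

    def test_different_sequences_not_merged(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), size=200))
        s2 = "".join(rng.choice(list("ACGT"), size=200))
        a = ir.InsertionCall("within_read", "c1", 1000, s1, 200, ["r1"])
        b = ir.InsertionCall("self_mapped", "c1", 1002, s2, 200, ["r2"])
        assert len(ir.merge_calls([a, b])) == 2

    def test_idempotence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        calls = [
            ir.InsertionCall("self_mapped", "c1", 1000, seq, 120, ["r1"]),
            ir.InsertionCall("cross_mapped", "c1", 1004, seq, 120, ["r2"]),
            ir.InsertionCall("within_read", "c1", 9000, seq, 120, ["r3"]),
        ]
        once = ir.merge_calls(calls)
        twice = ir.merge_calls(once)
        assert [(c.chrom, c.breakpoint, c.category, tuple(c.support)) for c in once] == [
            (c.chrom, c.breakpoint, c.category, tuple(c.support)) for c in twice
        ]

    def test_gapped_merges_into_full_call(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        full = ir.InsertionCall("self_mapped", "c1", 1000, seq, 600, ["r1"])
        gapped = ir.InsertionCall(
            "close_breakpoint", "c1", 1001, seq[:200] + GAP_MARKER + seq[400:], 400, ["r2"]
        )
        merged = ir.merge_calls([full, gapped])
        assert len(merged) == 1
        assert merged[0].category == "self_mapped" and not merged[0].gapped


class TestContext:
    def test_context_classes(self):
        genes = [
            GeneModel("g1", "c1", "+", [(1000, 1200), (1500, 1700)], coding=True),
        ]
        calls = [
            ir.InsertionCall("within_read", "c1", 1100, "A" * 20, 20, ["r"]),
            ir.InsertionCall("within_read", "c1", 1210, "A" * 20, 20, ["r"]),  # 10 bp past exon
            ir.InsertionCall("within_read", "c1", 5000, "A" * 20, 20, ["r"]),
        ]
        ir.annotate_context(calls, genes)
        assert [c.context for c in calls] == ["coding_exon", "intron", "intergenic"]


class TestTruthRecovery:
    def test_error_free_simulation_recovers_insertions_exactly(self, insertion_sim):
        """Every injected insertion ≥ 9 bp at 12× is one merged call with an
        exact breakpoint and the exact injected sequence."""
        b = insertion_sim
        records = b.records
        genome = b.reference.genome
        from longread_audit.coverage_length import depth_track

        events = vp.extract_read_variants(records)
        track = depth_track(records, genome)
        sites = vp.aggregate_sites(events, track, genome)
        called = vp.called_sites(sites)
        merged = ir.recover_insertions(records, genome, called, b.reference.genes)
        truth = [t for t in b.donor.truth if t.vtype == "INS"]
        by_bp = {}
        for c in merged:
            by_bp.setdefault((c.chrom, c.breakpoint), []).append(c)
        n_exact = 0
        for t in truth:
            t_pos, t_seq = vp.left_align_indel("INS", genome[t.chrom], t.ref_pos, t.size, t.alt_seq)
            hits = by_bp.get((t.chrom, t_pos), [])
            if len(hits) == 1 and hits[0].sequence == t_seq:
                n_exact += 1
        assert n_exact >= 0.9 * len(truth)
        # no truth insertion maps to more than one merged call
        for t in truth:
            near = [
                c for c in merged if c.chrom == t.chrom and abs(c.breakpoint - t.ref_pos) <= 10
            ]
            assert len(near) <= 1
        assert len(merged) <= len(truth)
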