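"""Variant extraction, site aggregation, error ratios and positional profile."""

import numpy as np
import pytest
from Bio import Align

from longread_audit import variant_profile as vp
from longread_audit.coverage_length import DepthTrack, depth_track
from longread_audit.io_formats import AlignmentRecord, GenomeSequences, build_md


def rec(cigar, seq, md=None, ref_start=100, read_id="r1", strand="+"):
    return AlignmentRecord(
        read_id=read_id,
        chrom="c1",
        ref_start=ref_start,
        strand=strand,
        cigar=cigar,
        read_sequence=seq,
        md=md,
    )


class TestExtraction:
    def test_cigar_insertion_event(self):
        events = vp.extract_read_variants([rec([("M", 5), ("I", 2), ("M", 3)], "AAAAATTCCC", md="8")])
        ins = [e for e in events if e.vtype == "INS"]
        assert len(ins) == 1 and ins[0].size == 2 and ins[0].alt == "TT"
        assert ins[0].ref_pos == 105

    def test_identity_alignment_no_events(self):
        assert vp.extract_read_variants([rec([("M", 8)], "ACGTACGT", md="8")]) == []

    def test_deletion_with_ref_allele_from_md(self):
        events = vp.extract_read_variants([rec([("M", 3), ("D", 2), ("M", 3)], "AAACCC", md="3^AC3")])
        dels = [e for e in events if e.vtype == "DEL"]
        assert len(dels) == 1 and dels[0].size == 2

    def test_missing_md_skips_snvs_but_keeps_indels(self):
        skipped = []
        events = vp.extract_read_variants(
            [rec([("M", 5), ("I", 1), ("M", 3)], "AAAATGCCC")], skipped_md=skipped
        )
        assert [e.vtype for e in events] == ["INS"]
        assert skipped == ["r1"]

    def test_soft_clips_are_not_variants(self):
        events = vp.extract_read_variants([rec([("S", 4), ("M", 4)], "TTTTACGT", md="4")])
        assert events == []


# ---------------------------------------------------------------------------


def brute_force_diff(ref_window, read, ref_offset):
    """Independent oracle: global-alignment diff between read and reference."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(ref_window, read)[0]
    t_blocks, q_blocks = aln.aligned
    out = []
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for k in range(te - ts):
            if ref_window[ts + k] != read[qs + k]:
                out.append(("SNV", ref_offset + ts + k, 1, read[qs + k]))
    for i in range(len(t_blocks) - 1):
        t_gap = t_blocks[i + 1][0] - t_blocks[i][1]
        q_gap = q_blocks[i + 1][0] - q_blocks[i][1]
        if q_gap and not t_gap:
            seq = read[q_blocks[i][1] : q_blocks[i + 1][0]]
            out.append(("INS", ref_offset + t_blocks[i][1], q_gap, seq))
        elif t_gap and not q_gap:
            out.append(("DEL", ref_offset + t_blocks[i][1], t_gap, ""))
    return out


def mutate(ref, rng, n_edits):
    """Apply sparse random edits; return (read, true CIGAR, edit list)."""
    L = len(ref)
    positions = np.sort(rng.choice(np.arange(10, L - 10), size=n_edits, replace=False))
    positions = [int(p) for p in positions if all(abs(int(p) - q) >= 12 for q in positions if q < p)]
    edits = []
    for p in positions:
        kind = str(rng.choice(["SNV", "INS", "DEL"]))
        size = 1 if kind == "SNV" else int(rng.integers(1, 5))
        if kind == "INS":
            seq = "".join(rng.choice(list("ACGT"), size=size))
            edits.append((p, kind, size, seq))
        elif kind == "SNV":
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref[p]]
            edits.append((p, kind, 1, alt))
        else:
            edits.append((p, kind, size, ""))
    # build read + CIGAR
    read = []
    cigar = []
    cur = 0

    def add_m(n):
        if n:
            if cigar and cigar[-1][0] == "M":
                cigar[-1] = ("M", cigar[-1][1] + n)
            else:
                cigar.append(("M", n))

    for p, kind, size, seq in edits:
        add_m(p - cur)
        read.append(ref[cur:p])
        if kind == "SNV":
            read.append(seq)
            add_m(1)
            cur = p + 1
        elif kind == "INS":
            read.append(seq)
            cigar.append(("I", size))
            cur = p
        else:
            cigar.append(("D", size))
            cur = p + size
    add_m(L - cur)
    read.append(ref[cur:])
    return "".join(read), cigar, edits


class TestOracleEquivalence:
    def test_cigar_md_extraction_matches_alignment_diff(self, rng):
        """On short read/reference pairs, CIGAR/MD-derived variants equal an
        independent global-alignment diff."""
        genome_seq = "".join(rng.choice(list("ACGT"), size=5000))
        genome = GenomeSequences(c1=genome_seq)
        for trial in range(100):
            start = int(rng.integers(0, 4700))
            L = int(rng.integers(80, 201))
            ref_window = genome_seq[start : start + L]
            read, cigar, edits = mutate(ref_window, rng, n_edits=int(rng.integers(0, 4)))
            md = build_md(cigar, read, genome_seq, start)
            record = rec(cigar, read, md=md, ref_start=start)
            ours = vp.extract_read_variants([record])
            oracle = brute_force_diff(ref_window, read, start)

            def norm(items):
                out = set()
                for vtype, pos, size, alt in items:
                    if vtype == "SNV":
                        out.add((vtype, pos, size, alt))
                    else:
                        p, a = vp.left_align_indel(vtype, genome_seq, pos, size, alt)
                        out.add((vtype, p, size, a if vtype == "INS" else ""))
                return out

            got = norm([(e.vtype, e.ref_pos, e.size, e.alt) for e in ours])
            want = norm(oracle)
            assert got == want, f"trial {trial}"


class TestAggregation:
    def make_genome(self):
        return GenomeSequences(c1="ACGTT" * 60)

    def test_majority_support_called(self):
        genome = self.make_genome()
        track = DepthTrack({"c1": np.full(300, 4, dtype=np.int32)})
        events = [
            vp.ReadVariant("INS", "c1", 105, 2, "", "TT", f"r{i}", 0.5) for i in range(3)
        ]
        calls = vp.aggregate_sites(events, track, genome)
        assert len(calls) == 1
        assert calls[0].called and len(calls[0].support) == 3 and calls[0].depth == 4

    def test_minority_support_retained_but_not_called(self):
        genome = self.make_genome()
        track = DepthTrack({"c1": np.full(300, 3, dtype=np.int32)})
        events = [vp.ReadVariant("INS", "c1", 105, 2, "", "TT", "r1", 0.5)]
        calls = vp.aggregate_sites(events, track, genome)
        assert len(calls) == 1 and not calls[0].called

    def test_homopolymer_placements_merge_after_left_alignment(self):
        # reference ...AAAAAA... ; the same 2 bp A-insertion reported at two
        # breakpoints is one variant
        genome = GenomeSequences(c1="CCCC" + "A" * 8 + "CCCC")
        track = DepthTrack({"c1": np.full(16, 2, dtype=np.int32)})
        events = [
            vp.ReadVariant("INS", "c1", 5, 2, "", "AA", "r1", 0.5),
            vp.ReadVariant("INS", "c1", 6, 2, "", "AA", "r2", 0.5),
        ]
        calls = vp.aggregate_sites(events, track, genome)
        assert len(calls) == 1 and len(calls[0].support) == 2
        # brute-force oracle: the merged breakpoint is the leftmost placement
        # producing the same mutated sequence
        ref = genome["c1"]
        target = ref[:5] + "AA" + ref[5:]
        equivalent = [
            p for p in range(len(ref) + 1) if ref[:p] + "AA" + ref[p:] == target
        ]
        assert calls[0].ref_pos == min(equivalent)

    def test_out_of_bounds_event_raises(self):
        genome = self.make_genome()
        track = DepthTrack({"c1": np.full(300, 2, dtype=np.int32)})
        events = [vp.ReadVariant("DEL", "c1", 299, 5, "", "", "r1", 0.5)]
        with pytest.raises(ValueError, match="beyond"):
            vp.aggregate_sites(events, track, genome)


class TestErrorSummary:
    def test_ratio_arithmetic(self):
        records = [rec([("M", 10000)], "A" * 10000, md="10000")]
        events = [vp.ReadVariant("SNV", "c1", 150, 1, "A", "G", "r1", 0.5)]
        s = vp.error_summary(events, records)
        assert s.ratio("SNV") == pytest.approx(1e-4)
        assert 100 * s.ratio("SNV") == pytest.approx(0.01)  # percent

    def test_window_assignment(self):
        records = [rec([("M", 10000)], "A" * 10000, md="10000")]
        events = [vp.ReadVariant("SNV", "c1", 150, 1, "A", "G", "r1", 4950 / 9999)]
        s = vp.error_summary(events, records)
        assert s.windows.iloc[49]["SNV"] == 1

    def test_size_classes_split_at_nine(self):
        records = [rec([("M", 1000)], "A" * 1000, md="1000")]
        events = [
            vp.ReadVariant("DEL", "c1", 10, 8, "", "", "r1", 0.2),
            vp.ReadVariant("DEL", "c1", 50, 9, "", "", "r1", 0.4),
        ]
        s = vp.error_summary(events, records)
        sc = s.size_classes.set_index(["type", "size_class"])["events"]
        assert sc[("DEL", "short")] == 1 and sc[("DEL", "long")] == 1
        assert s.event_bases["DEL"] == 17

    def test_zero_aligned_bases_raises(self):
        with pytest.raises(ValueError):
            vp.error_summary([], [])


class TestSimulationProperties:
    def test_rates_recovered_from_alignments(self, error_sim):
        """Configured per-base rates recovered from the SAM within 3 SE."""
        events = vp.extract_read_variants(error_sim.records)
        summary = vp.error_summary(events, error_sim.records)
        cfg = error_sim.config.errors
        n = summary.aligned_bases
        for vtype, rate in [("SNV", cfg.snv_rate), ("INS", cfg.ins_rate), ("DEL", cfg.del_rate)]:
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(summary.ratio(vtype) - rate) <= 3 * se, vtype

    def test_end_windows_enriched(self, error_sim):
        events = vp.extract_read_variants(error_sim.records)
        summary = vp.error_summary(events, error_sim.records)
        total = summary.windows.to_numpy().sum(axis=1)
        outer = np.r_[total[:5], total[-5:]].mean()
        inner = total[5:-5].mean()
        assert outer > inner

    def test_false_deletions_concentrate_in_repeats(self):
        from longread_audit import synthetic_data as sd

        bundle = sd.run_simulation(sd.deletion_artifact_scenario(seed=21))
        events = vp.extract_read_variants(bundle.records)
        dels = [e for e in events if e.vtype == "DEL"]
        repeats = bundle.reference.repeats
        glen = bundle.reference.genome.total_length
        repeat_frac = sum(r.length for r in repeats) / glen
        in_repeat = sum(
            any(r.start <= e.ref_pos < r.end and r.chrom == e.chrom for r in repeats)
            for e in dels
        )
        assert in_repeat / len(dels) > repeat_frac
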