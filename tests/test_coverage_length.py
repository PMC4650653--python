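"""Depth tracks, gaps, N50/median, strata and accumulative coverage curves."""

import numpy as np
import pytest

from longread_audit import coverage_length as cl
from longread_audit.io_formats import AlignmentRecord, GenomeSequences


def rec(start, length, chrom="c1", read_id="r", seq_len=None):
    n = seq_len or length
    return AlignmentRecord(
        read_id=read_id,
        chrom=chrom,
        ref_start=start,
        strand="+",
        cigar=[("M", length)] + ([("S", n - length)] if n > length else []),
        read_sequence="A" * n,
    )


class TestDepthAndGaps:
    def test_overlap_depth_and_trailing_gap(self):
        genome = GenomeSequences(c1="A" * 20)
        track = cl.depth_track([rec(0, 10), rec(5, 10)], genome)
        assert (track.depth["c1"][5:10] == 2).all()
        assert (track.depth["c1"][:5] == 1).all()
        gaps = cl.extract_gaps(track)
        assert [(g.start, g.end) for g in gaps] == [(15, 20)]

    def test_no_alignments_one_full_gap_per_chromosome(self):
        genome = GenomeSequences(c1="A" * 30, c2="A" * 10)
        gaps = cl.extract_gaps(cl.depth_track([], genome))
        assert {(g.chrom, g.start, g.end) for g in gaps} == {("c1", 0, 30), ("c2", 0, 10)}

    def test_deletions_do_not_add_depth(self):
        genome = GenomeSequences(c1="A" * 20)
        r = AlignmentRecord("r", "c1", 0, "+", [("M", 5), ("D", 5), ("M", 5)], "A" * 10)
        track = cl.depth_track([r], genome)
        assert (track.depth["c1"][5:10] == 0).all()

    def test_blocked_cluster_leaves_gap(self, tandem_sim):
        from longread_audit.synthetic_data import blocked_clusters

        track = cl.depth_track(tandem_sim.records, tandem_sim.reference.genome)
        gaps = cl.extract_gaps(track)
        (cluster,) = blocked_clusters(tandem_sim.reference, 500)
        assert any(g.start <= cluster.start and g.end >= cluster.end for g in gaps)


class TestLengthStats:
    def test_n50_by_definition(self):
        assert cl.n50([2, 2, 2, 3, 3]) == 3

    def test_uniform_lengths(self):
        median, v, strata = cl.length_stats([4000] * 10)
        assert v == 4000 and median == 4000

    def test_n50_matches_brute_force(self, rng):
        lengths = rng.integers(1500, 20000, size=1000)
        total = lengths.sum()
        desc = np.sort(lengths)[::-1]
        acc = 0
        expect = None
        for x in desc:
            acc += x
            if acc >= total / 2:
                expect = int(x)
                break
        assert cl.n50(lengths) == expect

    def test_strata_shape_and_conservation(self, rng):
        lengths = rng.integers(1500, 30000, size=500)
        _, _, strata = cl.length_stats(lengths)
        assert len(strata.counts) == 140  # 139 closed bins + open bin
        assert strata.counts.sum() == 500
        assert strata.yields.sum() == lengths.sum()

    def test_empty_read_set_raises(self):
        with pytest.raises(ValueError):
            cl.length_stats([])

    def test_n50_at_least_median_in_bimodal_regime(self, error_sim):
        lengths = [len(r.sequence) for r in error_sim.reads.reads]
        median, v, _ = cl.length_stats(lengths)
        assert v >= median


class TestAccumulativeCurves:
    def make(self):
        genome = GenomeSequences(c1="A" * 10000)
        # two read populations: short 2 kb reads on the left half, long 8 kb
        # reads on the right half
        records = [rec(i * 1000, 2000, read_id=f"s{i}") for i in range(4)]
        records += [rec(5000 + i * 500, 4000, read_id=f"l{i}", seq_len=8000) for i in range(2)]
        return genome, records

    def test_boundary_values(self):
        genome, records = self.make()
        masks = cl.target_masks(genome)
        curves = cl.accumulative_coverage(records, genome, masks)
        first = curves.iloc[0]
        assert first["frac_shorter_genome"] == 0.0  # L at the minimum length
        last = curves.iloc[-1]
        assert last["frac_longer_genome"] == 0.0
        all_cov = cl.depth_track(records, genome).depth["c1"] > 0
        assert last["frac_shorter_genome"] == pytest.approx(all_cov.mean())

    def test_monotonicity(self):
        genome, records = self.make()
        curves = cl.accumulative_coverage(records, genome, cl.target_masks(genome))
        fs = curves["frac_shorter_genome"].to_numpy()
        fl = curves["frac_longer_genome"].to_numpy()
        assert (np.diff(fs) >= -1e-12).all()
        assert (np.diff(fl) <= 1e-12).all()

    def test_subset_union_equals_full_coverage(self):
        genome, records = self.make()
        for L in (3000, 5000):
            short = [r for r in records if len(r.read_sequence) < L]
            long = [r for r in records if len(r.read_sequence) >= L]
            full = cl.depth_track(records, genome).depth["c1"] > 0
            union = (cl.depth_track(short, genome).depth["c1"] > 0) | (
                cl.depth_track(long, genome).depth["c1"] > 0
            )
            assert (union == full).all()

    def test_crossing_point_matches_brute_force(self):
        genome, records = self.make()
        masks = cl.target_masks(genome)
        curves = cl.accumulative_coverage(records, genome, masks)
        ip = cl.intersection_point(curves, "genome")
        # brute force over the same grid
        best = None
        for L in curves["L"]:
            short = [r for r in records if len(r.read_sequence) < L]
            long = [r for r in records if len(r.read_sequence) >= L]
            fs = (cl.depth_track(short, genome).depth["c1"] > 0).mean()
            fl = (cl.depth_track(long, genome).depth["c1"] > 0).mean()
            d = abs(fs - fl)
            if best is None or d < best[1] - 1e-12:
                best = (int(L), d)
        assert ip.L == best[0]

    def test_no_crossing_flag(self):
        # every read is longer than the whole grid: frac_shorter stays 0 and
        # the curves never meet
        genome = GenomeSequences(c1="A" * 50000)
        records = [rec(0, 20000, read_id="a"), rec(20000, 20000, read_id="b")]
        curves = cl.accumulative_coverage(records, genome, cl.target_masks(genome))
        ip = cl.intersection_point(curves, "genome")
        assert not ip.crossed
        assert ip.L == 1500  # ties resolve to the smallest grid point


class TestChromosomeProfile:
    def test_single_read_hits_its_bins_only(self):
        genome = GenomeSequences(c1="A" * 10000)
        records = [rec(1000, 2000)]
        prof = cl.per_chromosome_profile(records, genome, n_bins=10)
        by_bin = prof.set_index("bin")["covered_frac"]
        assert by_bin[1] == 1.0 and by_bin[2] == 1.0
        assert set(prof["bin"]) == set(range(10))
        assert by_bin[5] == 0.0

    def test_uniform_simulation_has_low_row_variance(self, null_sim):
        prof = cl.per_chromosome_profile(null_sim.records, null_sim.reference.genome, n_bins=20)
        total = prof.groupby("bin")["covered_frac"].sum()
        # coverage by all strata together is near-complete in every bin
        assert (total > 0.5).all()
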