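"""Read-length statistics and accumulative shorter/longer coverage curves.

Shows the N50/median of a bimodal read set, the 100 bp length strata, and
the split length at which reads shorter and longer than L cover the genome
equally well.
"""

from longread_audit import coverage_length as cl
from longread_audit import synthetic_data as sd

bundle = sd.run_simulation(sd.error_profile_scenario(seed=1))
lengths = [len(r.sequence) for r in bundle.reads.reads]
median, n50, strata = cl.length_stats(lengths)
print(f"reads: {len(lengths)}  median: {median:.0f} bp  N50: {n50} bp")
busiest = strata.frame().sort_values("count", ascending=False).head(3)
print("busiest 100 bp strata:")
print(busiest.to_string(index=False))

genome = bundle.reference.genome
masks = cl.target_masks(genome, bundle.reference.genes)  # this genome has no repeats
curves = cl.accumulative_coverage(bundle.records, genome, masks)
ip = cl.intersection_point(curves, "genome")
print(f"shorter/longer curves meet at L = {ip.L} bp "
      f"(both cover {100 * ip.frac_shorter:.1f}% of the genome)")
# Reads shorter than L and reads ≥ L recover the same genome fraction at
# the intersection point; with a heavy ~10 kb mode the point sits high.
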