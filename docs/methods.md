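# Methods

This note documents the models implemented in `longread_audit`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Coordinate conventions

Internally every interval is 0-based, half-open. SAM POS (1-based), GFF3
(1-based closed) and VCF (1-based, anchor base before the event) are
converted exactly once, inside `io_formats`. An insertion breakpoint *b*
means "between reference bases *b−1* and *b*"; its VCF POS is *b* with the
reference base at *b−1* as anchor.

## Variant extraction and calling

Per-read events come from two sources: CIGAR I/D ops (insertions and
deletions in the read relative to the reference) and MD-tag mismatch
tokens (SNVs), walked in lockstep so every event carries both reference
and read coordinates. `N` read bases are never counted as SNVs. Soft clips
are not variants; they feed insertion recovery.

Sites are aggregated across reads after left-aligning indels against the
reference (an insertion shifts left while the base before the breakpoint
equals its last inserted base, the standard VCF normalization). Without
this step, homopolymer placements fragment the read support across
adjacent breakpoints. A site is *called* when depth ≥ 1, support ≥ 1 and
support/depth > 0.5. The 0.5 support-fraction rule is our emulation of a
probabilistic caller configured with minimum coverage 1, minimum count 1
and probability > 0.5 at ploidy 2; it is a faithful rendering of the
behaviour, not a reconstruction of the original tool's model. The
practical effect is identical on this data: genuine donor variants are
carried by essentially every overlapping read (support ≈ depth), while
sequencing errors appear in one read of ~24 and are filtered.

Error ratios are reported with aligned read bases (M/=/X) as the
denominator, and with two numerators: event counts and event bases (an
8 bp deletion contributes 8). The event-base ratio is what reproduces the
deletion ≫ SNV asymmetry seen in real synthetic long-read data; both are
written to `error_summary.tsv`. Indels split into short/long classes at
9 bp, the conventional cutoff separating abundant end-of-read consensus
errors from structurally meaningful events. The positional profile bins
each event into one of 100 equal windows of its read's normalized length,
in sequencing orientation (reverse-strand alignments are flipped back).

## Insertion recovery

Four routes, in decreasing order of directness:

1. **within_read** — called insertion sites ≥ 9 bp promoted directly.
2. **self_mapped** — for each soft-clipped unaligned end, the
   `relax_min_anchor` (200 bp) of reference sequence immediately adjacent
   to the breakpoint is located inside the clip by bit-parallel infix
   alignment (edlib). A hit at ≥ 90% identity is the second anchor; the
   clip bases on the insertion side of the hit are the recovered sequence.
   The 200 bp / 90% pair is deliberately permissive relative to primary
   mapping stringency (the route exists precisely because the primary
   aligner refused the second arm); both are configurable.
3. **cross_mapped** — a right-side clip and a left-side clip whose
   breakpoints face each other within 50 bp are overlap-aligned (suffix of
   one vs prefix of the other, free end gaps); an overlap ≥ 30 bp at ≥ 95%
   identity merges them into one gap-free sequence.
4. **close_breakpoint** — facing pairs that fail the overlap test are
   reported as armA + gap + armB with the gap of unknown length (rendered
   as 100 N's in VCF with `GAPPED=1`; size is a lower bound).

Pairing is greedy best-overlap-first; each end is used at most once, and
the two ends of one read are never paired with each other. Calls found by
several routes are merged when breakpoints lie within 10 bp and sequences
agree at ≥ 95% identity; the category of highest precedence (the order
above) wins and supports are unioned. Merging is idempotent. Context is
assigned by breakpoint overlap: coding exon, else intron (inside a gene
span), else intergenic.

All gap-free calls are normalized to their leftmost equivalent placement
before merging, regardless of route: within-read calls inherit it from
site aggregation, and clip-derived calls are shifted from the raw
primary-alignment boundary. An insertion whose edge bases match the
adjacent reference admits several equivalent (breakpoint, sequence)
renderings; the canonical left-aligned form makes duplicates merge exactly
and makes "breakpoint exact" well defined — truth comparisons are done in
the same canonical coordinates.

## Coverage, length strata and gaps

Depth counts reference bases consumed by M/=/X ops of primary alignments
(deletions contribute nothing); supplementary records are included only
where stated. Gaps are maximal zero-depth runs. Read lengths are
stratified from 1500 bp in 100 bp steps into 139 closed bins plus one open
bin above 15.4 kb. N50 is the smallest read in the minimal set of longest
reads holding at least half the total yield. Accumulative curves use
"shorter" = length < L and "longer" = length ≥ L (ties to longer); covered
fractions are exact interval unions, computed incrementally in one sweep
per direction. The intersection point is the smallest grid L minimizing
|frac_shorter − frac_longer|, with a flag when the curves never actually
cross.

## Repeat analysis

Recovery of a repeat instance or gene requires its full annotated span
covered at least once. Subsampling to 3/6/12/24× is by whole reads,
uniform without replacement, drawn once per seed so the subsets are
nested; a requested level within 15% above the realized depth means "the
full read set" (the top level of a nominally 24× run that realized 23×),
anything higher is an error.

Tandem clusters are found by self-comparison at each candidate period
p ≤ 20: positions where s[i] = s[i−p] form runs, and a run of r ≥ p
matches covering r+p bases is a cluster of period p; smaller periods win
where detections overlap. Clusters longer than 500 bp are flagged as
pre-assembly blockers. Detection is exact-match; diverged clusters are
expected to come from the annotation BED instead.

Collapsed-repeat copy number is regional mean depth divided by
genome-average depth, where the genome average excludes the queried region
(avoiding self-dilution) and zero-depth gap bases; the naive all-bases
version is reported alongside. This stage reads alignments with
supplementary records retained: reads from the donor's tandem array wrap
around the single reference copy, and the wraps beyond the primary
placement carry roughly half of the regional evidence.

## Validation

One contig per insertion call: 2,500 bp left flank + insertion + 2,500 bp
right flank (flanks truncated and flagged near chromosome ends; gapped
calls get one contig per arm and can only ever be partially confirmed).
Confirmation requires depth ≥ 10 at *every base* of both junction windows
— per-base minimum, the conservative reading of "10× across both
boundaries" — plus full coverage of the insertion body. The junction
window is one (median) short-read length per side. Exonic support inside
the insertion uses maximal runs of depth ≥ 2; full/partial/none according
to whether those runs cover the whole insertion.

## Assembly assessment

Input is a block-level alignment table (contig interval ↔ reference
interval, strand, identity), with a PAF converter; running an assembler or
whole-genome aligner is out of scope — the metric definitions are the
content. For each adjacent block pair of a contig: different chromosomes →
translocation; opposite strands → inversion; same chromosome and strand
with |ref_step − contig_step| ≥ 1000 bp → relocation (the discontinuity is
measured relative to the contig-coordinate step, strand-aware). NA50/LA50
re-rank contig pieces after cutting at misassembly junctions, against the
total assembly size, so NA50 ≤ N50 holds structurally. Duplication ratio
is total aligned contig bases over covered reference bases; it is exactly
1 when blocks tile the covered reference once.

## The synthetic study generator

The generator reproduces the *structure* of a synthetic long-read study,
not any particular organism:

* **Reference** — random unique background; identical interspersed copies
  per repeat class; tandem clusters of one short unit (e.g. TGATA) at
  controlled lengths both below and above the 500 bp blocker size; exactly
  one copy of a ~7.2 kb collapsed-repeat unit; gene models (3–6 exons of
  100–300 bp) in unique sequence.
* **Donor** — the reference plus SNVs, insertions of 9–2000 bp
  (log-uniform sizes; a configurable fraction placed inside coding exons)
  and deletions; the collapsed unit expanded to k tandem copies. Structural
  events keep ≥ 3 kb from chromosome ends and ≥ 15 kb from each other —
  chosen to exceed the maximum read length so one read spans at most one
  event, which keeps the aligner emulator's single-split model exact.
* **Reads** — lengths from a two-component normal mixture (means 1.8 kb /
  9.8 kb, SDs 0.8 / 1.2 kb, weights 0.35 / 0.65) truncated at 1500 bp; the
  mixture reproduces the bimodal count profile qualitatively, with the
  peak locations the constrained quantities. The read count is
  depth × genome / E[length] with the truncated-mixture mean computed
  analytically. Fragment starts are uniform and may run off chromosome
  ends (ends are fragment boundaries in a real library), so chromosome
  edges are not spurious gaps. Per-base error rates (defaults 0.01% SNV /
  0.02% insertion / 0.10% deletion) are genome-wide means; the outer 5% of
  each read carries 5× the interior rate, with the profile normalized to
  mean 1 so the configured rate is what a whole-read estimator should
  recover. Deletion errors can be biased into repeat intervals by a
  configurable multiplier, mirroring the observation that read deletions
  concentrate in repetitive sequence (and are mostly artifacts). Quality
  strings encode the two-level positional error model.
* **Pre-assembly blocking** — a read overlapping a tandem cluster longer
  than 500 bp is truncated to its largest cluster-free piece and dropped
  entirely if nothing ≥ 1500 bp remains. Blocking therefore acts at read
  generation: the read over the cluster never exists, which is what
  produces the zero-coverage gap over the cluster. The hard threshold is a
  simplification — real pre-assembly failure is probabilistic in cluster
  length — and the failure probability function is not modeled.
* **Aligner emulator** — reads are projected onto the reference through
  the donor coordinate map, not aligned. An injected insertion of size s
  with reference-anchored flanks ≥ 1000 bp appears as a CIGAR I op when
  s ≤ 100 bp; otherwise the longer flank is the primary alignment and the
  rest of the read becomes a soft clip (the "unaligned end"). Read-level
  error indels are always CIGAR-encoded regardless of position — a real
  aligner does not clip a read at every 1 bp end-window indel, and the
  positional error profile depends on those events surviving. Reads over
  the collapsed array wrap modularly onto the single reference copy; the
  longest wrap is the primary record and the other wraps are emitted as
  supplementary records. MD tags are computed against the reference, so
  donor SNVs and read SNV errors surface as mismatches without special
  handling. The minimum primary anchor (1000 bp) mirrors a long-seed
  primary mapping policy.

**What passing tests do and do not show.** The generator's reads have
position-independent, independent errors within each rate tier, exact
truth-driven placements, no chimeras, no GC or mappability bias, and
repeats that are internally identical. Passing the recovery and
rate-recovery tests therefore demonstrates the *machinery* — coordinate
bookkeeping, detection rules, merging, thresholds — under controlled
conditions; it does not certify performance on real alignments, where
mapping ambiguity in diverged repeats and alignment-boundary noise are the
dominant error sources. The pipeline accepts real SAM precisely so those
conditions can be brought in from outside.

## Problem sizes and determinism

The shipped scenarios use a 2 Mb single-chromosome genome at 24× for the
error regime (≈48 Mb of read bases), 2 Mb at 12× with 50 insertions for
recovery, and 0.3–0.6 Mb genomes for the tandem and collapsed scenarios —
sizes at which every property under test is comfortably resolved (3
binomial SEs at 48 Mb separate rates 4% apart) while a full suite run
stays in the tens of seconds. All randomness flows from
`numpy.random.SeedSequence` spawns of a single seed; identical configs
produce byte-identical FASTA/FASTQ/SAM/TSV outputs.

## Known limitations

* The support-fraction calling rule is an emulation of a proprietary
  probabilistic caller's settings; "complex variation" (mixed adjacent
  events) is not emitted as a category — primitive parts are reported.
* Cross-mapped/close-breakpoint pairing is greedy; a global matching could
  differ when many breakpoints crowd within the 50 bp pairing distance,
  which the generator's event spacing deliberately avoids.
* Tandem-cluster detection is exact-match with unit length ≤ 20 bp.
* The relocation rule implements the 1 kb-discontinuity definition
  directly; other assembly-QC tools differ subtly in how they measure the
  discontinuity, so counts are comparable only at the definition level.
* BAM/CRAM are not parsed; plain SAM suffices at these scales (convert
  externally where needed).
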