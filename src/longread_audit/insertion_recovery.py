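"""Recovery of sequences missing from the reference genome.

A read carrying sequence absent from the reference either shows a CIGAR
insertion (when the aligner can place both flanks) or an *unaligned end* —
a soft-clipped arm at the edge of its primary alignment.  Four categories
of missing sequence are recovered from these signals:

* **within_read** — a called CIGAR insertion ≥ the long-indel cutoff;
* **self_mapped** — one read's clip realigned at relaxed stringency: a
  distal portion of the clip anchors back onto the reference next to the
  breakpoint, and the unanchored middle is the insertion;
* **cross_mapped** — the facing clips of two independent reads overlap and
  are merged into one gap-free sequence;
* **close_breakpoint** — facing clips that do not overlap; the insertion is
  reported with a single unknown-length gap between the two arms.

Duplicates found by several routes are merged (category precedence
within_read > self_mapped > cross_mapped > close_breakpoint) and annotated
with their genomic context (coding exon / intron / intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align
from intervaltree import IntervalTree

from .io_formats import GAP_MARKER, AlignmentRecord, GeneModel, GenomeSequences, cigar_walk, SoftClipEvent
from .variant_profile import LONG_INDEL_CUTOFF, VariantCall


@dataclass
class RecoveryParams:
    min_insertion_size: int = LONG_INDEL_CUTOFF
    min_clip: int = 30  # shorter clips are alignment noise
    relax_min_anchor: int = 200  # second-arm anchor, relaxed vs primary mapping
    relax_min_identity: float = 0.90
    self_map_slack: int = 200  # extra reference window beyond the clip length
    pair_max_distance: int = 50  # facing breakpoints at most this far apart
    min_overlap: int = 30
    min_overlap_identity: float = 0.95
    merge_tolerance: int = 10
    merge_identity: float = 0.95


@dataclass(frozen=True)
class UnalignedEnd:
    read_id: str
    side: str  # clip on the "left" or "right" of the primary alignment
    chrom: str
    breakpoint: int  # reference boundary of the primary alignment on that side
    sequence: str  # clipped bases, reference orientation
    primary_span: tuple[int, int]


@dataclass
class InsertionCall:
    category: str  # within_read | self_mapped | cross_mapped | close_breakpoint
    chrom: str
    breakpoint: int
    sequence: str  # contains one GAP_MARKER for close_breakpoint calls
    size: int  # bp; lower bound when gapped
    support: list[str]
    context: str = ""
    validation: str = "unconfirmed"

    @property
    def gapped(self) -> bool:
        return GAP_MARKER in self.sequence


CATEGORY_RANK = {"within_read": 0, "self_mapped": 1, "cross_mapped": 2, "close_breakpoint": 3}


# ---------------------------------------------------------------------------
# unaligned ends
# ---------------------------------------------------------------------------


def collect_unaligned_ends(
    records: list[AlignmentRecord], params: RecoveryParams | None = None
) -> list[UnalignedEnd]:
    """Soft-clipped arms of primary alignments, indexed by breakpoint."""
    params = params or RecoveryParams()
    ends = []
    for rec in records:
        if not rec.is_primary:
            continue
        for ev in cigar_walk(rec):
            if isinstance(ev, SoftClipEvent) and ev.length >= params.min_clip:
                if ev.side == "left":
                    bp = rec.ref_start
                else:
                    bp = rec.ref_end
                ends.append(
                    UnalignedEnd(
                        rec.read_id,
                        ev.side,
                        rec.chrom,
                        bp,
                        ev.sequence,
                        (rec.ref_start, rec.ref_end),
                    )
                )
    return ends


# ---------------------------------------------------------------------------
# pairwise alignment helpers
# ---------------------------------------------------------------------------


def _aligner(free_query_left: bool, free_query_right: bool, free_target_left: bool, free_target_right: bool) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    if free_query_left:  # target overhang at left costs nothing
        a.open_left_deletion_score = 0
        a.extend_left_deletion_score = 0
    if free_query_right:
        a.open_right_deletion_score = 0
        a.extend_right_deletion_score = 0
    if free_target_left:  # query overhang at left costs nothing
        a.open_left_insertion_score = 0
        a.extend_left_insertion_score = 0
    if free_target_right:
        a.open_right_insertion_score = 0
        a.extend_right_insertion_score = 0
    return a


def _best_alignment(aligner: Align.PairwiseAligner, target: str, query: str):
    """Best alignment with (target_interval, query_interval, identity)."""
    if not target or not query:
        return None
    aln = aligner.align(target, query)
    if len(aln) == 0:
        return None
    best = aln[0]
    t_blocks, q_blocks = best.aligned
    if len(t_blocks) == 0:
        return None
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    counts = best.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    return t_span, q_span, identity


# ---------------------------------------------------------------------------
# the four recovery routes
# ---------------------------------------------------------------------------


def find_within_read(
    calls: list[VariantCall], params: RecoveryParams | None = None
) -> list[InsertionCall]:
    """Promote called CIGAR insertions ≥ the size cutoff."""
    params = params or RecoveryParams()
    out = []
    for c in calls:
        if c.vtype == "INS" and c.size >= params.min_insertion_size:
            out.append(
                InsertionCall(
                    "within_read", c.chrom, c.ref_pos, c.alt, c.size, list(c.support)
                )
            )
    return out


def find_self_mapped(
    ends: list[UnalignedEnd],
    genome: GenomeSequences,
    params: RecoveryParams | None = None,
) -> tuple[list[InsertionCall], list[UnalignedEnd]]:
    """Realign each clip's distal portion to the reference next to its
    breakpoint (the relaxed second-arm mapping).

    For a right-side clip the insertion is the clip's prefix and the anchor
    its suffix, matching the reference window that starts at the breakpoint;
    left-side clips mirror this.  Ends without a qualifying second anchor are
    returned for cross-mapped / close-breakpoint pairing.
    """
    params = params or RecoveryParams()
    calls: list[InsertionCall] = []
    leftovers: list[UnalignedEnd] = []
    probe_len = params.relax_min_anchor
    for end in ends:
        chrom_seq = genome[end.chrom]
        clip = end.sequence
        result = None
        # The second-arm anchor is searched for by locating a reference probe
        # (the relax_min_anchor bases adjacent to the breakpoint) inside the
        # clip; the clip bases on the insertion side of the hit are the
        # recovered sequence.  edlib's infix mode keeps this linear-time.
        if end.side == "right":
            probe = chrom_seq[end.breakpoint : end.breakpoint + probe_len]
            if len(probe) == probe_len and len(clip) >= probe_len:
                res = edlib.align(probe, clip, mode="HW", task="locations")
                if res["editDistance"] >= 0:
                    ident = 1.0 - res["editDistance"] / probe_len
                    if ident >= params.relax_min_identity:
                        k = res["locations"][0][0]
                        result = clip[:k]
        else:
            probe = chrom_seq[max(0, end.breakpoint - probe_len) : end.breakpoint]
            if len(probe) == probe_len and len(clip) >= probe_len:
                res = edlib.align(probe, clip, mode="HW", task="locations")
                if res["editDistance"] >= 0:
                    ident = 1.0 - res["editDistance"] / probe_len
                    if ident >= params.relax_min_identity:
                        k = res["locations"][-1][1] + 1
                        result = clip[k:]
        if result is not None and len(result) >= params.min_insertion_size:
            calls.append(
                InsertionCall(
                    "self_mapped",
                    end.chrom,
                    end.breakpoint,
                    result,
                    len(result),
                    [end.read_id],
                )
            )
        else:
            leftovers.append(end)
    return calls, leftovers


def pair_ends(
    ends: list[UnalignedEnd], params: RecoveryParams | None = None
) -> tuple[list[InsertionCall], list[InsertionCall]]:
    """Pair facing clips into cross-mapped / close-breakpoint calls.

    A right-side end (clip downstream of its primary) is paired with a
    left-side end whose breakpoint lies within ``pair_max_distance``.  If
    the right end's clip suffix overlaps the left end's clip prefix by at
    least ``min_overlap`` at ``min_overlap_identity``, the merged sequence
    is one cross-mapped call; otherwise the pair yields a close-breakpoint
    call with a single unknown-length gap.  Greedy best-overlap-first; each
    end is used at most once.  Two ends of the same read are never paired
    together.
    """
    params = params or RecoveryParams()
    rights = [e for e in ends if e.side == "right"]
    lefts = [e for e in ends if e.side == "left"]
    candidates = []
    # overlap mode: A-prefix and B-suffix overhangs are free, so the best
    # alignment is A's suffix against B's prefix
    overlap_aligner = _aligner(False, True, True, False)
    cap = 2500  # the overlap sits at the facing ends; distal bases suffice
    for i, a in enumerate(rights):
        for j, b in enumerate(lefts):
            if a.read_id == b.read_id:
                continue
            if a.chrom != b.chrom or abs(a.breakpoint - b.breakpoint) > params.pair_max_distance:
                continue
            a_seq = a.sequence[-cap:]
            b_seq = b.sequence[:cap]
            best = _best_alignment(overlap_aligner, b_seq, a_seq)
            overlap = 0
            ident = 0.0
            if best is not None:
                (t0, t1), (q0, q1), ident = best
                # a suffix ↔ b prefix requires the alignment to touch both
                if q1 == len(a_seq) and t0 == 0:
                    overlap = min(t1 - t0, q1 - q0)
            candidates.append((overlap, ident, i, j))
    candidates.sort(key=lambda c: (-c[0], c[2], c[3]))
    used_r: set[int] = set()
    used_l: set[int] = set()
    cross: list[InsertionCall] = []
    close: list[InsertionCall] = []
    for overlap, ident, i, j in candidates:
        if i in used_r or j in used_l:
            continue
        used_r.add(i)
        used_l.add(j)
        a, b = rights[i], lefts[j]
        bp = min(a.breakpoint, b.breakpoint)
        if overlap >= params.min_overlap and ident >= params.min_overlap_identity:
            merged = a.sequence + b.sequence[overlap:]
            cross.append(
                InsertionCall(
                    "cross_mapped", a.chrom, bp, merged, len(merged), sorted({a.read_id, b.read_id})
                )
            )
        else:
            gapped = a.sequence + GAP_MARKER + b.sequence
            close.append(
                InsertionCall(
                    "close_breakpoint",
                    a.chrom,
                    bp,
                    gapped,
                    len(a.sequence) + len(b.sequence),
                    sorted({a.read_id, b.read_id}),
                )
            )
    return cross, close


def find_cross_mapped(ends, params=None):
    return pair_ends(ends, params)[0]


def find_close_breakpoint(ends, params=None):
    return pair_ends(ends, params)[1]


# ---------------------------------------------------------------------------
# merging and annotation
# ---------------------------------------------------------------------------


def _sequences_match(a: InsertionCall, b: InsertionCall, min_identity: float) -> bool:
    """Identity between two calls' sequences; a gapped call matches when each
    of its arms matches into the other call's sequence."""
    aligner = _aligner(True, True, True, True)  # local-ish: all end gaps free

    def ident(x: str, y: str) -> float:
        if not x or not y:
            return 0.0
        best = _best_alignment(aligner, x, y)
        if best is None:
            return 0.0
        (t0, t1), (q0, q1), identity = best
        span = min(len(x), len(y))
        cover = (q1 - q0) / span if span else 0.0
        return identity if cover >= 0.5 else identity * cover / 0.5

    if a.gapped and b.gapped:
        a1, a2 = a.sequence.split(GAP_MARKER)
        b1, b2 = b.sequence.split(GAP_MARKER)
        return ident(b1, a1) >= min_identity and ident(b2, a2) >= min_identity
    if a.gapped or b.gapped:
        g, full = (a, b) if a.gapped else (b, a)
        arm1, arm2 = g.sequence.split(GAP_MARKER)
        return ident(full.sequence, arm1) >= min_identity and ident(full.sequence, arm2) >= min_identity
    return ident(a.sequence, b.sequence) >= min_identity


def merge_calls(
    calls: list[InsertionCall], params: RecoveryParams | None = None
) -> list[InsertionCall]:
    """Collapse duplicate recoveries of the same insertion.

    Calls whose breakpoints lie within ``merge_tolerance`` and whose
    sequences agree at ``merge_identity`` become one call; the category of
    highest precedence wins, supports are unioned, and the least-gapped,
    longest sequence is kept.  Merging is idempotent.
    """
    params = params or RecoveryParams()
    ordered = sorted(
        calls, key=lambda c: (CATEGORY_RANK[c.category], c.chrom, c.breakpoint, -c.size)
    )
    merged: list[InsertionCall] = []
    for call in ordered:
        home = None
        for m in merged:
            if m.chrom != call.chrom:
                continue
            if abs(m.breakpoint - call.breakpoint) > params.merge_tolerance:
                continue
            if _sequences_match(m, call, params.merge_identity):
                home = m
                break
        if home is None:
            merged.append(
                InsertionCall(
                    call.category,
                    call.chrom,
                    call.breakpoint,
                    call.sequence,
                    call.size,
                    list(call.support),
                    call.context,
                )
            )
        else:
            home.support = sorted(set(home.support) | set(call.support))
            if home.gapped and not call.gapped:
                home.sequence = call.sequence
                home.size = call.size
    merged.sort(key=lambda c: (c.chrom, c.breakpoint))
    return merged


def annotate_context(
    calls: list[InsertionCall], genes: list[GeneModel]
) -> list[InsertionCall]:
    """Assign coding_exon / intron / intergenic by breakpoint overlap."""
    exon_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gt = gene_trees.setdefault(g.chrom, IntervalTree())
        s, e = g.span
        gt[s:e] = g.gene_id
        if g.coding:
            et = exon_trees.setdefault(g.chrom, IntervalTree())
            for xs, xe in g.exons:
                et[xs:xe] = g.gene_id
    for call in calls:
        bp = call.breakpoint
        if call.chrom in exon_trees and exon_trees[call.chrom][bp]:
            call.context = "coding_exon"
        elif call.chrom in gene_trees and gene_trees[call.chrom][bp]:
            call.context = "intron"
        else:
            call.context = "intergenic"
    return calls


def left_normalize_calls(
    calls: list[InsertionCall], genome: GenomeSequences
) -> list[InsertionCall]:
    """Shift gap-free calls to their leftmost equivalent placement.

    Within-read calls arrive left-aligned from site aggregation; clip-derived
    calls carry the raw primary-alignment boundary.  Normalizing both to the
    same canonical placement lets duplicates merge exactly.  Gapped calls
    are left untouched (their sequence is incomplete).
    """
    from .variant_profile import left_align_indel

    for c in calls:
        if c.gapped:
            continue
        c.breakpoint, c.sequence = left_align_indel(
            "INS", genome[c.chrom], c.breakpoint, c.size, c.sequence
        )
    return calls


def merge_and_annotate(
    calls: list[InsertionCall],
    genes: list[GeneModel],
    params: RecoveryParams | None = None,
) -> list[InsertionCall]:
    return annotate_context(merge_calls(calls, params), genes)


def recover_insertions(
    records: list[AlignmentRecord],
    genome: GenomeSequences,
    variant_calls: list[VariantCall],
    genes: list[GeneModel],
    params: RecoveryParams | None = None,
) -> list[InsertionCall]:
    """Full four-route recovery: within-read + clip routes, merged."""
    params = params or RecoveryParams()
    within = find_within_read(variant_calls, params)
    ends = collect_unaligned_ends(records, params)
    selfm, leftovers = find_self_mapped(ends, genome, params)
    cross, close = pair_ends(leftovers, params)
    calls = left_normalize_calls(within + selfm + cross + close, genome)
    return merge_and_annotate(calls, genes, params)
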