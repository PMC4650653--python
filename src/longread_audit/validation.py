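"""Independent confirmation of recovered insertions with short-read data.

Each insertion, flanked by 2,500 bp of reference sequence on either side,
becomes one contig of a validation reference.  Genomic short reads aligned
to those contigs confirm an insertion when every base of both junction
windows reaches 10× depth and the insertion body itself is fully covered.
RNA-seq alignments classify exonic support inside the insertion: maximal
runs with ≥ 2× coverage are exonic regions, and an insertion is fully /
partially / not expressed accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .insertion_recovery import InsertionCall
from .io_formats import GAP_MARKER, AlignmentRecord, GenomeSequences

FLANK = 2500
CONFIRM_DEPTH = 10
EXON_DEPTH = 2


@dataclass
class ValidationContig:
    name: str
    sequence: str
    junctions: tuple[int, int]  # contig coordinates of the two breakpoints
    insertion_span: tuple[int, int]
    call_index: int
    truncated: bool = False  # a flank hit a chromosome end
    arm: str = ""  # "", "left", "right" (gapped calls get per-arm contigs)


def build_validation_reference(
    calls: list[InsertionCall],
    genome: GenomeSequences,
    flank: int = FLANK,
) -> list[ValidationContig]:
    """One contig per call: left flank + insertion + right flank.

    Gap-free calls give a single contig of length ``2·flank + size``.
    Close-breakpoint (gapped) calls give two junction contigs, one per arm,
    flagged via ``arm``.  Flanks are truncated (and flagged) near
    chromosome ends.
    """
    contigs: list[ValidationContig] = []
    for idx, call in enumerate(calls):
        chrom_seq = genome[call.chrom]
        bp = call.breakpoint
        left = chrom_seq[max(0, bp - flank) : bp]
        right = chrom_seq[bp : bp + flank]
        truncated = len(left) < flank or len(right) < flank
        if not call.gapped:
            seq = left + call.sequence + right
            j1 = len(left)
            j2 = len(left) + len(call.sequence)
            contigs.append(
                ValidationContig(
                    f"ins_{idx:04d}", seq, (j1, j2), (j1, j2), idx, truncated
                )
            )
        else:
            arm_a, arm_b = call.sequence.split(GAP_MARKER)
            seq_a = left + arm_a
            contigs.append(
                ValidationContig(
                    f"ins_{idx:04d}_L",
                    seq_a,
                    (len(left), len(left)),
                    (len(left), len(seq_a)),
                    idx,
                    truncated,
                    arm="left",
                )
            )
            seq_b = arm_b + right
            contigs.append(
                ValidationContig(
                    f"ins_{idx:04d}_R",
                    seq_b,
                    (len(arm_b), len(arm_b)),
                    (0, len(arm_b)),
                    idx,
                    truncated,
                    arm="right",
                )
            )
    return contigs


def _contig_depth(contigs, records):
    depth = {c.name: np.zeros(len(c.sequence), dtype=np.int32) for c in contigs}
    names = set(depth)
    for rec in records:
        if rec.chrom not in names:
            raise ValueError(f"record aligned to unknown contig {rec.chrom!r}")
        ref = rec.ref_start
        for op, n in rec.cigar:
            if op in "M=X":
                depth[rec.chrom][ref : ref + n] += 1
                ref += n
            elif op in "DN":
                ref += n
    return depth


def _typical_read_length(records) -> int:
    if not records:
        return 100
    return int(np.median([len(r.read_sequence) for r in records]))


def confirm_genomic(
    contigs: list[ValidationContig],
    records: list[AlignmentRecord],
    min_depth: int = CONFIRM_DEPTH,
    junction_window: int | None = None,
) -> pd.DataFrame:
    """Apply the 10×-across-both-boundaries confirmation rule.

    The junction window is one (median) short-read length on each side of
    each junction.  *confirmed* requires depth ≥ ``min_depth`` at every base
    of both junction windows and depth ≥ 1 over the whole insertion body;
    anything else is *unconfirmed*.  Gapped calls are confirmed per arm and
    reported *partially_confirmed* when only one arm passes.
    """
    depth = _contig_depth(contigs, records)
    w = junction_window or _typical_read_length(records)
    by_call: dict[int, list[str]] = {}
    for c in contigs:
        arr = depth[c.name]
        L = len(arr)
        ok = True
        for j in c.junctions:
            lo, hi = max(0, j - w), min(L, j + w)
            if hi <= lo or (arr[lo:hi] < min_depth).any():
                ok = False
        s, e = c.insertion_span
        if e > s and (arr[s:e] == 0).any():
            ok = False
        by_call.setdefault(c.call_index, []).append("confirmed" if ok else "unconfirmed")
    rows = []
    for idx, statuses in sorted(by_call.items()):
        if all(s == "confirmed" for s in statuses):
            status = "confirmed"
        elif any(s == "confirmed" for s in statuses):
            status = "partially_confirmed"
        else:
            status = "unconfirmed"
        rows.append({"call_index": idx, "status": status})
    return pd.DataFrame(rows)


def exon_support(
    contigs: list[ValidationContig],
    records: list[AlignmentRecord],
    min_depth: int = EXON_DEPTH,
) -> pd.DataFrame:
    """Coverage-defined exonic support within each insertion.

    Maximal runs with depth ≥ ``min_depth`` inside the insertion segment are
    exonic regions; *full* when they cover the entire insertion, *partial*
    when some but not all bases are exonic, *none* otherwise.
    """
    depth = _contig_depth(contigs, records)
    rows = []
    for c in contigs:
        s, e = c.insertion_span
        if e <= s:
            continue
        seg = depth[c.name][s:e]
        exonic = seg >= min_depth
        if exonic.all():
            status = "full"
        elif exonic.any():
            status = "partial"
        else:
            status = "none"
        rows.append({"call_index": c.call_index, "contig": c.name, "status": status})
    return pd.DataFrame(rows)
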