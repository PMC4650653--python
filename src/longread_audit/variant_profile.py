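"""Per-read variant extraction, site aggregation and error-ratio profiling.

Reads carry three kinds of variation relative to the reference: SNVs
(from the MD tag), insertions and deletions (from CIGAR I/D ops).  This
module turns alignments into per-read events, aggregates identical events
across reads into called sites (support fraction > 0.5 of the local depth,
after left-alignment normalization of indels), and summarizes the overall
error ratios and their distribution along the normalized read length.

Soft clips are never variants here; they are the substrate of
:mod:`longread_audit.insertion_recovery`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    DeletionEvent,
    GenomeSequences,
    InsertionEvent,
    MDInconsistencyError,
    cigar_walk,
    md_to_substitutions,
)

#: size (bp) splitting short from long indels, the CLC default cutoff
LONG_INDEL_CUTOFF = 9


@dataclass(frozen=True)
class ReadVariant:
    """One variant event observed in one read."""

    vtype: str  # SNV | INS | DEL
    chrom: str
    ref_pos: int  # SNV position / INS breakpoint / DEL start
    size: int
    ref_allele: str
    alt: str
    read_id: str
    read_frac: float  # position along the read, 0..1, sequencing orientation

    @property
    def ref_end(self) -> int:
        return self.ref_pos + (self.size if self.vtype == "DEL" else 0)


@dataclass
class VariantCall:
    """An aggregated site: identical events merged across reads."""

    vtype: str
    chrom: str
    ref_pos: int
    size: int
    ref_allele: str
    alt: str
    support: list[str]  # read ids
    depth: int

    @property
    def called(self) -> bool:
        return (
            self.depth >= 1
            and len(self.support) >= 1
            and self.depth > 0
            and len(self.support) / self.depth > 0.5
        )


@dataclass
class ErrorSummary:
    """Error ratios and positional profile over 100 normalized-read windows.

    Ratios are reported two ways: per event (events / aligned read bases)
    and per event base (an 8 bp deletion contributes 8).  ``windows`` is a
    (100 × 3) table of event counts for SNV/INS/DEL; ``size_classes`` splits
    indel counts at the 9 bp cutoff.
    """

    aligned_bases: int
    counts: dict[str, int]
    event_bases: dict[str, int]
    windows: pd.DataFrame
    size_classes: pd.DataFrame

    def ratio(self, vtype: str, per_base: bool = False) -> float:
        num = self.event_bases[vtype] if per_base else self.counts[vtype]
        return num / self.aligned_bases

    def frame(self) -> pd.DataFrame:
        rows = []
        for vt in ("SNV", "INS", "DEL"):
            rows.append(
                {
                    "type": vt,
                    "events": self.counts[vt],
                    "event_bases": self.event_bases[vt],
                    "ratio_events_pct": 100 * self.ratio(vt),
                    "ratio_bases_pct": 100 * self.ratio(vt, per_base=True),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def extract_read_variants(
    records: list[AlignmentRecord],
    skipped_md: list[str] | None = None,
) -> list[ReadVariant]:
    """Extract per-read SNV/INS/DEL events from CIGAR and MD.

    Records without an MD tag (or with an MD/CIGAR inconsistency) contribute
    their CIGAR indels but no SNVs; their ids are appended to ``skipped_md``.
    Read positions are reported as fractions of the full read length in
    sequencing orientation (reverse-strand alignments are flipped back).
    """
    events: list[ReadVariant] = []
    for rec in records:
        L = len(rec.read_sequence)

        def frac(read_pos: int) -> float:
            pos = L - 1 - read_pos if rec.strand == "-" else read_pos
            return pos / max(L - 1, 1)

        for ev in cigar_walk(rec):
            if isinstance(ev, InsertionEvent):
                events.append(
                    ReadVariant(
                        "INS",
                        rec.chrom,
                        ev.ref_breakpoint,
                        len(ev.sequence),
                        "",
                        ev.sequence,
                        rec.read_id,
                        frac(ev.read_start),
                    )
                )
            elif isinstance(ev, DeletionEvent):
                events.append(
                    ReadVariant(
                        "DEL",
                        rec.chrom,
                        ev.ref_start,
                        ev.ref_end - ev.ref_start,
                        "",
                        "",
                        rec.read_id,
                        frac(ev.read_pos),
                    )
                )
        if rec.md is None:
            if skipped_md is not None:
                skipped_md.append(rec.read_id)
            continue
        try:
            subs = md_to_substitutions(rec)
        except MDInconsistencyError:
            if skipped_md is not None:
                skipped_md.append(rec.read_id)
            continue
        for ref_pos, ref_base, read_base, read_pos in subs:
            events.append(
                ReadVariant(
                    "SNV", rec.chrom, ref_pos, 1, ref_base, read_base, rec.read_id, frac(read_pos)
                )
            )
    return events


def left_align_indel(
    vtype: str, chrom_seq: str, pos: int, size: int, alt: str
) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement.

    Standard VCF-style normalization: an insertion can move left while the
    base before the breakpoint equals the last inserted base; a deletion
    while the base before it equals its own last base.  Prevents support
    fragmentation in homopolymers and short tandem contexts.
    """
    if vtype == "INS":
        seq = alt
        while pos > 0 and chrom_seq[pos - 1] == seq[-1]:
            seq = chrom_seq[pos - 1] + seq[:-1]
            pos -= 1
        return pos, seq
    # DEL: alt unused; the deleted interval is [pos, pos+size)
    while pos > 0 and chrom_seq[pos - 1] == chrom_seq[pos + size - 1]:
        pos -= 1
    return pos, chrom_seq[pos : pos + size]


def aggregate_sites(
    events: list[ReadVariant],
    depth_track,
    genome: GenomeSequences,
    min_coverage: int = 1,
    min_count: int = 1,
    min_frac: float = 0.5,
) -> list[VariantCall]:
    """Merge identical per-read events into sites and apply the calling rule.

    A site is *called* when depth ≥ ``min_coverage``, support ≥ ``min_count``
    and support/depth > ``min_frac`` (the rendering of "probability larger
    than 0.5").  Indels are left-aligned against the reference before
    merging.  Returns all aggregated sites; filter on ``.called`` for the
    call set.  Raises for events beyond chromosome ends.
    """
    grouped: dict[tuple, list[ReadVariant]] = defaultdict(list)
    normalized: dict[tuple, tuple[int, str, str]] = {}
    for ev in events:
        clen = len(genome[ev.chrom])
        if ev.ref_end > clen or ev.ref_pos < 0:
            raise ValueError(
                f"event at {ev.chrom}:{ev.ref_pos} beyond chromosome end ({clen})"
            )
        if ev.vtype == "SNV":
            key = ("SNV", ev.chrom, ev.ref_pos, ev.alt)
            normalized[key] = (ev.ref_pos, ev.ref_allele, ev.alt)
        else:
            pos, allele = left_align_indel(
                ev.vtype, genome[ev.chrom], ev.ref_pos, ev.size, ev.alt
            )
            if ev.vtype == "INS":
                key = ("INS", ev.chrom, pos, allele)
                normalized[key] = (pos, "", allele)
            else:
                key = ("DEL", ev.chrom, pos, ev.size)
                normalized[key] = (pos, allele, "")
        grouped[key].append(ev)

    calls: list[VariantCall] = []
    for key, evs in grouped.items():
        vtype, chrom = key[0], key[1]
        pos, ref_allele, alt = normalized[key]
        size = evs[0].size if vtype != "SNV" else 1
        depth = int(depth_track.at(chrom, min(pos, len(genome[chrom]) - 1)))
        support = sorted({e.read_id for e in evs})
        call = VariantCall(vtype, chrom, pos, size, ref_allele, alt, support, depth)
        if depth >= min_coverage and len(support) >= min_count:
            calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.ref_pos))
    return calls


def called_sites(calls: list[VariantCall], min_frac: float = 0.5) -> list[VariantCall]:
    return [c for c in calls if c.depth > 0 and len(c.support) / c.depth > min_frac]


def error_summary(
    events: list[ReadVariant],
    records: list[AlignmentRecord],
    size_cutoff: int = LONG_INDEL_CUTOFF,
    n_windows: int = 100,
) -> ErrorSummary:
    """Overall error ratios, size classes and the positional profile.

    The denominator is the total number of aligned read bases (M/=/X).
    Each event falls into one of ``n_windows`` equal windows of its read's
    normalized length (window size 1% of the read by default).
    """
    aligned = sum(r.aligned_read_bases for r in records if not r.is_supplementary)
    if aligned == 0:
        raise ValueError("zero aligned bases; nothing to profile")
    counts = {"SNV": 0, "INS": 0, "DEL": 0}
    bases = {"SNV": 0, "INS": 0, "DEL": 0}
    win = np.zeros((n_windows, 3), dtype=int)
    size_rows = {
        ("INS", "short"): 0,
        ("INS", "long"): 0,
        ("DEL", "short"): 0,
        ("DEL", "long"): 0,
        ("SNV", "short"): 0,
    }
    col = {"SNV": 0, "INS": 1, "DEL": 2}
    for ev in events:
        counts[ev.vtype] += 1
        bases[ev.vtype] += ev.size
        w = min(int(ev.read_frac * n_windows), n_windows - 1)
        win[w, col[ev.vtype]] += 1
        if ev.vtype == "SNV":
            size_rows[("SNV", "short")] += 1
        else:
            cls = "long" if ev.size >= size_cutoff else "short"
            size_rows[(ev.vtype, cls)] += 1
    windows = pd.DataFrame(win, columns=["SNV", "INS", "DEL"])
    windows.index.name = "window"
    size_classes = pd.DataFrame(
        [
            {"type": t, "size_class": c, "events": n}
            for (t, c), n in size_rows.items()
        ]
    )
    return ErrorSummary(aligned, counts, bases, windows, size_classes)


def events_frame(events: list[ReadVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": e.read_id,
                "type": e.vtype,
                "chrom": e.chrom,
                "ref_pos": e.ref_pos,
                "size": e.size,
                "ref": e.ref_allele,
                "alt": e.alt,
                "read_frac": round(e.read_frac, 6),
            }
            for e in events
        ],
        columns=["read_id", "type", "chrom", "ref_pos", "size", "ref", "alt", "read_frac"],
    )
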