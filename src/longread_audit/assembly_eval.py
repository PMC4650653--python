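"""Contig statistics and reference-based assembly assessment.

Implements the standard contiguity metrics (N50/L50, and NA50/LA50 after
breaking contigs at misassembly events), duplication ratio, reference
coverage, per-100 kb variant rates and the three misassembly event classes:

* relocation — adjacent alignment blocks of one contig land on the same
  chromosome, same strand, with a reference-coordinate discontinuity of at
  least 1 kb relative to the contig-coordinate step;
* translocation — adjacent blocks on different chromosomes;
* inversion — adjacent blocks on opposite strands of one chromosome.

The input is a block-level alignment table (contig interval ↔ reference
interval, strand, identity); a converter from PAF records is provided.
Assembly and whole-genome alignment themselves are external steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeSequences
from .coverage_length import n50

RELOCATION_GAP = 1000


@dataclass(frozen=True)
class AlignmentBlock:
    contig: str
    c_start: int
    c_end: int
    chrom: str
    r_start: int
    r_end: int
    strand: str
    identity: float = 1.0
    n_snvs: int = 0
    n_short_indels: int = 0
    n_long_indels: int = 0


@dataclass(frozen=True)
class MisassemblyEvent:
    contig: str
    kind: str  # relocation | translocation | inversion
    contig_pos: int  # junction position on the contig


@dataclass
class AssemblyReport:
    n_contigs: int
    total_size: int
    largest: int
    n50: int
    l50: int
    gc_percent: float
    genome_coverage_percent: float = float("nan")
    duplication_ratio: float = float("nan")
    na50: int = 0
    la50: int = 0
    relocations: int = 0
    translocations: int = 0
    inversions: int = 0
    snvs_per_100kb: float = float("nan")
    short_indels_per_100kb: float = float("nan")
    long_indels_per_100kb: float = float("nan")
    fully_unaligned: int = 0
    partially_unaligned: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"metric": k, "value": v} for k, v in vars(self).items()]
        )


# ---------------------------------------------------------------------------


def contig_stats(contigs: dict[str, str]) -> AssemblyReport:
    """Count, total size, largest, N50, L50 and GC% of a contig set."""
    if not contigs:
        raise ValueError("empty contig set")
    lengths = np.array([len(s) for s in contigs.values()])
    total = int(lengths.sum())
    v50 = n50(lengths)
    desc = np.sort(lengths)[::-1]
    l50 = int(np.searchsorted(np.cumsum(desc), total / 2)) + 1
    gc = sum(s.count("G") + s.count("C") for s in contigs.values())
    return AssemblyReport(
        n_contigs=len(contigs),
        total_size=total,
        largest=int(lengths.max()),
        n50=v50,
        l50=l50,
        gc_percent=100.0 * gc / total,
    )


def classify_misassemblies(
    blocks: list[AlignmentBlock], relocation_gap: int = RELOCATION_GAP
) -> list[MisassemblyEvent]:
    """Classify each adjacent block pair of every contig.

    Different chromosomes → translocation; same chromosome, opposite
    strands → inversion; same chromosome and strand with a discontinuity
    ``|ref_step − contig_step| ≥ relocation_gap`` → relocation.  Single-block
    contigs yield no events.
    """
    events: list[MisassemblyEvent] = []
    by_contig: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_contig.setdefault(b.contig, []).append(b)
    for contig, bs in by_contig.items():
        bs = sorted(bs, key=lambda b: b.c_start)
        for prev, nxt in zip(bs, bs[1:]):
            pos = prev.c_end
            if prev.chrom != nxt.chrom:
                events.append(MisassemblyEvent(contig, "translocation", pos))
            elif prev.strand != nxt.strand:
                events.append(MisassemblyEvent(contig, "inversion", pos))
            else:
                contig_step = nxt.c_start - prev.c_end
                if prev.strand == "+":
                    ref_step = nxt.r_start - prev.r_end
                else:  # on "−" the contig walks the reference backwards
                    ref_step = prev.r_start - nxt.r_end
                if abs(ref_step - contig_step) >= relocation_gap:
                    events.append(MisassemblyEvent(contig, "relocation", pos))
    return events


def broken_piece_lengths(
    blocks: list[AlignmentBlock], events: list[MisassemblyEvent]
) -> list[int]:
    """Aligned contig piece lengths after breaking at misassembly junctions."""
    by_contig: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_contig.setdefault(b.contig, []).append(b)
    cuts: dict[str, set[int]] = {}
    for ev in events:
        cuts.setdefault(ev.contig, set()).add(ev.contig_pos)
    pieces: list[int] = []
    for contig, bs in by_contig.items():
        bs = sorted(bs, key=lambda b: b.c_start)
        cut = cuts.get(contig, set())
        start = bs[0].c_start
        prev_end = bs[0].c_end
        for prev, nxt in zip(bs, bs[1:]):
            if prev.c_end in cut:
                pieces.append(prev.c_end - start)
                start = nxt.c_start
            prev_end = nxt.c_end
        pieces.append(prev_end - start)
    return pieces


def alignment_metrics(
    blocks: list[AlignmentBlock],
    contigs: dict[str, str],
    genome: GenomeSequences,
    relocation_gap: int = RELOCATION_GAP,
    unaligned_min_frac: float = 0.5,
) -> AssemblyReport:
    """Full reference-based report for a contig set and its alignment blocks.

    Genome coverage is the union of reference intervals over genome length;
    duplication ratio is total aligned contig bases over covered reference
    bases.  NA50/LA50 use broken-at-misassembly piece lengths against the
    total assembly size, so NA50 ≤ N50 holds by construction.  Variant
    rates are per 100 kb of aligned contig sequence, with indels split at
    the 9 bp cutoff.
    """
    report = contig_stats(contigs)
    events = classify_misassemblies(blocks, relocation_gap)
    for ev in events:
        if ev.kind == "relocation":
            report.relocations += 1
        elif ev.kind == "translocation":
            report.translocations += 1
        else:
            report.inversions += 1

    covered_mask = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
    aligned_contig_bases = 0
    aligned_per_contig: dict[str, int] = {c: 0 for c in contigs}
    n_snvs = n_short = n_long = 0
    for b in blocks:
        covered_mask[b.chrom][b.r_start : b.r_end] = True
        aligned_contig_bases += b.c_end - b.c_start
        aligned_per_contig[b.contig] = aligned_per_contig.get(b.contig, 0) + (b.c_end - b.c_start)
        n_snvs += b.n_snvs
        n_short += b.n_short_indels
        n_long += b.n_long_indels
    covered_ref = sum(int(m.sum()) for m in covered_mask.values())
    report.genome_coverage_percent = 100.0 * covered_ref / genome.total_length
    report.duplication_ratio = (
        aligned_contig_bases / covered_ref if covered_ref else float("nan")
    )

    pieces = broken_piece_lengths(blocks, events) if blocks else []
    if pieces:
        desc = np.sort(np.array(pieces))[::-1]
        half = report.total_size / 2
        cum = np.cumsum(desc)
        idx = int(np.searchsorted(cum, half))
        if idx >= len(desc):  # aligned pieces hold less than half the assembly
            report.na50 = int(desc[-1])
            report.la50 = len(desc)
        else:
            report.na50 = int(desc[idx])
            report.la50 = idx + 1
    if aligned_contig_bases:
        scale = 1e5 / aligned_contig_bases
        report.snvs_per_100kb = n_snvs * scale
        report.short_indels_per_100kb = n_short * scale
        report.long_indels_per_100kb = n_long * scale
    report.fully_unaligned = sum(1 for c in contigs if aligned_per_contig.get(c, 0) == 0)
    report.partially_unaligned = sum(
        1
        for c in contigs
        if 0 < aligned_per_contig.get(c, 0) < unaligned_min_frac * len(contigs[c])
    )
    return report


# ---------------------------------------------------------------------------
# PAF converter and a synthetic assembly for end-to-end runs
# ---------------------------------------------------------------------------


def paf_to_blocks(path) -> list[AlignmentBlock]:
    """Convert PAF records to alignment blocks (identity = matches/alen)."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            matches, alen = int(f[9]), int(f[10])
            blocks.append(
                AlignmentBlock(
                    contig=f[0],
                    c_start=int(f[2]),
                    c_end=int(f[3]),
                    chrom=f[5],
                    r_start=int(f[7]),
                    r_end=int(f[8]),
                    strand=f[4],
                    identity=matches / alen if alen else 0.0,
                )
            )
    return blocks


def blocks_frame(blocks: list[AlignmentBlock]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in blocks])


def read_blocks_tsv(path) -> list[AlignmentBlock]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AlignmentBlock(
            contig=str(r.contig),
            c_start=int(r.c_start),
            c_end=int(r.c_end),
            chrom=str(r.chrom),
            r_start=int(r.r_start),
            r_end=int(r.r_end),
            strand=str(r.strand),
            identity=float(getattr(r, "identity", 1.0)),
            n_snvs=int(getattr(r, "n_snvs", 0)),
            n_short_indels=int(getattr(r, "n_short_indels", 0)),
            n_long_indels=int(getattr(r, "n_long_indels", 0)),
        )
        for r in df.itertuples()
    ]


def make_synthetic_assembly(
    genome: GenomeSequences,
    seed: int = 0,
    n_contigs: int = 40,
    n_relocations: int = 2,
    n_translocations: int = 1,
    n_inversions: int = 1,
) -> tuple[dict[str, str], list[AlignmentBlock], list[str]]:
    """Cut the reference into contigs, a few of them deliberately chimeric.

    Returns (contigs, true alignment blocks, expected event kinds).  Chimeric
    contigs join two reference segments with a ≥ 1 kb relocation jump, a
    chromosome switch, or a strand flip, so the classifier's output can be
    checked against construction.
    """
    rng = np.random.default_rng(seed)
    from .io_formats import revcomp

    chroms = list(genome)
    contigs: dict[str, str] = {}
    blocks: list[AlignmentBlock] = []
    expected: list[str] = []
    seg_len = max(2000, genome.total_length // (n_contigs * 2))
    n_chimeric = n_relocations + n_translocations + n_inversions
    kinds = (
        ["relocation"] * n_relocations
        + ["translocation"] * n_translocations
        + ["inversion"] * n_inversions
    )
    ci = 0

    def random_segment(chrom=None):
        c = chrom or chroms[int(rng.integers(len(chroms)))]
        limit = len(genome[c]) - seg_len
        s = int(rng.integers(0, max(1, limit)))
        return c, s, s + seg_len

    for kind in kinds:
        name = f"contig{ci:03d}"
        ci += 1
        c1, s1, e1 = random_segment()
        if kind == "translocation":
            others = [c for c in chroms if c != c1] or [c1]
            c2, s2, e2 = random_segment(others[int(rng.integers(len(others)))])
            strand2 = "+"
        elif kind == "inversion":
            c2, s2, e2 = c1, e1 + 5000, e1 + 5000 + seg_len
            if e2 > len(genome[c1]):
                s2, e2 = max(0, s1 - 5000 - seg_len), max(seg_len, s1 - 5000)
            strand2 = "-"
        else:  # relocation: jump ≥ relocation gap
            jump = 40000
            c2 = c1
            s2, e2 = e1 + jump, e1 + jump + seg_len
            if e2 > len(genome[c1]):
                s2, e2 = s1 - jump - seg_len, s1 - jump
            strand2 = "+"
        part1 = genome[c1][s1:e1]
        part2 = genome[c2][s2:e2]
        contigs[name] = part1 + (revcomp(part2) if strand2 == "-" else part2)
        blocks.append(AlignmentBlock(name, 0, len(part1), c1, s1, e1, "+"))
        blocks.append(
            AlignmentBlock(name, len(part1), len(part1) + len(part2), c2, s2, e2, strand2)
        )
        expected.append(kind)
    for _ in range(n_contigs - n_chimeric):
        name = f"contig{ci:03d}"
        ci += 1
        c, s, e = random_segment()
        length = int(rng.integers(seg_len // 2, seg_len * 2))
        e = min(s + length, len(genome[c]))
        contigs[name] = genome[c][s:e]
        blocks.append(AlignmentBlock(name, 0, e - s, c, s, e, "+"))
    return contigs, blocks, expected
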