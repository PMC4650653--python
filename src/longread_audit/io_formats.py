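"""Readers, writers and low-level alignment machinery shared by all stages.

Every coordinate inside the package is 0-based, half-open.  The conversions
to and from the 1-based conventions of SAM, GFF3 and VCF happen in this
module and nowhere else.

Formats handled: FASTA, FASTQ, SAM (via :mod:`pysam`), BED (4+ columns with a
repeat class), GFF3 gene models, VCF 4.2 output for insertion calls, and a
RepeatMasker ``.out`` → BED converter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

__all__ = [
    "FormatError",
    "GenomeSequences",
    "AlignmentRecord",
    "RepeatInterval",
    "GeneModel",
    "SamReadStats",
    "REPEAT_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_fastq_lengths",
    "write_fastq",
    "read_sam",
    "write_sam",
    "cigar_walk",
    "MatchBlock",
    "InsertionEvent",
    "DeletionEvent",
    "SoftClipEvent",
    "md_to_substitutions",
    "read_bed_repeats",
    "write_bed_repeats",
    "read_gff_genes",
    "write_gff_genes",
    "write_insertions_vcf",
    "repeatmasker_out_to_bed",
]


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


VALID_BASES = set("ACGTN")

#: Closed vocabulary of repeat classes (RepeatMasker main classes).
REPEAT_CLASSES = frozenset(
    {
        "DNA",
        "LINE",
        "SINE",
        "LTR",
        "RC_Helitron",
        "Unknown",
        "Simple",
        "Satellite",
        "Low_complexity",
    }
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class GenomeSequences(dict):
    """Mapping of chromosome name → uppercase nucleotide string.

    A thin ``dict`` subclass so the genome can be passed anywhere a mapping
    is expected while still carrying convenience accessors.
    """

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.values())

    def validate(self) -> None:
        for name, seq in self.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains illegal characters {sorted(bad)}"
                )


# CIGAR ops that consume read bases / reference bases.
READ_CONSUMING = set("MIS=X")
REF_CONSUMING = set("MD=X")

_CIGAR_OPS = "MIDNSHP=X"


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment (the substrate of all stages)."""

    read_id: str
    chrom: str
    ref_start: int  # 0-based
    strand: str  # "+" or "-"
    cigar: list[tuple[str, int]]
    read_sequence: str
    md: str | None = None
    mapq: int = 60
    is_primary: bool = True
    is_supplementary: bool = False
    quality: str | None = None

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in READ_CONSUMING)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def aligned_read_bases(self) -> int:
        return sum(n for op, n in self.cigar if op in "M=X")

    def validate(self) -> None:
        if self.read_length != len(self.read_sequence):
            raise FormatError(
                f"{self.read_id}: CIGAR consumes {self.read_length} read bases "
                f"but SEQ is {len(self.read_sequence)} bp"
            )


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int  # 0-based half-open
    repeat_class: str
    unit_sequence: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty repeat interval {self.chrom}:{self.start}-{self.end}")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"unknown repeat class {self.repeat_class!r}; "
                f"allowed: {sorted(REPEAT_CLASSES)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    coding: bool = True

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def validate(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"{self.gene_id}: exons not sorted/disjoint")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path) -> GenomeSequences:
    """Read a FASTA file into :class:`GenomeSequences` (uppercase-folded).

    Raises :class:`FormatError` naming the line number for duplicate headers,
    sequence before the first header, or illegal characters.
    """
    genome = GenomeSequences()
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                if name in genome:
                    raise FormatError(f"{path}: duplicate header {name!r} at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before first header at line {lineno}")
                seq = line.upper()
                if set(seq) - VALID_BASES:
                    raise FormatError(f"{path}: illegal characters at line {lineno}")
                chunks.append(seq)
    if name is not None:
        genome[name] = "".join(chunks)
    genome.validate()
    return genome


def write_fasta(genome: dict, path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    """Write (read_id, sequence, quality) triples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq_lengths(path) -> dict[str, int]:
    """Read-id → length map from a FASTQ file (sequences are not kept)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            lengths[header.strip().split()[0][1:]] = len(seq)
    return lengths


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


@dataclass
class SamReadStats:
    n_kept: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_supplementary_dropped: int = 0
    n_rejected: int = 0  # CIGAR/SEQ length mismatch etc.


_PYSAM_OP = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 6: "P", 7: "=", 8: "X"}
_OP_PYSAM = {v: k for k, v in _PYSAM_OP.items()}


def read_sam(
    path,
    keep_supplementary: bool = False,
    allow_hard_clips: bool = True,
    stats: SamReadStats | None = None,
) -> list[AlignmentRecord]:
    """Read a SAM file into :class:`AlignmentRecord` objects.

    Unmapped and secondary records are skipped (counted in ``stats``);
    supplementary records are kept only on request.  Records whose CIGAR does
    not account for their SEQ length are rejected and counted, per record.
    With ``allow_hard_clips=False`` any H op raises (insertion recovery needs
    the clipped bases, which hard clips discard).
    """
    if stats is None:
        stats = SamReadStats()
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        it = iter(sam)
        while True:
            try:
                seg = next(it)
            except StopIteration:
                break
            except OSError:
                # htslib cannot resume after a malformed record; count it and
                # keep what was parsed so far
                stats.n_rejected += 1
                break
            if seg.is_unmapped:
                stats.n_unmapped += 1
                continue
            if seg.is_secondary:
                stats.n_secondary += 1
                continue
            if seg.is_supplementary and not keep_supplementary:
                stats.n_supplementary_dropped += 1
                continue
            cigar = [(_PYSAM_OP[op], n) for op, n in (seg.cigartuples or [])]
            if not allow_hard_clips and any(op == "H" for op, _ in cigar):
                raise FormatError(
                    f"{seg.query_name}: hard-clipped record; clipped sequence "
                    "is required for insertion recovery"
                )
            rec = AlignmentRecord(
                read_id=seg.query_name,
                chrom=seg.reference_name,
                ref_start=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                cigar=cigar,
                read_sequence=(seg.query_sequence or "").upper(),
                md=seg.get_tag("MD") if seg.has_tag("MD") else None,
                mapq=seg.mapping_quality,
                is_primary=not (seg.is_secondary or seg.is_supplementary),
                is_supplementary=seg.is_supplementary,
                quality=(
                    pysam.qualities_to_qualitystring(seg.query_qualities)
                    if seg.query_qualities is not None
                    else None
                ),
            )
            try:
                rec.validate()
            except FormatError:
                stats.n_rejected += 1
                continue
            records.append(rec)
            stats.n_kept += 1
    return records


def write_sam(records: Iterable[AlignmentRecord], chrom_lengths: dict[str, int], path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.reference_name = rec.chrom
            seg.reference_start = rec.ref_start
            seg.mapping_quality = rec.mapq
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if rec.is_supplementary:
                flag |= 0x800
            seg.flag = flag
            seg.cigartuples = [(_OP_PYSAM[op], n) for op, n in rec.cigar]
            seg.query_sequence = rec.read_sequence
            if rec.quality is not None:
                seg.query_qualities = pysam.qualitystring_to_array(rec.quality)
            if rec.md is not None:
                seg.set_tag("MD", rec.md)
            out.write(seg)


# ---------------------------------------------------------------------------
# CIGAR walking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchBlock:
    ref_start: int
    read_start: int
    length: int


@dataclass(frozen=True)
class InsertionEvent:
    ref_breakpoint: int  # between ref bases breakpoint-1 and breakpoint
    read_start: int
    sequence: str


@dataclass(frozen=True)
class DeletionEvent:
    ref_start: int
    ref_end: int
    read_pos: int  # read offset at which the deletion occurs


@dataclass(frozen=True)
class SoftClipEvent:
    side: str  # "left" | "right"
    length: int
    sequence: str


def cigar_walk(record: AlignmentRecord):
    """Decompose an alignment into match blocks, indels and soft clips.

    Events are emitted in read order; all positions 0-based.  H ops are
    tolerated only at the ends and produce nothing (no stored sequence).
    """
    events = []
    ref = record.ref_start
    read = 0
    seq = record.read_sequence
    n_ops = len(record.cigar)
    for i, (op, n) in enumerate(record.cigar):
        if op in "M=X":
            events.append(MatchBlock(ref, read, n))
            ref += n
            read += n
        elif op == "I":
            events.append(InsertionEvent(ref, read, seq[read : read + n]))
            read += n
        elif op in "DN":
            events.append(DeletionEvent(ref, ref + n, read))
            ref += n
        elif op == "S":
            side = "left" if i == 0 or all(o in "SH" for o, _ in record.cigar[:i]) else "right"
            events.append(SoftClipEvent(side, n, seq[read : read + n]))
            read += n
        elif op == "H":
            if 0 < i < n_ops - 1:
                raise FormatError(f"{record.read_id}: internal hard clip")
        elif op == "P":
            continue
        else:
            raise FormatError(f"{record.read_id}: unsupported CIGAR op {op!r}")
    return events


# ---------------------------------------------------------------------------
# MD tag
# ---------------------------------------------------------------------------

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


class MDInconsistencyError(FormatError):
    """MD tag does not agree with the CIGAR string."""


def md_to_substitutions(record: AlignmentRecord) -> list[tuple[int, str, str, int]]:
    """Extract SNVs from the MD tag as (ref_pos, ref_base, read_base, read_pos).

    The MD string covers aligned (M/=/X) reference bases and deleted runs
    (``^``-prefixed); it is walked in lockstep with the CIGAR so each
    substitution is located in both reference and read coordinates.  Deleted
    runs are cross-checked against CIGAR D ops.  N read bases are never
    reported as substitutions.
    """
    if record.md is None:
        raise MDInconsistencyError(f"{record.read_id}: no MD tag")
    # aligned columns: (ref_pos, read_pos) for M ops; deletion markers for D
    subs: list[tuple[int, str, str, int]] = []
    seq = record.read_sequence
    # Build iterators over CIGAR-aligned reference positions.
    blocks = []  # ("M", ref_pos, read_pos, len) / ("D", ref_pos, len)
    ref = record.ref_start
    read = 0
    for op, n in record.cigar:
        if op in "M=X":
            blocks.append(("M", ref, read, n))
            ref += n
            read += n
        elif op == "I":
            read += n
        elif op in "DN":
            blocks.append(("D", ref, n))
            ref += n
        elif op == "S":
            read += n
    bi = 0  # block index
    off = 0  # offset within current block (M only)

    def advance_match(k: int):
        """Move k matched columns forward, returning nothing."""
        nonlocal bi, off
        while k:
            if bi >= len(blocks) or blocks[bi][0] != "M":
                raise MDInconsistencyError(f"{record.read_id}: MD longer than CIGAR matches")
            length = blocks[bi][3]
            step = min(k, length - off)
            off += step
            k -= step
            if off == length:
                bi += 1
                off = 0

    for m in _MD_TOKEN.finditer(record.md):
        num, deletion, mismatch = m.groups()
        if num:
            advance_match(int(num))
        elif deletion:
            run = deletion[1:].upper()
            if off != 0 or bi >= len(blocks) or blocks[bi][0] != "D" or blocks[bi][2] != len(run):
                raise MDInconsistencyError(
                    f"{record.read_id}: MD deletion {run!r} does not match CIGAR D op"
                )
            bi += 1
        else:
            if bi >= len(blocks) or blocks[bi][0] != "M":
                raise MDInconsistencyError(f"{record.read_id}: MD mismatch outside M block")
            _, bref, bread, _ = blocks[bi]
            ref_pos = bref + off
            read_pos = bread + off
            read_base = seq[read_pos]
            if read_base != "N":
                subs.append((ref_pos, mismatch.upper(), read_base, read_pos))
            advance_match(1)
    if bi < len(blocks) or off:
        raise MDInconsistencyError(f"{record.read_id}: MD shorter than CIGAR")
    return subs


def build_md(cigar: list[tuple[str, int]], read_seq: str, ref_seq: str, ref_start: int) -> str:
    """Compute the MD tag for an alignment against ``ref_seq`` (one chromosome)."""
    parts: list[str] = []
    match_run = 0
    ref = ref_start
    read = 0
    for op, n in cigar:
        if op in "M=X":
            for i in range(n):
                r = ref_seq[ref + i]
                q = read_seq[read + i]
                if r == q:
                    match_run += 1
                else:
                    parts.append(str(match_run))
                    parts.append(r)
                    match_run = 0
            ref += n
            read += n
        elif op == "I":
            read += n
        elif op in "DN":
            parts.append(str(match_run))
            match_run = 0
            parts.append("^" + ref_seq[ref : ref + n])
            ref += n
        elif op == "S":
            read += n
    parts.append(str(match_run))
    return "".join(parts)


# ---------------------------------------------------------------------------
# BED / GFF3 / VCF
# ---------------------------------------------------------------------------


def read_bed_repeats(path) -> list[RepeatInterval]:
    """BED 4+ columns: chrom, start, end, repeat_class[, unit_sequence]."""
    repeats = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}: expected ≥4 BED columns at line {lineno}")
            chrom, start, end, cls = fields[:4]
            if cls not in REPEAT_CLASSES:
                raise FormatError(
                    f"{path}: unknown repeat class {cls!r} at line {lineno}; "
                    f"allowed: {sorted(REPEAT_CLASSES)}"
                )
            unit = fields[4] if len(fields) > 4 and fields[4] != "." else None
            repeats.append(RepeatInterval(chrom, int(start), int(end), cls, unit))
    return repeats


def write_bed_repeats(repeats: Sequence[RepeatInterval], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            unit = r.unit_sequence or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.repeat_class}\t{unit}\n")


def read_gff_genes(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/exon/CDS features, 1-based closed).

    The converter to internal 0-based half-open coordinates is applied here,
    exactly once.  A gene is flagged coding when it owns at least one CDS
    feature.
    """
    genes: dict[str, GeneModel] = {}
    coding: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: expected 9 GFF columns at line {lineno}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            s, e = int(start) - 1, int(end)  # GFF 1-based closed → half-open
            if ftype == "gene":
                gid = attr.get("ID", f"gene_line{lineno}")
                genes[gid] = GeneModel(gid, chrom, strand, [], coding=False)
            elif ftype == "exon":
                gid = attr.get("Parent", "").split(":")[-1]
                gid = _resolve_gene(gid, genes)
                if gid is None:
                    raise FormatError(f"{path}: exon without gene parent at line {lineno}")
                genes[gid].exons.append((s, e))
            elif ftype == "CDS":
                gid = _resolve_gene(attr.get("Parent", "").split(":")[-1], genes)
                if gid is not None:
                    coding.add(gid)
    out = []
    for gid, g in genes.items():
        g.exons.sort()
        g.coding = gid in coding
        g.validate()
        out.append(g)
    return out


def _resolve_gene(parent: str, genes: dict) -> str | None:
    if parent in genes:
        return parent
    # mRNA ids in the synthetic GFF are "<gene>.t1"
    base = parent.rsplit(".", 1)[0]
    return base if base in genes else None


def write_gff_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsynthetic\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.e{i};Parent={tid}\n"
                )
                if g.coding:
                    fh.write(
                        f"{g.chrom}\tsynthetic\tCDS\t{xs + 1}\t{xe}\t.\t{g.strand}\t0\t"
                        f"ID={tid}.c{i};Parent={tid}\n"
                    )


def write_insertions_vcf(calls, genome: GenomeSequences, path) -> None:
    """Write insertion calls as VCF 4.2.

    POS is the 1-based base before the internal breakpoint.  Gap-containing
    (close-breakpoint) calls render the unknown middle as 100 N's with
    ``GAPPED=1``; SVLEN is the (lower-bound) insertion size.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=longread-audit')
    for name, seq in genome.items():
        header.contigs.add(name, length=len(seq))
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Insertion size (lower bound if gapped)">')
    header.add_line('##INFO=<ID=CATEGORY,Number=1,Type=String,Description="within_read|self_mapped|cross_mapped|close_breakpoint">')
    header.add_line('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting reads">')
    header.add_line('##INFO=<ID=CONTEXT,Number=1,Type=String,Description="coding_exon|intron|intergenic">')
    header.add_line('##INFO=<ID=GAPPED,Number=0,Type=Flag,Description="Sequence contains an unknown-length gap">')
    header.add_line('##INFO=<ID=VALIDATION,Number=1,Type=String,Description="unconfirmed|confirmed|partially_confirmed">')
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chrom, c.breakpoint)):
            bp = call.breakpoint
            ref_base = genome[call.chrom][max(bp - 1, 0)]
            if getattr(call, "gapped", False):
                alt_seq = call.sequence.replace(GAP_MARKER, "N" * 100)
            else:
                alt_seq = call.sequence
            rec = out.new_record(
                contig=call.chrom,
                start=max(bp - 1, 0),  # pysam start is 0-based → VCF POS = bp
                alleles=(ref_base, ref_base + alt_seq),
            )
            rec.info["SVLEN"] = int(call.size)
            rec.info["CATEGORY"] = call.category
            rec.info["SUPPORT"] = len(call.support)
            rec.info["CONTEXT"] = call.context or "intergenic"
            if getattr(call, "gapped", False):
                rec.info["GAPPED"] = True
            rec.info["VALIDATION"] = getattr(call, "validation", "unconfirmed")
            out.write(rec)


#: Marker separating the two arms of a gap-containing (close-breakpoint) call.
GAP_MARKER = "-"


# ---------------------------------------------------------------------------
# RepeatMasker .out converter
# ---------------------------------------------------------------------------

_RM_CLASS_MAP = {
    "Simple_repeat": "Simple",
    "Low_complexity": "Low_complexity",
    "Satellite": "Satellite",
    "Unknown": "Unknown",
}


def _rm_class(token: str) -> str:
    base = token.split("/")[0]
    if token.startswith("RC"):
        return "RC_Helitron"
    if base in ("DNA", "LINE", "SINE", "LTR"):
        return base
    return _RM_CLASS_MAP.get(token, _RM_CLASS_MAP.get(base, "Unknown"))


def repeatmasker_out_to_bed(out_path, bed_path) -> int:
    """Convert a RepeatMasker ``.out`` table to the package's repeat BED.

    Returns the number of intervals written.  RepeatMasker coordinates are
    1-based closed; the conversion to 0-based half-open happens here.
    """
    n = 0
    with open(out_path) as fh, open(bed_path, "w") as out:
        for line in fh:
            fields = line.split()
            if len(fields) < 11 or not fields[0].isdigit():
                continue  # header / blank lines
            chrom, start, end = fields[4], int(fields[5]) - 1, int(fields[6])
            cls = _rm_class(fields[10])
            out.write(f"{chrom}\t{start}\t{end}\t{cls}\t.\n")
            n += 1
    return n
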