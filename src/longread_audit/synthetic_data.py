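"""Synthetic study generator: toy reference, mutated donor, long reads, SAM.

Every downstream stage of the pipeline is exercised against data produced
here, with machine-readable truth tables for all injected events.  The
generator emulates the study design of a synthetic long-read experiment:

* a repeat-structured reference genome (interspersed elements, tandem
  clusters of a single short unit both below and above the ~500 bp
  pre-assembly blocker size, one copy of a collapsed-repeat unit, and gene
  models placed in unique sequence);
* a donor genome that differs from the reference by SNVs, insertions
  (sequence "missing" from the reference) and deletions, plus a k-copy
  expansion of the collapsed repeat;
* long reads with a bimodal length distribution (peaks near 1.5 kb and
  10 kb, hard minimum 1.5 kb) and end-elevated error rates;
* an aligner *emulator* that projects each read onto the reference through
  the truth table, emitting SAM in which small insertions appear as CIGAR
  I ops and large ones as soft-clipped unaligned ends.

The emulator is not an aligner: placements are exact by construction, which
makes detection regimes controllable ground truth.  Real SAM from any
aligner remains a valid input to the rest of the pipeline.

Determinism: a fixed :class:`SimulationConfig` (including seed) yields
byte-identical FASTA/FASTQ/SAM/truth outputs.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import (
    AlignmentRecord,
    GeneModel,
    GenomeSequences,
    RepeatInterval,
    build_md,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TandemClusterSpec:
    """A tandem cluster of one short unit (e.g. ``TGATA`` × 400 = 2 kb)."""

    unit: str
    n_units: int
    repeat_class: str = "Simple"
    count: int = 1

    @property
    def length(self) -> int:
        return len(self.unit) * self.n_units


@dataclass
class InterspersedRepeatSpec:
    """Identical copies of one element scattered through unique sequence."""

    repeat_class: str
    element_length: int = 400
    n_copies: int = 10


@dataclass
class CollapsedRepeatSpec:
    """A unit present once in the reference but ``donor_copies`` times,
    tandemly, in the donor (the rDNA-array situation; unit ~7.2 kb)."""

    unit_length: int = 7200
    donor_copies: int = 20


@dataclass
class VariantSpec:
    snv_rate: float = 0.0  # donor SNVs per reference base
    n_insertions: int = 0
    insertion_size_range: tuple[int, int] = (9, 2000)
    n_deletions: int = 0
    deletion_size_range: tuple[int, int] = (9, 500)
    exon_insertion_fraction: float = 0.2
    min_end_margin: int = 3000  # structural events keep this far from chrom ends
    min_event_spacing: int = 15000  # > max read length, so one read spans one event


@dataclass
class ReadSpec:
    """Two-component truncated-normal length mixture, hard floor 1500 bp.

    Defaults place the modes near 1.5 kb and 10 kb with the long mode
    heavier, reproducing the bimodal read-length profile of synthetic
    long-read libraries.
    """

    depth: float = 24.0
    mode1_mean: float = 1800.0
    mode1_sd: float = 800.0
    mode1_weight: float = 0.35
    mode2_mean: float = 9800.0
    mode2_sd: float = 1200.0
    min_length: int = 1500


@dataclass
class ErrorSpec:
    """Per-base read error rates; elevated by ``end_multiplier`` inside the
    first and last ``end_window_frac`` of each read."""

    snv_rate: float = 1e-4
    ins_rate: float = 2e-4
    del_rate: float = 1e-3
    end_window_frac: float = 0.05
    end_multiplier: float = 5.0
    indel_size_mean: float = 1.0  # geometric; 1.0 → all single-base
    del_repeat_multiplier: float = 1.0  # deletion-artifact bias inside repeats


@dataclass
class AlignerSpec:
    min_anchor: int = 1000  # smallest aligned span worth a record (seed length)
    max_cigar_insertion: int = 100  # larger insertions become soft clips
    max_cigar_deletion: int = 100
    blocker_threshold: int = 500  # tandem clusters longer than this block pre-assembly


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=lambda: {"chrI": 2_000_000})
    tandem_clusters: list[TandemClusterSpec] = field(default_factory=list)
    interspersed: list[InterspersedRepeatSpec] = field(default_factory=list)
    collapsed: CollapsedRepeatSpec | None = None
    n_genes: int = 40
    variants: VariantSpec = field(default_factory=VariantSpec)
    reads: ReadSpec = field(default_factory=ReadSpec)
    errors: ErrorSpec = field(default_factory=ErrorSpec)
    aligner: AlignerSpec = field(default_factory=AlignerSpec)

    def validate(self) -> None:
        e = self.errors
        for r in (e.snv_rate, e.ins_rate, e.del_rate, e.end_window_frac):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0,1]")
        if self.reads.min_length < 1500:
            raise ValueError("minimum read length must be ≥ 1500 bp")
        if self.reads.depth <= 0:
            raise ValueError("target depth must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


@dataclass
class ReferenceBundle:
    genome: GenomeSequences
    repeats: list[RepeatInterval]
    genes: list[GeneModel]
    collapsed_region: tuple[str, int, int] | None  # single reference copy
    collapsed_unit: str | None


class _Placer:
    """Rejection-samples non-overlapping feature placements on one chromosome."""

    def __init__(self, length: int, rng: np.random.Generator, margin: int = 1000):
        self.length = length
        self.rng = rng
        self.margin = margin
        self.starts: list[int] = []
        self.ends: list[int] = []

    def place(self, size: int, max_tries: int = 2000) -> int:
        lo, hi = 2000, self.length - size - 2000
        if hi <= lo:
            raise ValueError("requested feature content exceeds chromosome length")
        for _ in range(max_tries):
            pos = int(self.rng.integers(lo, hi))
            i = bisect_right(self.starts, pos)
            ok = True
            if i > 0 and self.ends[i - 1] + self.margin > pos:
                ok = False
            if i < len(self.starts) and pos + size + self.margin > self.starts[i]:
                ok = False
            if ok:
                self.starts.insert(i, pos)
                self.ends.insert(i, pos + size)
                return pos
        raise ValueError("requested repeat/gene content exceeds genome length")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def build_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> ReferenceBundle:
    """Construct the repeat-structured toy reference plus annotations."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genome = GenomeSequences()
    repeats: list[RepeatInterval] = []
    genes: list[GeneModel] = []
    collapsed_region = None
    collapsed_unit = None
    gene_no = 0
    for ci, (chrom, length) in enumerate(config.chromosomes.items()):
        seq = rng.choice(BASES, size=length)
        placer = _Placer(length, rng)

        for spec in config.interspersed:
            element = rng.choice(BASES, size=spec.element_length)
            for _ in range(spec.n_copies):
                pos = placer.place(spec.element_length)
                seq[pos : pos + spec.element_length] = element
                repeats.append(
                    RepeatInterval(chrom, pos, pos + spec.element_length, spec.repeat_class)
                )

        for spec in config.tandem_clusters:
            cluster = np.frombuffer((spec.unit * spec.n_units).encode(), dtype=np.uint8)
            for _ in range(spec.count):
                pos = placer.place(len(cluster))
                seq[pos : pos + len(cluster)] = cluster
                repeats.append(
                    RepeatInterval(
                        chrom, pos, pos + len(cluster), spec.repeat_class, spec.unit
                    )
                )

        if config.collapsed is not None and ci == 0:
            u = config.collapsed.unit_length
            unit = rng.choice(BASES, size=u)
            pos = placer.place(u)
            seq[pos : pos + u] = unit
            collapsed_region = (chrom, pos, pos + u)
            collapsed_unit = unit.tobytes().decode()

        n_genes_here = config.n_genes if len(config.chromosomes) == 1 else max(
            1, round(config.n_genes * length / sum(config.chromosomes.values()))
        )
        for _ in range(n_genes_here):
            n_exons = int(rng.integers(3, 7))
            exon_lens = rng.integers(100, 301, size=n_exons)
            intron_lens = rng.integers(100, 501, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            try:
                pos = placer.place(span)
            except ValueError:
                break
            exons = []
            cur = pos
            for i in range(n_exons):
                exons.append((cur, cur + int(exon_lens[i])))
                cur += int(exon_lens[i])
                if i < n_exons - 1:
                    cur += int(intron_lens[i])
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_no:04d}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                    coding=bool(rng.random() < 0.9),
                )
            )
        genome[chrom] = seq.tobytes().decode()
    repeats.sort(key=lambda r: (r.chrom, r.start))
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return ReferenceBundle(genome, repeats, genes, collapsed_region, collapsed_unit)


def blocked_clusters(bundle: ReferenceBundle, threshold: int) -> list[RepeatInterval]:
    """Tandem clusters long enough to block pre-assembly (> threshold)."""
    return [
        r for r in bundle.repeats if r.unit_sequence is not None and r.length > threshold
    ]


# ---------------------------------------------------------------------------
# donor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """One segment of the donor↔reference coordinate map."""

    kind: str  # "M" | "INS" | "DEL" | "COLLAPSED"
    chrom: str
    ref_start: int
    ref_end: int
    donor_start: int
    donor_end: int
    unit_length: int = 0  # COLLAPSED only


@dataclass(frozen=True)
class TruthVariant:
    event_id: str
    vtype: str  # SNV | INS | DEL
    chrom: str
    ref_pos: int  # SNV position / INS breakpoint / DEL start (0-based)
    size: int
    ref_allele: str
    alt_seq: str
    context: str  # coding_exon | intron | intergenic
    expected_regime: str  # cigar | clip | "" (non-insertions)


@dataclass
class DonorResult:
    genome: GenomeSequences
    truth: list[TruthVariant]
    blocks: dict[str, list[Block]]
    blocked_donor: dict[str, list[tuple[int, int]]]  # pre-assembly blockers, donor coords
    repeat_donor: dict[str, list[tuple[int, int]]] = field(default_factory=dict)  # all repeats, donor coords

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(t) for t in self.truth],
            columns=[
                "event_id",
                "vtype",
                "chrom",
                "ref_pos",
                "size",
                "ref_allele",
                "alt_seq",
                "context",
                "expected_regime",
            ],
        )


def _context_of(pos: int, chrom: str, genes: list[GeneModel]) -> str:
    for g in genes:
        if g.chrom != chrom:
            continue
        s, e = g.span
        if s <= pos < e:
            for xs, xe in g.exons:
                if xs <= pos < xe:
                    return "coding_exon" if g.coding else "intron"
            return "intron"
    return "intergenic"


def make_donor(
    bundle: ReferenceBundle,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> DonorResult:
    """Inject SNVs/insertions/deletions into the reference to build the donor.

    Insertions model sequence missing from the reference.  Structural events
    are kept ``min_event_spacing`` apart, away from chromosome ends, repeat
    clusters and the collapsed-repeat region, so that each event is
    independently recoverable.  The collapsed repeat is expanded to
    ``donor_copies`` tandem copies.  Overlapping placements are resampled; if
    placement keeps failing a config error is raised.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    vs = config.variants
    al = config.aligner
    truth: list[TruthVariant] = []
    blocks: dict[str, list[Block]] = {}
    donor = GenomeSequences()
    blocked_donor: dict[str, list[tuple[int, int]]] = {}
    repeat_donor: dict[str, list[tuple[int, int]]] = {}

    # ---- forbidden zones for structural events (reference coords) ----
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in bundle.genome}
    margin = 1000
    for r in bundle.repeats:
        forbidden[r.chrom].append((r.start - margin, r.end + margin))
    if bundle.collapsed_region is not None:
        c, s, e = bundle.collapsed_region
        forbidden[c].append((s - margin, e + margin))

    def is_free(chrom: str, s: int, e: int) -> bool:
        return not any(fs < e and s < fe for fs, fe in forbidden[chrom])

    chrom_names = list(bundle.genome)
    chrom_lens = np.array([len(bundle.genome[c]) for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    # ---- sample structural events ----
    events: list[tuple[str, int, int, str]] = []  # (chrom, pos, size, kind)

    def spaced(chrom: str, pos: int, size: int) -> bool:
        for ec, ep, es, _ in events:
            if ec == chrom and abs(pos - ep) < vs.min_event_spacing + es + size:
                return False
        return True

    def sample_position(size: int, in_exon: bool) -> tuple[str, int]:
        for attempt in range(8000):
            if attempt > 2000:
                in_exon = False  # fall back when exon space is exhausted
            if in_exon:
                coding = [g for g in bundle.genes if g.coding]
                if not coding:
                    in_exon = False
                    continue
                g = coding[int(rng.integers(len(coding)))]
                xs, xe = g.exons[int(rng.integers(len(g.exons)))]
                pos = int(rng.integers(xs + 5, xe - 5))
                chrom = g.chrom
            else:
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
                pos = int(rng.integers(vs.min_end_margin, len(bundle.genome[chrom]) - vs.min_end_margin - size))
            if is_free(chrom, pos, pos + size) and spaced(chrom, pos, size):
                end_ok = vs.min_end_margin <= pos <= len(bundle.genome[chrom]) - vs.min_end_margin - size
                if end_ok:
                    return chrom, pos
        raise ValueError("could not place structural events; genome too small or spacing too large")

    lo, hi = vs.insertion_size_range
    for i in range(vs.n_insertions):
        # log-uniform sizes cover the 9–2000 bp range evenly across decades
        size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi + 1)))))
        size = max(lo, min(hi, size))
        in_exon = rng.random() < vs.exon_insertion_fraction
        chrom, pos = sample_position(size, in_exon)
        events.append((chrom, pos, size, "INS"))
    dlo, dhi = vs.deletion_size_range
    for i in range(vs.n_deletions):
        size = int(round(np.exp(rng.uniform(np.log(dlo), np.log(dhi + 1)))))
        size = max(dlo, min(dhi, size))
        chrom, pos = sample_position(size, False)
        events.append((chrom, pos, size, "DEL"))

    # ---- build donor chromosome by chromosome ----
    ev_by_chrom: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_names}
    for chrom, pos, size, kind in events:
        ev_by_chrom[chrom].append((pos, size, kind))
    n_ins = n_del = n_snv = 0
    for chrom in chrom_names:
        ref = bundle.genome[chrom]
        cuts = sorted(ev_by_chrom[chrom])
        coll = None
        if bundle.collapsed_region is not None and bundle.collapsed_region[0] == chrom:
            _, cs, ce = bundle.collapsed_region
            coll = (cs, ce - cs, "COLLAPSED")
            cuts = sorted(cuts + [coll])
        pieces: list[str] = []
        chrom_blocks: list[Block] = []
        rpos = 0
        dpos = 0

        def add_match(upto: int):
            nonlocal rpos, dpos
            if upto > rpos:
                pieces.append(ref[rpos:upto])
                chrom_blocks.append(Block("M", chrom, rpos, upto, dpos, dpos + upto - rpos))
                dpos += upto - rpos
                rpos = upto

        for pos, size, kind in cuts:
            add_match(pos)
            if kind == "INS":
                n_ins += 1
                ins_seq = _random_seq(rng, size)
                pieces.append(ins_seq)
                chrom_blocks.append(Block("INS", chrom, pos, pos, dpos, dpos + size))
                truth.append(
                    TruthVariant(
                        f"ins{n_ins:04d}",
                        "INS",
                        chrom,
                        pos,
                        size,
                        "",
                        ins_seq,
                        _context_of(pos, chrom, bundle.genes),
                        "cigar" if size <= al.max_cigar_insertion else "clip",
                    )
                )
                dpos += size
            elif kind == "DEL":
                n_del += 1
                chrom_blocks.append(Block("DEL", chrom, pos, pos + size, dpos, dpos))
                truth.append(
                    TruthVariant(
                        f"del{n_del:04d}",
                        "DEL",
                        chrom,
                        pos,
                        size,
                        ref[pos : pos + size],
                        "",
                        _context_of(pos, chrom, bundle.genes),
                        "",
                    )
                )
                rpos = pos + size
            else:  # COLLAPSED
                k = config.collapsed.donor_copies
                unit = ref[pos : pos + size]
                pieces.append(unit * k)
                chrom_blocks.append(
                    Block("COLLAPSED", chrom, pos, pos + size, dpos, dpos + size * k, unit_length=size)
                )
                dpos += size * k
                rpos = pos + size
        add_match(len(ref))
        donor_seq = "".join(pieces)

        # ---- SNVs (substitutions only; donor length unchanged) ----
        n_target = int(round(vs.snv_rate * len(ref)))
        if n_target:
            arr = np.frombuffer(donor_seq.encode(), dtype=np.uint8).copy()
            struct_bad = set()
            for b in chrom_blocks:
                if b.kind != "M":
                    struct_bad.add((b.donor_start, b.donor_end))
            m_blocks = [b for b in chrom_blocks if b.kind == "M"]
            starts = [b.donor_start for b in m_blocks]
            chosen: set[int] = set()
            tries = 0
            while len(chosen) < n_target and tries < 50 * n_target + 100:
                tries += 1
                d = int(rng.integers(0, len(donor_seq)))
                i = bisect_right(starts, d) - 1
                if i < 0 or d >= m_blocks[i].donor_end or d in chosen:
                    continue
                b = m_blocks[i]
                refpos = b.ref_start + (d - b.donor_start)
                old = arr[d]
                alt = old
                while alt == old:
                    alt = int(rng.choice(BASES))
                arr[d] = alt
                chosen.add(d)
                n_snv += 1
                truth.append(
                    TruthVariant(
                        f"snv{n_snv:05d}",
                        "SNV",
                        chrom,
                        refpos,
                        1,
                        chr(old),
                        chr(alt),
                        _context_of(refpos, chrom, bundle.genes),
                        "",
                    )
                )
            donor_seq = arr.tobytes().decode()
        donor[chrom] = donor_seq
        blocks[chrom] = chrom_blocks

        # ---- project repeat annotations into donor coordinates ----
        blocked_donor[chrom] = []
        repeat_donor[chrom] = []
        blocked_set = {
            (r.chrom, r.start, r.end) for r in blocked_clusters(bundle, al.blocker_threshold)
        }
        for r in bundle.repeats:
            if r.chrom != chrom:
                continue
            for b in chrom_blocks:
                if b.kind == "M" and b.ref_start <= r.start and r.end <= b.ref_end:
                    off = b.donor_start - b.ref_start
                    repeat_donor[chrom].append((r.start + off, r.end + off))
                    if (r.chrom, r.start, r.end) in blocked_set:
                        blocked_donor[chrom].append((r.start + off, r.end + off))
                    break
    truth.sort(key=lambda t: (t.chrom, t.ref_pos))
    return DonorResult(donor, truth, blocks, blocked_donor, repeat_donor)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class ReadEdit:
    kind: str  # "SNV" | "INS" | "DEL"
    donor_pos: int  # absolute donor coordinate (edit applies before this base)
    size: int
    seq: str = ""  # inserted bases (INS) / substituted base (SNV)


@dataclass
class SimRead:
    read_id: str
    chrom: str
    donor_start: int
    donor_end: int
    strand: str
    sequence: str  # donor-forward orientation
    quality: str
    edits: list[ReadEdit]
    blocked: bool = False  # pre-assembly failure (never aligned)

    @property
    def fastq_sequence(self) -> str:
        return revcomp(self.sequence) if self.strand == "-" else self.sequence

    @property
    def fastq_quality(self) -> str:
        return self.quality[::-1] if self.strand == "-" else self.quality


@dataclass
class SimulatedReads:
    reads: list[SimRead]
    n_blocked_dropped: int
    n_sampled: int

    def lengths(self) -> np.ndarray:
        return np.array([len(r.sequence) for r in self.reads])


def truncated_mixture_mean(spec: ReadSpec) -> float:
    """Analytic mean of the length mixture truncated at ``min_length``.

    For each normal component, E[X; X ≥ t] = μ(1−Φ(α)) + σφ(α) with
    α=(t−μ)/σ; the truncated-mixture mean is the weight-renormalized ratio.
    """
    t = spec.min_length
    num = den = 0.0
    for w, mu, sd in (
        (spec.mode1_weight, spec.mode1_mean, spec.mode1_sd),
        (1.0 - spec.mode1_weight, spec.mode2_mean, spec.mode2_sd),
    ):
        a = (t - mu) / sd
        num += w * (mu * norm.sf(a) + sd * norm.pdf(a))
        den += w * norm.sf(a)
    return num / den


def sample_read_lengths(spec: ReadSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        m = (n - out.size) * 2 + 16
        comp = rng.random(m) < spec.mode1_weight
        x = np.where(
            comp,
            rng.normal(spec.mode1_mean, spec.mode1_sd, size=m),
            rng.normal(spec.mode2_mean, spec.mode2_sd, size=m),
        )
        x = x[x >= spec.min_length]
        out = np.concatenate([out, np.round(x).astype(np.int64)])
    return out[:n]


def _qual_string(L: int, errors: ErrorSpec) -> str:
    p = errors.snv_rate + errors.ins_rate + errors.del_rate
    w = int(round(L * errors.end_window_frac))
    q_in = int(min(60, round(-10 * np.log10(max(p, 1e-6)))))
    q_out = int(min(60, round(-10 * np.log10(max(p * errors.end_multiplier, 1e-6)))))
    arr = bytearray([q_in + 33] * L)
    arr[:w] = bytes([q_out + 33] * w)
    if w:
        arr[L - w :] = bytes([q_out + 33] * w)
    return arr.decode()


def simulate_reads(
    donor_result: DonorResult,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedReads:
    """Draw reads from the donor with the configured length/error model.

    The read count is ``round(depth · donor_length / E[length])`` using the
    analytic truncated-mixture mean, so the expected total yield equals the
    target depth.  Reads overlapping a pre-assembly blocker (tandem cluster
    longer than the blocker threshold) are truncated to their largest
    cluster-free piece — emulating pre-assembly failure over the cluster —
    and dropped entirely when no piece reaches the minimum length.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    spec = config.reads
    err = config.errors
    donor = donor_result.genome
    chrom_names = list(donor)
    chrom_lens = np.array([len(donor[c]) for c in chrom_names], dtype=float)
    total = chrom_lens.sum()
    mean_len = truncated_mixture_mean(spec)
    n_reads = int(round(spec.depth * total / mean_len))

    lengths = sample_read_lengths(spec, n_reads, rng)
    chrom_idx = rng.choice(len(chrom_names), size=n_reads, p=chrom_lens / total)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    # repeat mask in donor coordinates, only needed for the deletion bias
    repeat_mask: dict[str, np.ndarray] = {}
    if err.del_repeat_multiplier != 1.0:
        for chrom in chrom_names:
            mask = np.zeros(len(donor[chrom]), dtype=bool)
            for rs, re_ in donor_result.repeat_donor.get(chrom, []):
                mask[rs:re_] = True
            repeat_mask[chrom] = mask
    reads: list[SimRead] = []
    n_dropped = 0
    for i in range(n_reads):
        chrom = chrom_names[chrom_idx[i]]
        clen = len(donor[chrom])
        L = int(min(lengths[i], clen))
        # fragments may run off the chromosome ends (ends are fragment
        # boundaries in a real library), so edges stay covered; off-end
        # portions are truncated and too-short leftovers dropped
        lo = -(L - spec.min_length)
        hi = clen - spec.min_length
        start = int(rng.integers(lo, hi + 1))
        end = min(clen, start + L)
        start = max(0, start)
        L = end - start

        # pre-assembly blockers: keep the largest cluster-free piece
        pieces = [(start, end)]
        for bs, be in donor_result.blocked_donor.get(chrom, []):
            nxt = []
            for ps, pe in pieces:
                if bs < pe and ps < be:
                    if ps < bs:
                        nxt.append((ps, bs))
                    if be < pe:
                        nxt.append((be, pe))
                else:
                    nxt.append((ps, pe))
            pieces = nxt
        if not pieces:
            n_dropped += 1
            continue
        start, end = max(pieces, key=lambda p: p[1] - p[0])
        L = end - start
        if L < spec.min_length:
            n_dropped += 1
            continue

        edits = _sample_read_errors(chrom, start, end, err, repeat_mask, rng)
        seq = _apply_edits(donor[chrom], start, end, edits)
        reads.append(
            SimRead(
                read_id=f"sim_{i:06d}",
                chrom=chrom,
                donor_start=start,
                donor_end=end,
                strand=str(strands[i]),
                sequence=seq,
                quality=_qual_string(len(seq), err),
                edits=edits,
            )
        )
    return SimulatedReads(reads, n_dropped, n_reads)


def _sample_read_errors(
    chrom: str,
    start: int,
    end: int,
    err: ErrorSpec,
    repeat_mask: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> list[ReadEdit]:
    L = end - start
    if err.snv_rate == err.ins_rate == err.del_rate == 0.0:
        return []
    # end windows carry end_multiplier× the interior rate; the profile is
    # normalized to mean 1 so the configured rates are genome-wide means
    mult = np.ones(L)
    w = int(round(L * err.end_window_frac))
    if w:
        mult[:w] = err.end_multiplier
        mult[L - w :] = err.end_multiplier
    mult /= mult.mean()
    u = rng.random((3, L))
    snv_pos = np.nonzero(u[0] < err.snv_rate * mult)[0]
    ins_pos = np.nonzero(u[1] < err.ins_rate * mult)[0]
    del_rate = np.full(L, err.del_rate) * mult
    if chrom in repeat_mask and repeat_mask[chrom].any():
        del_rate *= np.where(repeat_mask[chrom][start:end], err.del_repeat_multiplier, 1.0)
    del_pos = np.nonzero(u[2] < del_rate)[0]

    def indel_size() -> int:
        if err.indel_size_mean <= 1.0:
            return 1
        return int(rng.geometric(1.0 / err.indel_size_mean))

    edits: list[ReadEdit] = []
    for p in snv_pos:
        edits.append(ReadEdit("SNV", start + int(p), 1, ""))
    for p in ins_pos:
        edits.append(ReadEdit("INS", start + int(p), indel_size(), ""))
    for p in del_pos:
        s = indel_size()
        if int(p) + s < L - 1:
            edits.append(ReadEdit("DEL", start + int(p), s, ""))
    edits.sort(key=lambda e: e.donor_pos)
    # drop edits that collide with a preceding edit (same base, or inside a
    # preceding deletion's span)
    cleaned: list[ReadEdit] = []
    busy_until = -1
    for e in edits:
        if e.donor_pos <= busy_until:
            continue
        cleaned.append(e)
        busy_until = e.donor_pos + (e.size - 1 if e.kind == "DEL" else 0)
    # materialize random bases now, in donor order, for determinism
    for e in cleaned:
        if e.kind == "INS":
            e.seq = rng.choice(BASES, size=e.size).tobytes().decode()
    return cleaned


def _apply_edits(donor_seq: str, start: int, end: int, edits: list[ReadEdit]) -> str:
    """Build the read sequence from a donor window plus read-level edits."""
    if not edits:
        return donor_seq[start:end]
    out = []
    cur = start
    for e in edits:
        out.append(donor_seq[cur : e.donor_pos])
        if e.kind == "SNV":
            old = donor_seq[e.donor_pos]
            # deterministic substitution: next base in ACGT order
            alt = "ACGT"[("ACGT".index(old) + 1) % 4]
            e.seq = alt
            out.append(alt)
            cur = e.donor_pos + 1
        elif e.kind == "INS":
            out.append(e.seq)
            out.append(donor_seq[e.donor_pos])
            cur = e.donor_pos + 1
        else:  # DEL
            cur = e.donor_pos + e.size
    out.append(donor_seq[cur:end])
    return "".join(out)


def write_reads_fastq(sim: SimulatedReads, path) -> None:
    from .io_formats import write_fastq

    write_fastq(
        ((r.read_id, r.fastq_sequence, r.fastq_quality) for r in sim.reads), path
    )


def reads_truth_frame(sim: SimulatedReads) -> pd.DataFrame:
    rows = []
    for r in sim.reads:
        rows.append(
            {
                "read_id": r.read_id,
                "chrom": r.chrom,
                "donor_start": r.donor_start,
                "donor_end": r.donor_end,
                "strand": r.strand,
                "length": len(r.sequence),
                "n_snv_err": sum(e.kind == "SNV" for e in r.edits),
                "n_ins_err": sum(e.kind == "INS" for e in r.edits),
                "n_del_err": sum(e.kind == "DEL" for e in r.edits),
                "blocked": r.blocked,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "chrom",
            "donor_start",
            "donor_end",
            "strand",
            "length",
            "n_snv_err",
            "n_ins_err",
            "n_del_err",
            "blocked",
        ],
    )


# ---------------------------------------------------------------------------
# aligner emulator
# ---------------------------------------------------------------------------


@dataclass
class _Piece:
    """Atomic read segment in donor order, before chain assembly."""

    kind: str  # "M" (ref-mapped) | "INS" (unaligned bases)
    length: int
    ref_start: int = -1  # M only
    wrap: bool = False  # M inside the collapsed array
    full_insertion: bool = False  # INS piece covering a whole donor insertion
    seq: str = ""


def _pieces_for_read(read: SimRead, blocks: list[Block]) -> list[_Piece]:
    s, e = read.donor_start, read.donor_end
    pieces: list[_Piece] = []
    for b in blocks:
        if b.donor_end <= s or b.donor_start >= e:
            if b.kind == "DEL" and s < b.donor_start < e:
                pass  # zero-width; ref gap emerges from neighbours
            continue
        lo, hi = max(s, b.donor_start), min(e, b.donor_end)
        if b.kind == "M":
            pieces.append(_Piece("M", hi - lo, b.ref_start + (lo - b.donor_start)))
        elif b.kind == "INS":
            pieces.append(
                _Piece(
                    "INS",
                    hi - lo,
                    full_insertion=(lo == b.donor_start and hi == b.donor_end),
                )
            )
        elif b.kind == "COLLAPSED":
            u = b.unit_length
            d = lo
            while d < hi:
                off = (d - b.donor_start) % u
                step = min(u - off, hi - d)
                pieces.append(_Piece("M", step, b.ref_start + off, wrap=True))
                d += step
    return pieces


def _overlay_edits(pieces: list[_Piece], read: SimRead) -> list[_Piece]:
    """Apply read-level edits (donor coordinates) onto the piece list."""
    if not read.edits:
        return pieces
    out: list[_Piece] = []
    # walk pieces against edits; donor cursor tracks M/INS donor span equally
    donor = read.donor_start
    edits = list(read.edits)
    ei = 0
    for p in pieces:
        seg_start, seg_end = donor, donor + p.length
        donor = seg_end
        cur = seg_start
        sub: list[_Piece] = []

        def emit(a: int, b: int):
            if b > a:
                if p.kind == "M":
                    sub.append(
                        _Piece("M", b - a, p.ref_start + (a - seg_start), wrap=p.wrap)
                    )
                else:
                    sub.append(_Piece("INS", b - a, full_insertion=False))

        while ei < len(edits) and edits[ei].donor_pos < seg_end:
            e = edits[ei]
            if e.donor_pos < seg_start:
                # deletion spilling in from a previous piece
                if e.kind == "DEL" and e.donor_pos + e.size > seg_start:
                    cur = min(seg_end, e.donor_pos + e.size)
                    if e.donor_pos + e.size > seg_end:
                        break  # still spills further; keep for the next piece
                ei += 1
                continue
            if e.kind == "SNV":
                ei += 1
                continue  # sequence already differs; no structural change
            emit(cur, e.donor_pos)
            if e.kind == "INS":
                sub.append(_Piece("INS", e.size, seq=e.seq))
                cur = e.donor_pos
                # the base at donor_pos itself still belongs to the piece
                ei += 1
                # emit the single base now so later edits stay ordered
                emit(cur, cur + 1)
                cur += 1
            else:  # DEL
                cur = min(seg_end, e.donor_pos + e.size)
                if e.donor_pos + e.size <= seg_end:
                    ei += 1
                else:
                    break  # spills into next piece; keep edit for it
        emit(cur, seg_end)
        # preserve full-insertion marker when the piece survived intact
        if p.kind == "INS" and p.full_insertion and len(sub) == 1 and sub[0].length == p.length:
            sub[0].full_insertion = True
        out.extend(sub)
    return [p for p in out if p.length > 0]


@dataclass
class _Chain:
    ref_start: int
    ops: list[tuple[str, int]]
    read_start: int
    read_end: int
    aligned: int
    wrap: bool = False

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in "MD")


def emulate_alignment(
    sim: SimulatedReads,
    bundle: ReferenceBundle,
    donor_result: DonorResult,
    config: SimulationConfig,
) -> tuple[list[AlignmentRecord], int]:
    """Project reads onto the reference through the truth table, emitting SAM
    records with the study's detection regimes.

    For a read spanning an injected insertion of size *s* with
    reference-anchored flanks *f_left*, *f_right*: when
    ``s ≤ max_cigar_insertion`` and both flanks ≥ ``min_anchor`` the record
    carries an I op (regime "cigar"); otherwise the longer flank becomes the
    primary alignment and the rest of the read a soft clip (regime "clip").
    Read-level error indels are always CIGAR-encoded.  Reads over the donor's
    collapsed-repeat array are wrapped modularly onto the single reference
    copy; the longest wrap is the primary record, the others supplementary.
    Returns (records, n_unmapped).
    """
    al = config.aligner
    records: list[AlignmentRecord] = []
    n_unmapped = 0
    for read in sim.reads:
        if read.blocked:
            continue
        chrom_blocks = donor_result.blocks[read.chrom]
        pieces = _overlay_edits(_pieces_for_read(read, chrom_blocks), read)
        total = sum(p.length for p in pieces)
        if total != len(read.sequence):
            raise RuntimeError(
                f"{read.read_id}: truth/read mismatch ({total} vs {len(read.sequence)})"
            )
        # flank sums for the donor-insertion regime rule
        m_total = sum(p.length for p in pieces if p.kind == "M")
        chains: list[_Chain] = []
        cur: _Chain | None = None
        read_pos = 0
        m_seen = 0
        for p in pieces:
            if p.kind == "M":
                if cur is None:
                    cur = _Chain(p.ref_start, [], read_pos, read_pos, 0, wrap=p.wrap)
                else:
                    gap = p.ref_start - cur.ref_end
                    if gap == 0:
                        pass
                    elif 0 < gap <= al.max_cigar_deletion:
                        cur.ops.append(("D", gap))
                    else:
                        chains.append(cur)
                        cur = _Chain(p.ref_start, [], read_pos, read_pos, 0, wrap=p.wrap)
                cur.ops.append(("M", p.length))
                cur.read_end = read_pos + p.length
                cur.aligned += p.length
                cur.wrap = cur.wrap or p.wrap
                read_pos += p.length
                m_seen += p.length
            else:  # INS piece
                is_error_ins = bool(p.seq)
                f_left, f_right = m_seen, m_total - m_seen
                keep = is_error_ins or (
                    p.full_insertion
                    and p.length <= al.max_cigar_insertion
                    and f_left >= al.min_anchor
                    and f_right >= al.min_anchor
                )
                if keep and cur is not None:
                    cur.ops.append(("I", p.length))
                    cur.read_end = read_pos + p.length
                else:
                    if cur is not None:
                        chains.append(cur)
                        cur = None
                read_pos += p.length
        if cur is not None:
            chains.append(cur)
        chains = [c for c in chains if c.aligned > 0]
        if not chains:
            n_unmapped += 1
            continue
        primary = max(chains, key=lambda c: c.aligned)
        if primary.aligned < al.min_anchor:
            n_unmapped += 1
            continue
        emit = [primary]
        overlaps_collapsed = any(c.wrap for c in chains)
        if overlaps_collapsed:
            emit += [
                c for c in chains if c is not primary and c.aligned >= al.min_anchor
            ]
        for c in emit:
            cigar: list[tuple[str, int]] = []
            if c.read_start > 0:
                cigar.append(("S", c.read_start))
            cigar.extend(_merge_ops(c.ops))
            if c.read_end < len(read.sequence):
                cigar.append(("S", len(read.sequence) - c.read_end))
            # trailing I op cannot end an aligned chain; fold into the clip
            cigar = _sanitize(cigar)
            md = build_md(cigar, read.sequence, bundle.genome[read.chrom], c.ref_start)
            rec = AlignmentRecord(
                read_id=read.read_id,
                chrom=read.chrom,
                ref_start=c.ref_start,
                strand=read.strand,
                cigar=cigar,
                read_sequence=read.sequence,
                md=md,
                mapq=60,
                is_primary=(c is primary),
                is_supplementary=(c is not primary),
                quality=read.quality,
            )
            rec.validate()
            records.append(rec)
    return records, n_unmapped


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _sanitize(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Fold I/D ops adjacent to soft clips into the clip (aligners never end
    an alignment on an indel)."""
    ops = list(cigar)
    changed = True
    while changed:
        changed = False
        # leading
        i = 0
        lead_s = 0
        if ops and ops[0][0] == "S":
            lead_s = ops[0][1]
            i = 1
        if i < len(ops) and ops[i][0] == "I":
            lead_s += ops[i][1]
            ops = ([("S", lead_s)] if lead_s else []) + ops[i + 1 :]
            changed = True
            continue
        if i < len(ops) and ops[i][0] == "D":
            ops = ([("S", lead_s)] if lead_s else []) + ops[i + 1 :]
            # a leading deletion shifts ref_start; emulator never produces this
            changed = True
            continue
        # trailing
        j = len(ops)
        tail_s = 0
        if ops and ops[-1][0] == "S":
            tail_s = ops[-1][1]
            j = len(ops) - 1
        if j > 0 and ops[j - 1][0] == "I":
            tail_s += ops[j - 1][1]
            ops = ops[: j - 1] + ([("S", tail_s)] if tail_s else [])
            changed = True
            continue
        if j > 0 and ops[j - 1][0] == "D":
            ops = ops[: j - 1] + ([("S", tail_s)] if tail_s else [])
            changed = True
            continue
    return _merge_ops(ops)


# ---------------------------------------------------------------------------
# whole-simulation convenience + scenarios
# ---------------------------------------------------------------------------


@dataclass
class SimulationBundle:
    config: SimulationConfig
    reference: ReferenceBundle
    donor: DonorResult
    reads: SimulatedReads
    records: list[AlignmentRecord]
    n_unmapped: int


def run_simulation(config: SimulationConfig) -> SimulationBundle:
    """Reference → donor → reads → emulated SAM, in one deterministic call."""
    reference = build_reference(config)
    donor = make_donor(reference, config)
    reads = simulate_reads(donor, config)
    records, n_unmapped = emulate_alignment(reads, reference, donor, config)
    return SimulationBundle(config, reference, donor, reads, records, n_unmapped)


def error_profile_scenario(seed: int = 0, genome_length: int = 2_000_000) -> SimulationConfig:
    """The read-accuracy regime: 24× over 2 Mb, configured per-base error
    rates 0.01% SNV / 0.02% insertion / 0.10% deletion, no donor variants."""
    return SimulationConfig(
        seed=seed,
        chromosomes={"chrI": genome_length},
        errors=ErrorSpec(snv_rate=1e-4, ins_rate=2e-4, del_rate=1e-3),
        reads=ReadSpec(depth=24.0),
        n_genes=40,
    )


def insertion_scenario(
    seed: int = 0,
    n_insertions: int = 50,
    depth: float = 12.0,
    with_errors: bool = False,
    genome_length: int = 2_000_000,
) -> SimulationConfig:
    """Missing-sequence recovery: insertions of 9–2000 bp with wide flanks."""
    errors = (
        ErrorSpec(snv_rate=1e-4, ins_rate=2e-4, del_rate=1e-3)
        if with_errors
        else ErrorSpec(snv_rate=0.0, ins_rate=0.0, del_rate=0.0)
    )
    return SimulationConfig(
        seed=seed,
        chromosomes={"chrI": genome_length},
        variants=VariantSpec(n_insertions=n_insertions, insertion_size_range=(9, 2000)),
        reads=ReadSpec(depth=depth),
        errors=errors,
        n_genes=40,
    )


def tandem_scenario(seed: int = 0, genome_length: int = 300_000) -> SimulationConfig:
    """Tandem-cluster blocking: one 2 kb and one 300 bp TGATA cluster plus a
    background of other repeat classes."""
    return SimulationConfig(
        seed=seed,
        chromosomes={"chrI": genome_length},
        tandem_clusters=[
            TandemClusterSpec("TGATA", 400),  # 2000 bp — blocks pre-assembly
            TandemClusterSpec("TGATA", 60),  # 300 bp — does not
        ],
        interspersed=[
            InterspersedRepeatSpec("DNA", 400, 6),
            InterspersedRepeatSpec("LINE", 600, 4),
            InterspersedRepeatSpec("SINE", 200, 6),
        ],
        errors=ErrorSpec(snv_rate=0.0, ins_rate=0.0, del_rate=0.0),
        reads=ReadSpec(depth=24.0),
        n_genes=10,
    )


def collapsed_scenario(seed: int = 0, donor_copies: int = 20) -> SimulationConfig:
    """Collapsed-repeat copy number: one 7.2 kb unit, k donor copies, 24×."""
    return SimulationConfig(
        seed=seed,
        chromosomes={"chrI": 600_000},
        collapsed=CollapsedRepeatSpec(unit_length=7200, donor_copies=donor_copies),
        errors=ErrorSpec(snv_rate=0.0, ins_rate=0.0, del_rate=0.0),
        reads=ReadSpec(depth=24.0),
        n_genes=10,
    )


def null_scenario(seed: int = 0, genome_length: int = 300_000) -> SimulationConfig:
    """End-to-end null: zero error rates, zero injected variants; one blocked
    cluster so the only expected gap is the blocked one."""
    return SimulationConfig(
        seed=seed,
        chromosomes={"chrI": genome_length},
        tandem_clusters=[TandemClusterSpec("TGATA", 400)],
        errors=ErrorSpec(snv_rate=0.0, ins_rate=0.0, del_rate=0.0),
        reads=ReadSpec(depth=24.0),
        n_genes=10,
    )


def deletion_artifact_scenario(seed: int = 0, genome_length: int = 500_000) -> SimulationConfig:
    """Read-level (false) deletions biased into repeat intervals, mirroring
    the observation that read deletions concentrate in repetitive sequence."""
    return SimulationConfig(
        seed=seed,
        chromosomes={"chrI": genome_length},
        interspersed=[
            InterspersedRepeatSpec("DNA", 500, 20),
            InterspersedRepeatSpec("LINE", 800, 10),
        ],
        errors=ErrorSpec(
            snv_rate=1e-4, ins_rate=2e-4, del_rate=1e-3, del_repeat_multiplier=8.0
        ),
        reads=ReadSpec(depth=24.0),
        n_genes=10,
    )


# ---------------------------------------------------------------------------
# short-read generators for the validation stage
# ---------------------------------------------------------------------------


def simulate_contig_reads(
    contig_name: str,
    contig_seq: str,
    depth: float,
    rng: np.random.Generator,
    read_length: int = 100,
    intervals: list[tuple[int, int]] | None = None,
) -> list[AlignmentRecord]:
    """Uniform error-free short reads over a validation contig.

    With ``intervals`` given, reads are drawn only from those sub-intervals
    (the RNA-seq case: reads come from expressed exons).  Records are
    returned aligned to the contig, ready for the confirmation rules.
    """
    records = []
    regions = intervals if intervals is not None else [(0, len(contig_seq))]
    n = 0
    for rs, re_ in regions:
        span = re_ - rs
        if span < read_length:
            continue
        count = int(round(depth * span / read_length))
        starts = rng.integers(rs, re_ - read_length + 1, size=count)
        for st in np.sort(starts):
            st = int(st)
            records.append(
                AlignmentRecord(
                    read_id=f"{contig_name}_sr{n:06d}",
                    chrom=contig_name,
                    ref_start=st,
                    strand="+" if rng.random() < 0.5 else "-",
                    cigar=[("M", read_length)],
                    read_sequence=contig_seq[st : st + read_length],
                    md=str(read_length),
                )
            )
            n += 1
    return records
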