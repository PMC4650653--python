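"""Depth tracks, coverage gaps, read-length statistics and accumulative
shorter/longer-than-L coverage curves.

The central question these tools answer is how read length drives genome
recovery: reads are stratified into 100 bp length bins (1.5–15.4 kb plus an
open top bin), and for every candidate split length L the fraction of a
target space (whole genome, gene space, repeat space) covered using only
reads shorter than L is compared with the fraction covered using reads of
length ≥ L.  The grid point where the two curves meet is the length at which
short and long reads recover the target equally well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, GeneModel, GenomeSequences, RepeatInterval

STRATA_START = 1500
STRATA_STEP = 100
STRATA_LAST = 15400  # lengths beyond this fall into one open bin


@dataclass
class DepthTrack:
    """Per-base depth arrays, one per chromosome.

    Depth counts reference bases consumed by M/=/X ops only; deletions do
    not add depth.  ``mean`` is total aligned reference bases over genome
    length.
    """

    depth: dict[str, np.ndarray]

    def at(self, chrom: str, pos: int) -> int:
        return int(self.depth[chrom][pos])

    @property
    def genome_length(self) -> int:
        return sum(len(a) for a in self.depth.values())

    @property
    def mean(self) -> float:
        return sum(int(a.sum()) for a in self.depth.values()) / self.genome_length

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        return float(self.depth[chrom][start:end].mean())


def _record_ref_intervals(rec: AlignmentRecord):
    ref = rec.ref_start
    for op, n in rec.cigar:
        if op in "M=X":
            yield ref, ref + n
            ref += n
        elif op in "DN":
            ref += n


def depth_track(
    records: list[AlignmentRecord],
    genome: GenomeSequences,
    include_supplementary: bool = False,
) -> DepthTrack:
    """Per-base depth from primary alignments (supplementary by request)."""
    depth = {c: np.zeros(len(s), dtype=np.int32) for c, s in genome.items()}
    for rec in records:
        if rec.is_supplementary and not include_supplementary:
            continue
        arr = depth[rec.chrom]
        for s, e in _record_ref_intervals(rec):
            arr[s:e] += 1
    return DepthTrack(depth)


@dataclass(frozen=True)
class GapRegion:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_gaps(track: DepthTrack, min_length: int = 1) -> list[GapRegion]:
    """Maximal zero-depth runs, sorted by length (longest first)."""
    gaps: list[GapRegion] = []
    for chrom, arr in track.depth.items():
        zero = arr == 0
        # run boundaries via the discrete difference of the indicator
        d = np.diff(zero.astype(np.int8))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0] + 1)
        if zero[0]:
            starts.insert(0, 0)
        if zero[-1]:
            ends.append(len(arr))
        for s, e in zip(starts, ends):
            if e - s >= min_length:
                gaps.append(GapRegion(chrom, int(s), int(e)))
    gaps.sort(key=lambda g: -g.length)
    return gaps


# ---------------------------------------------------------------------------
# read length statistics
# ---------------------------------------------------------------------------


def n50(lengths) -> int:
    """Smallest length in the minimal set of longest items holding ≥ half
    the total yield."""
    arr = np.sort(np.asarray(lengths))[::-1]
    if arr.size == 0:
        raise ValueError("empty length set")
    half = arr.sum() / 2
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[min(idx, arr.size - 1)])


@dataclass
class LengthStrata:
    edges: np.ndarray  # closed-bin edges, 1500..15400 step 100
    counts: np.ndarray  # 139 closed bins + 1 open bin
    yields: np.ndarray

    def frame(self) -> pd.DataFrame:
        labels = [
            f"{int(self.edges[i])}-{int(self.edges[i + 1])}"
            for i in range(len(self.edges) - 1)
        ] + [f">{int(self.edges[-1])}"]
        return pd.DataFrame(
            {"bin": labels, "count": self.counts, "yield_bp": self.yields}
        )


def length_stats(lengths) -> tuple[float, int, LengthStrata]:
    """Median, N50 and the 100 bp length stratification of a read set."""
    arr = np.asarray(lengths)
    if arr.size == 0:
        raise ValueError("empty read set")
    edges = np.arange(STRATA_START, STRATA_LAST + STRATA_STEP, STRATA_STEP)
    idx = np.clip((arr - STRATA_START) // STRATA_STEP, 0, len(edges) - 1).astype(int)
    counts = np.bincount(idx, minlength=len(edges))
    yields = np.bincount(idx, weights=arr, minlength=len(edges)).astype(np.int64)
    return float(np.median(arr)), n50(arr), LengthStrata(edges, counts, yields)


def stratum_of(length: int) -> int:
    """Index of a read length's 100 bp stratum (139 = the open bin)."""
    return int(min((length - STRATA_START) // STRATA_STEP, (STRATA_LAST - STRATA_START) // STRATA_STEP))


# ---------------------------------------------------------------------------
# accumulative shorter/longer coverage curves
# ---------------------------------------------------------------------------


def target_masks(
    genome: GenomeSequences,
    genes: list[GeneModel] | None = None,
    repeats: list[RepeatInterval] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Boolean masks for the three target spaces (genome/gene/repeat)."""
    masks: dict[str, dict[str, np.ndarray]] = {
        "genome": {c: np.ones(len(s), dtype=bool) for c, s in genome.items()}
    }
    if genes is not None:
        m = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
        for g in genes:
            s, e = g.span
            m[g.chrom][s:e] = True
        masks["gene"] = m
    if repeats is not None:
        m = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
        for r in repeats:
            m[r.chrom][r.start : r.end] = True
        masks["repeat"] = m
    return masks


def accumulative_coverage(
    records: list[AlignmentRecord],
    genome: GenomeSequences,
    masks: dict[str, dict[str, np.ndarray]],
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covered fraction of each target space by reads shorter / longer than L.

    ``frac_shorter(L)`` uses reads with length < L, ``frac_longer(L)`` reads
    with length ≥ L (ties go to "longer").  Both are exact interval-union
    fractions, evaluated on a 100 bp grid; shorter is non-decreasing in L
    and longer non-increasing.
    """
    for name, m in masks.items():
        if sum(int(a.sum()) for a in m.values()) == 0:
            raise ValueError(f"empty target space {name!r}")
    if grid is None:
        grid = np.arange(STRATA_START, STRATA_LAST + 2 * STRATA_STEP, STRATA_STEP)
    primaries = [r for r in records if not r.is_supplementary]
    by_len = sorted(primaries, key=lambda r: len(r.read_sequence))
    target_total = {
        name: sum(int(a.sum()) for a in m.values()) for name, m in masks.items()
    }

    def sweep(read_iter, grid_points, reverse: bool):
        """Incrementally add reads, reporting covered counts at each grid L."""
        depth = {c: np.zeros(len(s), dtype=np.int32) for c, s in genome.items()}
        covered = {name: 0 for name in masks}
        out = []
        reads = list(read_iter)
        i = 0
        for L in grid_points:
            if reverse:
                while i < len(reads) and len(reads[i].read_sequence) >= L:
                    _add(reads[i], depth, masks, covered)
                    i += 1
            else:
                while i < len(reads) and len(reads[i].read_sequence) < L:
                    _add(reads[i], depth, masks, covered)
                    i += 1
            out.append(dict(covered))
        return out

    shorter = sweep(by_len, grid, reverse=False)
    longer_rev = sweep(reversed(by_len), grid[::-1], reverse=True)
    longer = longer_rev[::-1]
    rows = []
    for j, L in enumerate(grid):
        row = {"L": int(L)}
        for name in masks:
            row[f"frac_shorter_{name}"] = shorter[j][name] / target_total[name]
            row[f"frac_longer_{name}"] = longer[j][name] / target_total[name]
        rows.append(row)
    return pd.DataFrame(rows)


def _add(rec, depth, masks, covered) -> None:
    arr = depth[rec.chrom]
    for s, e in _record_ref_intervals(rec):
        seg = arr[s:e]
        new = seg == 0
        if new.any():
            for name, m in masks.items():
                covered[name] += int(m[rec.chrom][s:e][new].sum())
        seg += 1


@dataclass
class IntersectionPoint:
    L: int
    frac_shorter: float
    frac_longer: float
    crossed: bool  # False when the curves never actually cross


def intersection_point(curves: pd.DataFrame, target: str = "genome") -> IntersectionPoint:
    """Grid L minimizing |frac_shorter − frac_longer| (ties → smaller L)."""
    fs = curves[f"frac_shorter_{target}"].to_numpy()
    fl = curves[f"frac_longer_{target}"].to_numpy()
    diff = np.abs(fs - fl)
    i = int(np.argmin(diff))  # argmin returns the first (smallest-L) minimum
    sign = np.sign(fs - fl)
    nz = sign[sign != 0]
    crossed = bool(nz.size and (nz.min() < 0 < nz.max()))
    return IntersectionPoint(int(curves["L"].iloc[i]), float(fs[i]), float(fl[i]), crossed)


def per_chromosome_profile(
    records: list[AlignmentRecord],
    genome: GenomeSequences,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Covered fraction per (chromosome position bin × length stratum).

    Shows where reads of each length class land along the chromosome (the
    short-read concentration on chromosome arms in the real data).
    """
    n_strata = (STRATA_LAST - STRATA_START) // STRATA_STEP + 1
    by_stratum: dict[tuple[str, int], list[AlignmentRecord]] = {}
    for rec in records:
        if rec.is_supplementary:
            continue
        st = stratum_of(len(rec.read_sequence))
        by_stratum.setdefault((rec.chrom, st), []).append(rec)
    rows = []
    for chrom, seq in genome.items():
        clen = len(seq)
        edges = np.linspace(0, clen, n_bins + 1).astype(int)
        for st in range(n_strata):
            recs = by_stratum.get((chrom, st))
            if not recs:
                continue
            cov = np.zeros(clen, dtype=bool)
            for rec in recs:
                for s, e in _record_ref_intervals(rec):
                    cov[s:e] = True
            binned = np.add.reduceat(cov.astype(np.int64), edges[:-1])
            widths = np.diff(edges)
            for b in range(n_bins):
                rows.append(
                    {
                        "chrom": chrom,
                        "bin": b,
                        "stratum": st,
                        "covered_frac": binned[b] / widths[b] if widths[b] else 0.0,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "bin", "stratum", "covered_frac"])
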