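"""Per-strand genome coverage and the 100-bp strand-ratio window screen.

Transcribed / unidirectional / bidirectional genome fractions are computed from
merged per-strand read intervals: a base is *transcribed* if covered on either
strand, *bidirectionally transcribed* if covered on both.  The partition
``unidirectional + bidirectional = transcribed`` is exact in base counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_prep import GenomeAssembly, StrandedRead, ValidationError

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge possibly-overlapping half-open intervals into maximal runs."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two sorted disjoint interval lists (two-pointer sweep)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def union_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    return merge_intervals(list(a) + list(b))


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass
class StrandCoverage:
    """Disjoint sorted covered intervals per chromosome, per strand."""

    plus: dict[str, list[Interval]]
    minus: dict[str, list[Interval]]

    def chroms(self) -> set[str]:
        return set(self.plus) | set(self.minus)


@dataclass(frozen=True)
class CoverageSummary:
    transcribed_pct: float
    unidirectional_pct: float
    bidirectional_pct: float
    transcribed_bp: int
    bidirectional_bp: int
    genome_bp: int


@dataclass(frozen=True)
class RatioWindow:
    chrom: str
    start: int
    plus_reads: int
    minus_reads: int
    plus_bp: int
    minus_bp: int
    log2_ratio: float


def per_strand_coverage(
    reads: Iterable[StrandedRead], genome: GenomeAssembly
) -> StrandCoverage:
    """Maximal merged covered intervals per strand; full read spans count."""
    by: dict[str, dict[str, list[Interval]]] = {"+": {}, "-": {}}
    for r in reads:
        size = genome.chrom_sizes.get(r.chrom)
        if size is None:
            raise ValidationError(f"read on unknown chromosome {r.chrom!r}")
        if r.start < 0 or r.end > size:
            raise ValidationError(
                f"read at {r.chrom}:{r.start}-{r.end} beyond chromosome end"
            )
        by[r.strand].setdefault(r.chrom, []).append((r.start, r.end))
    return StrandCoverage(
        plus={c: merge_intervals(v) for c, v in by["+"].items()},
        minus={c: merge_intervals(v) for c, v in by["-"].items()},
    )


def coverage_summary(cov: StrandCoverage, genome: GenomeAssembly) -> CoverageSummary:
    """Genome fractions transcribed on >=1 strand and on both strands."""
    genome_bp = genome.total_length
    if genome_bp == 0:
        raise ValidationError("zero-length genome")
    transcribed = 0
    bidirectional = 0
    for chrom in cov.chroms():
        p = cov.plus.get(chrom, [])
        m = cov.minus.get(chrom, [])
        transcribed += total_length(union_intervals(p, m))
        bidirectional += total_length(intersect_intervals(p, m))
    uni = transcribed - bidirectional
    return CoverageSummary(
        transcribed_pct=100.0 * transcribed / genome_bp,
        unidirectional_pct=100.0 * uni / genome_bp,
        bidirectional_pct=100.0 * bidirectional / genome_bp,
        transcribed_bp=transcribed,
        bidirectional_bp=bidirectional,
        genome_bp=genome_bp,
    )


def bidirectional_intervals(cov: StrandCoverage) -> dict[str, list[Interval]]:
    """Per-chromosome intervals covered on both strands."""
    return {
        c: intersect_intervals(cov.plus.get(c, []), cov.minus.get(c, []))
        for c in cov.chroms()
    }


def strand_ratio_windows(
    reads: Iterable[StrandedRead],
    genome: GenomeAssembly,
    window: int = 100,
    min_total: int = 300,
) -> list[RatioWindow]:
    """Fixed windows where both strands carry reads and one carries >min_total bp.

    A read belongs to the window containing its 5' end.  Windows are anchored
    at multiples of ``window``.  Emitted windows have >=1 read on each strand
    and max per-strand summed read length strictly greater than ``min_total``;
    the reported ratio is log2(plus_reads / minus_reads).
    """
    acc: dict[tuple[str, int], list[int]] = {}
    for r in reads:
        key = (r.chrom, (r.pos5 // window) * window)
        cell = acc.setdefault(key, [0, 0, 0, 0])  # +n, -n, +bp, -bp
        if r.strand == "+":
            cell[0] += 1
            cell[2] += r.length
        else:
            cell[1] += 1
            cell[3] += r.length
    out = []
    for (chrom, start), (pn, mn, pbp, mbp) in sorted(acc.items()):
        if pn >= 1 and mn >= 1 and max(pbp, mbp) > min_total:
            out.append(
                RatioWindow(chrom, start, pn, mn, pbp, mbp, math.log2(pn / mn))
            )
    return out


def write_coverage_bed(cov: StrandCoverage, path_prefix: str) -> None:
    """Write merged covered intervals as one BED file per strand."""
    for strand, data, tag in (("+", cov.plus, "plus"), ("-", cov.minus, "minus")):
        with open(f"{path_prefix}.{tag}.bed", "w") as fh:
            for chrom in sorted(data):
                for s, e in data[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\tcov\t0\t{strand}\n")
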