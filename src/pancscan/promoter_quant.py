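"""RPKM quantification of the four promoter quadrants and metagene profiles.

Each gene's +/-1,000 bp neighbourhood around the (adjusted) TSS is split into
four quadrants: upstream/downstream x sense/antisense, where *sense* means the
read strand equals the gene strand.  Upstream-antisense reads measure the
promoter-associated ncRNA (pancRNA); downstream-sense reads measure the mRNA
promoter activity.  Read membership is by 5'-end position in gene-oriented
half-open windows [-window, 0) and [0, +window), so every read in the
neighbourhood contributes to exactly one quadrant.

RPKM = count / (window_kb * total_mapped / 1e6), with ``total_mapped`` the
library-wide deduplicated read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_prep import GenomeAssembly, StrandedRead, ValidationError
from .peaks_tss import AdjustedGene

QUADRANTS = ("up_antisense", "up_sense", "down_sense", "down_antisense")


class NormalizationError(ValueError):
    """RPKM normalization is undefined (zero mapped reads or empty window)."""


def rpkm(count: int, window: int, total_mapped: int) -> float:
    """Reads per kilobase of window per million mapped reads."""
    if total_mapped <= 0:
        raise NormalizationError("total_mapped must be positive for RPKM")
    if window <= 0:
        raise NormalizationError("window must be positive for RPKM")
    return count / ((window / 1000.0) * (total_mapped / 1e6))


@dataclass(frozen=True)
class PromoterQuant:
    gene_id: str
    counts: dict[str, int]
    rpkms: dict[str, float]
    total_mapped: int
    window: int = 1000
    clipped: bool = False

    @property
    def up_antisense_rpkm(self) -> float:
        return self.rpkms["up_antisense"]

    @property
    def up_sense_rpkm(self) -> float:
        return self.rpkms["up_sense"]

    @property
    def down_sense_rpkm(self) -> float:
        return self.rpkms["down_sense"]

    @property
    def down_antisense_rpkm(self) -> float:
        return self.rpkms["down_antisense"]


def _oriented_windows(strand: str, tss: int, window: int) -> dict[str, tuple[int, int]]:
    """Genomic half-open [start, end) intervals of the gene-oriented windows.

    Gene-oriented relative coordinates: the TSS base itself is position 0 of
    the downstream window; upstream spans [-window, 0).
    """
    if strand == "+":
        return {"up": (tss - window, tss), "down": (tss, tss + window)}
    return {"up": (tss + 1, tss + 1 + window), "down": (tss - window + 1, tss + 1)}


def quantify_promoter(
    gene: AdjustedGene,
    reads: Iterable[StrandedRead],
    total_mapped: int,
    window: int = 1000,
    genome: GenomeAssembly | None = None,
) -> PromoterQuant:
    """Count reads by 5' end in the four quadrants and normalize by RPKM.

    Windows truncated by a chromosome edge (when ``genome`` is supplied) are
    clipped; the actual clipped width feeds the RPKM denominator and the
    result is flagged.
    """
    g = gene.gene
    wins = _oriented_windows(g.strand, gene.adjusted_tss, window)
    widths = {}
    clipped = False
    for k, (s, e) in wins.items():
        if genome is not None:
            size = genome.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValidationError(f"gene {g.gene_id} on unknown chromosome")
            cs, ce = max(0, s), min(size, e)
            if (cs, ce) != (s, e):
                clipped = True
            wins[k] = (cs, ce)
        widths[k] = max(0, wins[k][1] - wins[k][0])

    counts = {q: 0 for q in QUADRANTS}
    for r in reads:
        if r.chrom != g.chrom:
            continue
        sense = "sense" if r.strand == g.strand else "antisense"
        if wins["up"][0] <= r.pos5 < wins["up"][1]:
            counts[f"up_{sense}"] += 1
        elif wins["down"][0] <= r.pos5 < wins["down"][1]:
            counts[f"down_{sense}"] += 1
    rpkms = {}
    for q in QUADRANTS:
        w = widths["up" if q.startswith("up") else "down"]
        if w == 0:
            raise NormalizationError(
                f"gene {g.gene_id}: promoter window fully outside chromosome"
            )
        rpkms[q] = rpkm(counts[q], w, total_mapped)
    return PromoterQuant(g.gene_id, counts, rpkms, total_mapped, window, clipped)


def quantify_all(
    genes: Sequence[AdjustedGene],
    reads: Sequence[StrandedRead],
    total_mapped: int | None = None,
    window: int = 1000,
    genome: GenomeAssembly | None = None,
) -> list[PromoterQuant]:
    """Quantify every gene; indexes reads per chromosome for speed."""
    if total_mapped is None:
        total_mapped = len(reads)
    by_chrom: dict[str, list[StrandedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    # sort by pos5 so each gene only scans its neighbourhood
    index: dict[str, tuple[np.ndarray, list[StrandedRead]]] = {}
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.pos5)
        index[chrom] = (np.array([r.pos5 for r in rs]), rs)
    out = []
    for gene in genes:
        chrom = gene.gene.chrom
        if chrom in index:
            pos, rs = index[chrom]
            t = gene.adjusted_tss
            lo = int(np.searchsorted(pos, t - window - 1))
            hi = int(np.searchsorted(pos, t + window + 1))
            nearby: Sequence[StrandedRead] = rs[lo:hi]
        else:
            nearby = []
        out.append(
            quantify_promoter(gene, nearby, total_mapped, window, genome)
        )
    return out


@dataclass
class MetageneProfile:
    """Mean read 5'-end counts per bin around aligned TSSs, per gene."""

    bin_edges: np.ndarray  # gene-oriented bin starts relative to the TSS
    sense_values: np.ndarray
    antisense_values: np.ndarray
    n_genes: int
    n_reads: int = 0

    def total_mass(self) -> float:
        return float((self.sense_values.sum() + self.antisense_values.sum()))


def metagene_profile(
    genes: Sequence[AdjustedGene],
    reads: Sequence[StrandedRead],
    bin: int = 100,
    span: int = 1000,
) -> MetageneProfile:
    """Per-gene-normalized distribution of read 5' ends around adjusted TSSs.

    Reads whose 5' end falls in [-span, +span) of a gene's adjusted TSS are
    binned in gene orientation.  Reads recorded as TSS-adjustment evidence
    (same strand, 5' end equal to a coordinate in ``adjustment_reads``) are
    excluded, so the adjustment itself cannot manufacture a peak at 0.
    """
    if not genes:
        raise ValidationError("metagene profile of an empty gene set")
    n_bins = (2 * span) // bin
    edges = np.arange(-span, span, bin)
    sense = np.zeros(n_bins)
    anti = np.zeros(n_bins)
    by_chrom: dict[str, list[StrandedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: r.pos5)
    index = {
        c: (np.array([r.pos5 for r in rs]), rs) for c, rs in by_chrom.items()
    }
    n_included = 0
    for gene in genes:
        g = gene.gene
        if g.chrom not in index:
            continue
        pos, rs = index[g.chrom]
        t = gene.adjusted_tss
        lo = int(np.searchsorted(pos, t - span, side="left"))
        hi = int(np.searchsorted(pos, t + span, side="right"))
        excluded = set(gene.adjustment_reads)
        for r in rs[lo:hi]:
            d = r.pos5 - t if g.strand == "+" else t - r.pos5
            if not (-span <= d < span):
                continue
            if r.strand == g.strand and r.pos5 in excluded:
                continue
            b = (d + span) // bin
            if r.strand == g.strand:
                sense[b] += 1
            else:
                anti[b] += 1
            n_included += 1
    return MetageneProfile(
        edges, sense / len(genes), anti / len(genes), len(genes), n_included
    )
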