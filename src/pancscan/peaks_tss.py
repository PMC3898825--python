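"""Transcript-enrichment detection, TSS adjustment, and minus-plus pitches.

The enrichment detector is a fixed-bin Poisson scan: 5'-end read counts in
fixed genomic bins are tested against a genome-wide Poisson background with
Benjamini-Hochberg control of the false discovery rate, and significant bins
closer than a merge gap are joined into regions.  It plays the role a generic
peak caller plays in TSS-adjustment workflows, but is fully specified and has
no randomness.

Annotated TSSs are replaced by the 5' end of a nearby enriched region on the
gene's strand (within +/-1,000 bp of the annotation), correcting annotation
drift.  A "minus-plus pitch" is a divergent adjacency in sorted genomic order
-- a minus-strand region immediately followed by a plus-strand one with 5'
ends within 2,000 bp -- whose boundary marks a candidate bidirectional
promoter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_prep import GeneModel, GenomeAssembly, StrandedRead

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichedRegion:
    chrom: str
    strand: str
    start: int
    end: int  # half-open
    five_prime_end: int
    read_count: int


@dataclass(frozen=True)
class AdjustedGene:
    gene: GeneModel
    adjusted_tss: int
    adjustment_source: str  # 'peak' or 'reference'
    adjustment_reads: tuple[int, ...] = ()  # 5' coordinates used for adjustment

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


@dataclass(frozen=True)
class PitchPair:
    minus_region: EnrichedRegion
    plus_region: EnrichedRegion
    gap: int


def benjamini_hochberg(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean mask of discoveries under the BH step-up procedure."""
    m = len(pvalues)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(pvalues, kind="stable")
    ranked = pvalues[order]
    thresh = alpha * (np.arange(1, m + 1) / m)
    passing = np.nonzero(ranked <= thresh)[0]
    keep = np.zeros(m, dtype=bool)
    if passing.size:
        keep[order[: passing[-1] + 1]] = True
    return keep


def call_enriched_regions(
    reads: Iterable[StrandedRead],
    genome: GenomeAssembly,
    strand: str,
    bin: int = 50,
    fdr: float = 0.05,
    merge_gap: int = 100,
    min_region_reads: int = 5,
) -> list[EnrichedRegion]:
    """Strand-specific read-enrichment regions from a Poisson bin scan.

    Bins of ``bin`` bp whose 5'-end read count is in the Poisson upper tail
    (lambda = genome-wide mean count per bin on this strand) survive BH-FDR
    control at ``fdr`` across all occupied bins, and are merged when their
    spans are <= ``merge_gap`` bp apart.  Each region is tightened to the
    extreme member 5' ends and reports its strand-aware 5' end (minimum
    member position for '+', maximum for '-').
    """
    by_chrom: dict[str, list[int]] = {}
    n_reads = 0
    for r in reads:
        if r.strand != strand:
            continue
        by_chrom.setdefault(r.chrom, []).append(r.pos5)
        n_reads += 1
    if n_reads == 0:
        log.warning("no mapped reads on strand %s; no regions called", strand)
        return []

    total_bins = sum(-(-size // bin) for size in genome.chrom_sizes.values())
    lam = n_reads / total_bins

    # collect occupied bins and their counts across chromosomes
    bins: list[tuple[str, int, int]] = []  # (chrom, bin_index, count)
    for chrom, positions in by_chrom.items():
        pos = np.asarray(positions)
        idx, counts = np.unique(pos // bin, return_counts=True)
        bins.extend((chrom, int(i), int(c)) for i, c in zip(idx, counts))

    counts = np.array([c for _, _, c in bins])
    pvals = stats.poisson.sf(counts - 1, lam)
    keep = benjamini_hochberg(pvals, fdr)

    regions: list[EnrichedRegion] = []
    sig_by_chrom: dict[str, list[int]] = {}
    for (chrom, i, _c), k in zip(bins, keep):
        if k:
            sig_by_chrom.setdefault(chrom, []).append(i)
    for chrom, sig in sig_by_chrom.items():
        sig.sort()
        positions = np.sort(np.asarray(by_chrom[chrom]))
        runs: list[tuple[int, int]] = []  # bin spans as [start_bp, end_bp)
        for i in sig:
            s, e = i * bin, (i + 1) * bin
            if runs and s - runs[-1][1] <= merge_gap:
                runs[-1] = (runs[-1][0], e)
            else:
                runs.append((s, e))
        for s, e in runs:
            lo = np.searchsorted(positions, s, side="left")
            hi = np.searchsorted(positions, e, side="left")
            member = positions[lo:hi]
            if member.size < min_region_reads:
                continue
            start = int(member.min())
            end = int(member.max()) + 1
            fpe = start if strand == "+" else end - 1
            regions.append(
                EnrichedRegion(chrom, strand, start, end, fpe, int(member.size))
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def adjust_tss(
    gene: GeneModel,
    regions: Sequence[EnrichedRegion],
    window: int = 1000,
) -> AdjustedGene:
    """Move the annotated TSS to the furthest-upstream qualifying region 5' end.

    Candidates are 5' ends of same-strand, same-chromosome regions within
    +/-``window`` bp of the annotated TSS.  Among candidates the one furthest
    upstream in gene orientation wins: a transcript's start is its 5'-most
    point, so enrichment fragments downstream of it are gene body, not the
    TSS.  With no candidate the reference TSS stands.
    """
    candidates = [
        r.five_prime_end
        for r in regions
        if r.chrom == gene.chrom
        and r.strand == gene.strand
        and abs(r.five_prime_end - gene.tss) <= window
    ]
    if not candidates:
        return AdjustedGene(gene, gene.tss, "reference")
    chosen = min(candidates) if gene.strand == "+" else max(candidates)
    return AdjustedGene(gene, chosen, "peak", adjustment_reads=(chosen,))


def adjust_all_tss(
    genes: Iterable[GeneModel],
    plus_regions: Sequence[EnrichedRegion],
    minus_regions: Sequence[EnrichedRegion],
    window: int = 1000,
) -> list[AdjustedGene]:
    """Adjust every gene against the regions called on its own strand."""
    by_strand = {"+": plus_regions, "-": minus_regions}
    return [adjust_tss(g, by_strand[g.strand], window) for g in genes]


def detect_pitches(
    plus_regions: Sequence[EnrichedRegion],
    minus_regions: Sequence[EnrichedRegion],
    max_gap: int = 2000,
) -> list[PitchPair]:
    """Divergent minus-then-plus adjacencies with 5' ends within ``max_gap``.

    Regions from both strands are sorted per chromosome by start; each
    adjacent pair with a minus-strand region immediately followed by a
    plus-strand one (no other region between) is emitted when the plus 5'
    end minus the minus 5' end is <= ``max_gap``.  Convergent (plus-then-
    minus) adjacencies are not candidate bidirectional promoters.
    """
    by_chrom: dict[str, list[EnrichedRegion]] = {}
    for r in list(plus_regions) + list(minus_regions):
        by_chrom.setdefault(r.chrom, []).append(r)
    pairs: list[PitchPair] = []
    for chrom in sorted(by_chrom):
        regs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        for a, b in zip(regs, regs[1:]):
            if a.strand == "-" and b.strand == "+":
                gap = b.five_prime_end - a.five_prime_end
                if gap <= max_gap:
                    pairs.append(PitchPair(a, b, gap))
    return pairs
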