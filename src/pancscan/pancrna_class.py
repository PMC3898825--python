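"""pancRNA candidate classification and tissue-specific calls.

A pancRNA candidate is a protein-coding gene whose upstream-antisense window
carries reads, after removing head-to-head (HtH) coding-coding promoters --
divergent protein-coding pairs whose opposite-strand transcription would
contaminate the antisense signal with mRNA.  Candidates are ranked by
upstream-antisense RPKM (mRNA level deliberately ignored), subgrouped by the
position of the antisense signal relative to the TSS (condition 1: upstream-
biased >=5x; condition 2: downstream-biased <=1/2; condition 3: the rest), and
called tissue-specific when the pancRNA RPKM is above 0.3 in one tissue and
below 0.1 in the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .io_prep import GeneModel
from .promoter_quant import PromoterQuant

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PancCandidate:
    gene_id: str
    quant: PromoterQuant
    condition: int
    rank: int


@dataclass(frozen=True)
class TissueComparison:
    gene_id: str
    rpkm_a: float
    rpkm_b: float
    call: str  # 'A_specific', 'B_specific', or 'none'


@dataclass(frozen=True)
class CorrelationResult:
    r: float  # NaN when undefined
    n: int
    reason: str = ""

    @property
    def defined(self) -> bool:
        return self.reason == ""


def filter_hth_coding(
    genes: Sequence[GeneModel], window: int = 1000
) -> list[GeneModel]:
    """Drop protein-coding genes in divergent coding-coding (HtH) pairs.

    A protein-coding gene is removed iff another protein-coding gene on the
    opposite strand of the same chromosome has its TSS within ``window`` bp
    upstream (in the focal gene's orientation) of the focal TSS.  Removal is
    mutual; non-coding neighbours never trigger removal.
    """
    coding = [g for g in genes if g.biotype == "protein_coding"]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    removed: set[str] = set()
    for chrom_genes in by_chrom.values():
        for g in chrom_genes:
            for other in chrom_genes:
                if other.strand == g.strand or other.gene_id == g.gene_id:
                    continue
                d = g.tss - other.tss if g.strand == "+" else other.tss - g.tss
                # other's TSS strictly upstream of g's, within the window
                if 0 < d <= window:
                    removed.add(g.gene_id)
                    removed.add(other.gene_id)
    return [g for g in genes if g.gene_id not in removed]


def rank_candidates(
    quants: Sequence[PromoterQuant], k: int = 100
) -> tuple[list[PromoterQuant], list[PromoterQuant]]:
    """Top-k and bottom-k genes by upstream-antisense (pancRNA) RPKM.

    Ordered descending; ties broken by gene_id lexicographically for
    determinism.  With fewer than ``k`` genes everything is returned (with a
    warning) in both lists.
    """
    ordered = sorted(quants, key=lambda q: (-q.up_antisense_rpkm, q.gene_id))
    if len(ordered) < k:
        log.warning("only %d genes available for top/bottom-%d", len(ordered), k)
    return ordered[:k], ordered[-k:] if len(ordered) >= k else list(ordered)


def assign_condition(
    quant: PromoterQuant, upper: float = 5.0, lower: float = 2.0
) -> int:
    """Subgroup by where the antisense signal sits relative to the TSS.

    Condition 1: upstream antisense RPKM >= ``upper`` x downstream antisense
    RPKM (bounds inclusive; up > 0 with down = 0 is the ratio's limit and is
    condition 1).  Condition 2: upstream <= downstream / ``lower``.  Condition
    3: neither (including up = down = 0).  Scale-invariant by construction.
    """
    up = quant.up_antisense_rpkm
    down = quant.down_antisense_rpkm
    if up == 0.0 and down == 0.0:
        return 3
    if up >= upper * down:
        return 1
    if up <= down / lower:
        return 2
    return 3


def classify_candidates(
    quants: Sequence[PromoterQuant], k: int = 100
) -> list[PancCandidate]:
    """Rank all genes by pancRNA RPKM and attach condition labels."""
    ordered = sorted(quants, key=lambda q: (-q.up_antisense_rpkm, q.gene_id))
    return [
        PancCandidate(q.gene_id, q, assign_condition(q), rank)
        for rank, q in enumerate(ordered, 1)
    ]


def call_tissue_specific(
    quant_a: PromoterQuant,
    quant_b: PromoterQuant,
    high: float = 0.3,
    low: float = 0.1,
) -> TissueComparison:
    """Tissue-specific pancRNA call with strict thresholds.

    A_specific iff pancRNA RPKM > ``high`` in tissue A and < ``low`` in tissue
    B; symmetric for B_specific; otherwise 'none'.  Each tissue must have been
    quantified against its own library size.
    """
    if quant_a.gene_id != quant_b.gene_id:
        raise ValueError(
            f"mismatched genes {quant_a.gene_id!r} vs {quant_b.gene_id!r}"
        )
    a, b = quant_a.up_antisense_rpkm, quant_b.up_antisense_rpkm
    if a > high and b < low:
        call = "A_specific"
    elif b > high and a < low:
        call = "B_specific"
    else:
        call = "none"
    return TissueComparison(quant_a.gene_id, a, b, call)


def panc_mrna_correlation(samples: Iterable[PromoterQuant]) -> CorrelationResult:
    """Pearson r between pancRNA and mRNA RPKM for one gene across tissues.

    Pairs (upstream-antisense RPKM, downstream-sense RPKM) across >=3 tissue
    samples of the same gene.  Zero variance in either vector makes the
    coefficient undefined; this is reported as NaN with a reason rather than
    raised.
    """
    panc = []
    mrna = []
    gene_ids = set()
    for q in samples:
        panc.append(q.up_antisense_rpkm)
        mrna.append(q.down_sense_rpkm)
        gene_ids.add(q.gene_id)
    if len(gene_ids) > 1:
        raise ValueError(f"samples span multiple genes: {sorted(gene_ids)}")
    n = len(panc)
    if n < 3:
        raise ValueError(f"need >=3 tissue samples, got {n}")
    if len(set(panc)) == 1 or len(set(mrna)) == 1:
        return CorrelationResult(float("nan"), n, "zero variance in one vector")
    r, _p = stats.pearsonr(panc, mrna)
    return CorrelationResult(float(r), n)
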