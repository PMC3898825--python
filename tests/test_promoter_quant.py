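"""Quadrant counting, RPKM arithmetic, and metagene profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pancscan.io_prep import GeneModel, GenomeAssembly, StrandedRead
from pancscan.peaks_tss import AdjustedGene
from pancscan.promoter_quant import (
    QUADRANTS,
    NormalizationError,
    metagene_profile,
    quantify_all,
    quantify_promoter,
    rpkm,
)

from conftest import random_reads


def adjusted(strand="+", tss=5000, gene_id="g1", chrom="chr1", adj_reads=()):
    end = tss + 2000 if strand == "+" else tss - 2000
    g = GeneModel(gene_id, chrom, strand, tss, end)
    return AdjustedGene(g, tss, "reference", tuple(adj_reads))


# ------------------------------------------------------------ rpkm


def test_rpkm_examples():
    assert rpkm(10, 1000, 10_000_000) == 1.0
    assert rpkm(0, 1000, 5_000_000) == 0.0
    assert rpkm(2, 500, 2_000_000) == 2.0


def test_rpkm_zero_total_rejected():
    with pytest.raises(NormalizationError):
        rpkm(10, 1000, 0)


# ------------------------------------------------------------ quadrants


def test_upstream_antisense_read_counted():
    q = quantify_promoter(
        adjusted("+"), [StrandedRead("chr1", "-", 4800, 50)], total_mapped=1_000_000
    )
    assert q.counts["up_antisense"] == 1
    assert q.up_antisense_rpkm == pytest.approx(1.0)
    assert sum(q.counts.values()) == 1


def test_quadrant_exclusivity_down_sense():
    q = quantify_promoter(
        adjusted("+"), [StrandedRead("chr1", "+", 5200, 50)], total_mapped=1_000_000
    )
    assert q.counts["down_sense"] == 1
    assert sum(q.counts.values()) == 1


def test_minus_gene_upstream_is_numerically_greater():
    q = quantify_promoter(
        adjusted("-"), [StrandedRead("chr1", "+", 5200, 50)], total_mapped=1_000_000
    )
    assert q.counts["up_antisense"] == 1


def test_tss_base_belongs_to_downstream():
    q = quantify_promoter(
        adjusted("+"), [StrandedRead("chr1", "+", 5000, 50)], total_mapped=1_000_000
    )
    assert q.counts["down_sense"] == 1
    q = quantify_promoter(
        adjusted("-"), [StrandedRead("chr1", "-", 5000, 50)], total_mapped=1_000_000
    )
    assert q.counts["down_sense"] == 1


def test_edge_clipping_flagged_and_width_used():
    genome = GenomeAssembly({"chr1": 100_000})
    g = adjusted("+", tss=400)
    q = quantify_promoter(
        g, [StrandedRead("chr1", "-", 399, 50)], total_mapped=1_000_000, genome=genome
    )
    assert q.clipped
    # upstream window clipped to [0, 400): width 400
    assert q.counts["up_antisense"] == 1
    assert q.up_antisense_rpkm == pytest.approx(1 / (0.4 * 1.0))


def test_window_fully_outside_chromosome_rejected():
    genome = GenomeAssembly({"chr1": 100_000})
    g = adjusted("-", tss=100_500)  # malformed adjustment: downstream window empty
    g = AdjustedGene(g.gene, 100_500 + 1000, "reference")
    with pytest.raises(NormalizationError):
        quantify_promoter(g, [], total_mapped=1_000_000, genome=genome)


def brute_force_quadrants(gene, reads, window=1000):
    """Direct gene-oriented relative-coordinate classification."""
    counts = {q: 0 for q in QUADRANTS}
    g = gene.gene
    for r in reads:
        if r.chrom != g.chrom:
            continue
        rel = r.pos5 - gene.adjusted_tss if g.strand == "+" else gene.adjusted_tss - r.pos5
        sense = "sense" if r.strand == g.strand else "antisense"
        if -window <= rel < 0:
            counts[f"up_{sense}"] += 1
        elif 0 <= rel < window:
            counts[f"down_{sense}"] += 1
    return counts


@given(st.integers(0, 10_000))
@settings(derandomize=True, max_examples=50)
def test_counts_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    genome = GenomeAssembly({"chr1": 12_000})
    reads = random_reads(rng, genome, 150)
    strand = "+" if rng.random() < 0.5 else "-"
    gene = adjusted(strand, tss=int(rng.integers(2000, 10_000)))
    q = quantify_promoter(gene, reads, total_mapped=len(reads))
    assert q.counts == brute_force_quadrants(gene, reads)


def test_quantify_all_matches_single_gene_calls():
    rng = np.random.default_rng(11)
    genome = GenomeAssembly({"chr1": 50_000})
    reads = random_reads(rng, genome, 400)
    genes = [
        adjusted("+", 5000, "a"),
        adjusted("-", 20_000, "b"),
        adjusted("+", 40_000, "c"),
    ]
    batch = quantify_all(genes, reads, genome=genome)
    for g, q in zip(genes, batch):
        single = quantify_promoter(g, reads, len(reads), genome=genome)
        assert q.counts == single.counts and q.rpkms == single.rpkms


# ------------------------------------------------------------ metagene


def test_metagene_single_read_split_over_two_genes():
    genes = [adjusted("+", 5000, "a"), adjusted("+", 20_000, "b")]
    reads = [StrandedRead("chr1", "+", 5010, 50)]
    prof = metagene_profile(genes, reads)
    i = list(prof.bin_edges).index(0)
    assert prof.sense_values[i] == pytest.approx(0.5)
    assert prof.sense_values.sum() == pytest.approx(0.5)
    assert prof.antisense_values.sum() == 0


def test_metagene_excludes_adjustment_reads():
    genes = [adjusted("+", 5000, "a", adj_reads=(5000,))]
    reads = [StrandedRead("chr1", "+", 5000, 50)]
    prof = metagene_profile(genes, reads)
    assert prof.total_mass() == 0


def test_metagene_mirror_invariance():
    """Flipping the genome left-right and both strands leaves the profile fixed."""
    L = 30_000
    rng = np.random.default_rng(3)
    genes = [adjusted("+", 5000, "a"), adjusted("-", 20_000, "b")]
    reads = random_reads(rng, GenomeAssembly({"chr1": L}), 300)

    def mirror_read(r):
        strand = "-" if r.strand == "+" else "+"
        return StrandedRead(r.chrom, strand, L - 1 - r.pos5, r.length)

    def mirror_gene(a):
        g = a.gene
        strand = "-" if g.strand == "+" else "+"
        gm = GeneModel(g.gene_id, g.chrom, strand, L - 1 - g.tss, L - 1 - g.end)
        return AdjustedGene(gm, L - 1 - a.adjusted_tss, a.adjustment_source)

    p1 = metagene_profile(genes, reads)
    p2 = metagene_profile([mirror_gene(g) for g in genes], [mirror_read(r) for r in reads])
    np.testing.assert_allclose(p1.sense_values, p2.sense_values)
    np.testing.assert_allclose(p1.antisense_values, p2.antisense_values)


def test_metagene_mass_conservation():
    rng = np.random.default_rng(9)
    genome = GenomeAssembly({"chr1": 12_000})
    reads = random_reads(rng, genome, 200)
    genes = [adjusted("+", 6000, "a")]
    prof = metagene_profile(genes, reads)
    in_span = sum(1 for r in reads if -1000 <= r.pos5 - 6000 < 1000)
    assert prof.total_mass() * prof.n_genes == pytest.approx(in_span)
    assert prof.n_reads == in_span


def test_metagene_empty_gene_set_rejected():
    from pancscan.io_prep import ValidationError

    with pytest.raises(ValidationError):
        metagene_profile([], [])
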