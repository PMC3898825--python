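"""Shared fixtures: tiny genomes and random read generators."""

import numpy as np
import pytest

from pancscan.io_prep import GenomeAssembly, StrandedRead


@pytest.fixture
def tiny_genome():
    return GenomeAssembly({"chr1": 1000})


def random_reads(rng, genome, n, read_len=50):
    """Uniform random stranded reads fully inside the genome."""
    reads = []
    chroms = list(genome.chrom_sizes)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        size = genome.chrom_sizes[chrom]
        length = int(rng.integers(20, min(read_len, size) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            pos5 = int(rng.integers(0, size - length + 1))
        else:
            pos5 = int(rng.integers(length - 1, size))
        reads.append(StrandedRead(chrom, strand, pos5, length))
    return reads


def brute_force_summary(reads, genome):
    """Per-base boolean-array coverage summary (independent oracle)."""
    transcribed = 0
    bidirectional = 0
    for chrom, size in genome.chrom_sizes.items():
        plus = np.zeros(size, dtype=bool)
        minus = np.zeros(size, dtype=bool)
        for r in reads:
            if r.chrom != chrom:
                continue
            (plus if r.strand == "+" else minus)[r.start: r.end] = True
        transcribed += int((plus | minus).sum())
        bidirectional += int((plus & minus).sum())
    return transcribed, bidirectional
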