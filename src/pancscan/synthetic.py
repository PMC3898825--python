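"""Synthetic genomes and stranded read sets with planted truth.

The generator emulates the structure of a two-tissue directional RNA-seq
experiment around protein-coding promoters so that every pipeline stage can be
tested closed-loop:

* five planted gene classes -- tissue-A-specific pancRNA-bearing, tissue-B-
  specific pancRNA-bearing, constitutive sense-only, overlapping sense-
  antisense (SAT), and silent;
* Poisson read counts per promoter quadrant with class- and tissue-specific
  rates; pancRNA presence multiplies the mRNA rate (``panc_effect``), so panc
  genes have basal mRNA expression even in the pancRNA-absent tissue;
* GC-rich promoters for pancRNA-bearing genes that satisfy the CpG-island
  criteria, with a (CCG)n run planted in [-100, +100) and a (CGG)n run in
  [+100, +400) of the TSS (gene-oriented); AT-rich promoters elsewhere;
* annotated TSSs offset from the true read start by a uniform shift, so TSS
  adjustment has something to recover;
* a dedicated region tiled with reads on both strands sized to a target
  both-strand genome fraction, plus sparse uniform background on each strand.

Reads carry a 5'-end pile-up at the transcript start (``tss_peak_fraction``
of downstream-sense reads start exactly at the true TSS), reflecting the
sharp 5' boundary of a transcription unit; the remaining read starts are
uniform within their quadrant window.

No generator routine calls analysis code; recovery checks live in tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_prep import GeneModel, GenomeAssembly, StrandedRead, write_fasta

CLASSES = (
    "panc_tissueA",
    "panc_tissueB",
    "constitutive",
    "overlapping_SAT",
    "silent",
)
QUADRANTS = ("up_antisense", "up_sense", "down_sense", "down_antisense")


class SimConfigError(ValueError):
    """The configuration cannot produce a collision-free genome."""


def _default_n_genes() -> dict[str, int]:
    return {
        "panc_tissueA": 40,
        "panc_tissueB": 40,
        "constitutive": 60,
        "overlapping_SAT": 20,
        "silent": 40,
    }


@dataclass
class SimConfig:
    """Study conditions for the simulator (desk scale: ~1 Mb, 200 genes)."""

    seed: int = 0
    genome_length: int = 1_000_000
    chrom: str = "chrS"
    read_length: int = 50
    n_genes: dict[str, int] = field(default_factory=_default_n_genes)
    # per-promoter mean read counts (per quadrant, per tissue)
    panc_rate: float = 20.0  # upstream-antisense rate where the pancRNA is on
    basal_mrna: float = 20.0  # downstream-sense rate without the pancRNA
    panc_effect: float = 3.0  # mRNA multiplier when the pancRNA is expressed
    const_mrna: float = 60.0  # constitutive downstream-sense rate
    sat_rate: float = 50.0  # sense and antisense rates of overlapping SAT genes
    rates: dict | None = None  # optional explicit class -> tissue -> quadrant map
    tss_offset_range: int = 800  # |annotated - true| TSS shift bound (bp)
    tss_peak_fraction: float = 0.25  # downstream-sense reads starting at the TSS
    background_rate: float = 5e-5  # uniform reads per bp per strand
    both_strand_fraction_target: float = 1.0  # % of genome tiled on both strands
    both_strand_depth: int = 50  # per-strand coverage of the tiled region
    window: int = 1000  # promoter quadrant width (bp)
    gene_body: int = 2000  # annotated gene length (bp)
    overdispersion: float = 0.0  # gamma-Poisson mixing; 0 = pure Poisson
    # The simulated chromosome is a slice of a notionally genome-wide library
    # sequenced at realistic per-promoter depth; RPKM is defined against the
    # whole library, so quantification should normalize by this size.  At the
    # default 2e7 mapped reads, a 20-read promoter quadrant is RPKM 1.0.
    library_size: int = 20_000_000

    def quadrant_rates(self, cls: str, tissue: str) -> dict[str, float]:
        """Planted mean read counts for one gene class in one tissue."""
        if self.rates is not None:
            return dict(self.rates[cls][tissue])
        zero = {q: 0.0 for q in QUADRANTS}
        if cls in ("panc_tissueA", "panc_tissueB"):
            on = (cls == "panc_tissueA") == (tissue == "A")
            r = dict(zero)
            r["up_antisense"] = self.panc_rate if on else 0.0
            r["down_sense"] = (
                self.basal_mrna * self.panc_effect if on else self.basal_mrna
            )
            return r
        if cls == "constitutive":
            return {**zero, "down_sense": self.const_mrna}
        if cls == "overlapping_SAT":
            return {**zero, "down_sense": self.sat_rate, "down_antisense": self.sat_rate}
        if cls == "silent":
            return zero
        raise KeyError(f"unknown gene class {cls!r}")


@dataclass
class SimulatedData:
    """A simulated genome with its planted truth."""

    genome: GenomeAssembly
    genes: list[GeneModel]  # annotated models (TSS = true TSS + offset)
    truth: pd.DataFrame  # one row per gene: class, true/annotated TSS, rates
    both_strand_region: tuple[int, int]
    config: SimConfig


def _random_seq(rng: np.random.Generator, n: int, p_gc: float) -> np.ndarray:
    """IID nucleotide array (uint8 ASCII) with the given G+C probability."""
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs
    )


_COMPLEMENT_MAP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT_MAP[a] = b


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT_MAP[arr][::-1]


def _draw_run_units(rng: np.random.Generator) -> int:
    # 1 + Poisson(1.2): mean ~2.2 units, occasional long runs, matching the
    # few-unit scale of promoter trinucleotide repeats
    return int(1 + min(rng.poisson(1.2), 12))


def simulate_genome(config: SimConfig) -> SimulatedData:
    """Deterministic genome + annotation + truth table from a config."""
    rng = np.random.default_rng(config.seed)
    n_total = sum(config.n_genes.get(c, 0) for c in CLASSES)
    L = config.genome_length
    region_len = int(round(config.both_strand_fraction_target / 100.0 * L))
    region = (L - region_len - 2000, L - 2000)
    usable_lo, usable_hi = 5000, region[0] - 5000

    seq = _random_seq(rng, L, p_gc=0.38)

    genes: list[GeneModel] = []
    rows = []
    if n_total > 0:
        spacing = (usable_hi - usable_lo) // n_total
        min_spacing = 2 * config.window + 2 * config.tss_offset_range + 200
        if spacing < min_spacing:
            raise SimConfigError(
                f"gene spacing {spacing} bp < {min_spacing} bp: promoters of "
                "non-overlapping classes would collide; enlarge the genome or "
                "reduce gene counts"
            )
        labels = [c for c in CLASSES for _ in range(config.n_genes.get(c, 0))]
        rng.shuffle(labels)
        strands = [str(s) for s in rng.choice(np.array(["+", "-"]), size=n_total)]
        for i, (cls, strand) in enumerate(zip(labels, strands)):
            true_tss = usable_lo + i * spacing + spacing // 2
            gid = f"g{i:04d}"
            if cls in ("panc_tissueA", "panc_tissueB"):
                promoter = _random_seq(rng, 2 * config.window, p_gc=0.60)
            else:
                # explicitly AT-rich promoter: the class contrast with the
                # GC-rich pancRNA promoters is categorical, not statistical
                promoter = _random_seq(rng, 2 * config.window, p_gc=0.30)
            if cls in ("panc_tissueA", "panc_tissueB"):
                n_ccg = _draw_run_units(rng)
                off = int(rng.integers(0, 200 - 3 * n_ccg))
                rel = config.window - 100 + off  # [-100, +100) gene-oriented
                promoter[rel: rel + 3 * n_ccg] = np.frombuffer(
                    b"CCG" * n_ccg, dtype=np.uint8
                )
                n_cgg = _draw_run_units(rng)
                off = int(rng.integers(0, 300 - 3 * n_cgg))
                rel = config.window + 100 + off  # [+100, +400)
                promoter[rel: rel + 3 * n_cgg] = np.frombuffer(
                    b"CGG" * n_cgg, dtype=np.uint8
                )
            if strand == "+":
                s = true_tss - config.window
                seq[s: s + 2 * config.window] = promoter
            else:
                s = true_tss - config.window + 1
                seq[s: s + 2 * config.window] = _revcomp_arr(promoter)
            offset = int(
                rng.integers(-config.tss_offset_range, config.tss_offset_range + 1)
            ) if config.tss_offset_range > 0 else 0
            ann_tss = true_tss + offset
            if strand == "+":
                end = ann_tss + config.gene_body
            else:
                end = ann_tss - config.gene_body
            genes.append(GeneModel(gid, config.chrom, strand, ann_tss, end))
            row = {
                "gene_id": gid,
                "cls": cls,
                "chrom": config.chrom,
                "strand": strand,
                "true_tss": true_tss,
                "annotated_tss": ann_tss,
            }
            for tissue in ("A", "B"):
                for q, v in config.quadrant_rates(cls, tissue).items():
                    row[f"rate_{tissue}_{q}"] = v
            rows.append(row)

    truth = pd.DataFrame(
        rows,
        columns=["gene_id", "cls", "chrom", "strand", "true_tss", "annotated_tss"]
        + [f"rate_{t}_{q}" for t in ("A", "B") for q in QUADRANTS],
    )
    genome = GenomeAssembly(
        {config.chrom: L}, {config.chrom: seq.tobytes().decode()}
    )
    return SimulatedData(genome, genes, truth, region, config)


def _draw_count(rng: np.random.Generator, rate: float, overdispersion: float) -> int:
    if rate <= 0:
        return 0
    if overdispersion > 0:
        rate = rng.gamma(1.0 / overdispersion, rate * overdispersion)
    return int(rng.poisson(rate))


def _quadrant_reads(
    rng: np.random.Generator,
    config: SimConfig,
    chrom: str,
    strand: str,
    true_tss: int,
    quadrant: str,
    count: int,
) -> list[StrandedRead]:
    """Reads for one promoter quadrant of one gene, in genomic coordinates."""
    w = config.window
    rl = config.read_length
    upstream = quadrant.startswith("up")
    sense = quadrant.endswith("sense") and not quadrant.endswith("antisense")
    read_strand = strand if sense else ("-" if strand == "+" else "+")
    rels = rng.integers(-w, 0, size=count) if upstream else rng.integers(0, w, size=count)
    if quadrant == "down_sense" and config.tss_peak_fraction > 0:
        # the transcript's 5' boundary: after 5'-end deduplication a cap
        # pile-up survives as a contiguous run of occupied start positions,
        # so the peak is planted as distinct consecutive starts from the TSS
        n_peak = min(int(round(config.tss_peak_fraction * count)), count)
        if n_peak:
            rels[:n_peak] = np.arange(n_peak)
    out = []
    L = config.genome_length
    for rel in rels:
        pos5 = true_tss + int(rel) if strand == "+" else true_tss - int(rel)
        # keep the covered interval inside the chromosome
        if read_strand == "+":
            pos5 = min(max(pos5, 0), L - rl)
        else:
            pos5 = min(max(pos5, rl - 1), L - 1)
        out.append(StrandedRead(chrom, read_strand, pos5, rl))
    return out


def simulate_reads(
    config: SimConfig,
    tissue: str,
    sim: SimulatedData,
    gene_rates: Mapping[str, Mapping[str, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> list[StrandedRead]:
    """One tissue's stranded read set (gene reads + background + tiled region).

    ``gene_rates`` optionally overrides the per-gene quadrant rates (keyed by
    gene id); by default the class/tissue rates from the config are used.
    The returned reads are *not* deduplicated -- that is the pipeline's job.
    """
    if tissue not in ("A", "B") and gene_rates is None:
        raise ValueError("tissue must be 'A' or 'B' unless gene_rates is given")
    if rng is None:
        rng = np.random.default_rng([config.seed, 7 if tissue == "A" else 11])
    reads: list[StrandedRead] = []
    for row in sim.truth.itertuples(index=False):
        if gene_rates is not None:
            rates = gene_rates.get(row.gene_id, {})
        else:
            rates = {
                q: getattr(row, f"rate_{tissue}_{q}") for q in QUADRANTS
            }
        for q in QUADRANTS:
            n = _draw_count(rng, rates.get(q, 0.0), config.overdispersion)
            if n:
                reads.extend(
                    _quadrant_reads(
                        rng, config, row.chrom, row.strand, row.true_tss, q, n
                    )
                )
    # sparse uniform background, each strand independently
    L = config.genome_length
    rl = config.read_length
    for strand in ("+", "-"):
        n_bg = int(rng.poisson(config.background_rate * L))
        lo, hi = (0, L - rl) if strand == "+" else (rl - 1, L - 1)
        for pos5 in rng.integers(lo, hi + 1, size=n_bg):
            reads.append(StrandedRead(config.chrom, strand, int(pos5), rl))
    # dedicated both-strand region: deterministic tiling at the target depth
    s, e = sim.both_strand_region
    if e > s:
        step = max(1, rl // config.both_strand_depth)
        for left in range(s, e - rl + 1, step):
            reads.append(StrandedRead(config.chrom, "+", left, rl))
            reads.append(StrandedRead(config.chrom, "-", left + rl - 1, rl))
    return reads


def simulate_coupled_panel(
    config: SimConfig,
    n_tissues: int = 12,
) -> tuple[SimulatedData, list[list[StrandedRead]], pd.DataFrame]:
    """A multi-tissue panel where pancRNA activity drives the mRNA rate.

    For each pancRNA-class gene and each tissue, the pancRNA rate is drawn
    uniformly in [0, 2 * panc_rate] and the mRNA rate follows the coupling
    mRNA = basal * (1 + (panc_effect - 1) * panc / panc_rate); other classes
    keep their constitutive rates.  Returns the genome, one read set per
    tissue, and the planted per-gene per-tissue rate table.  The panel
    isolates expression coupling, so configs passed here should use
    ``tss_offset_range = 0``.
    """
    sim = simulate_genome(config)
    rng = np.random.default_rng([config.seed, 101])
    rows = []
    per_tissue_reads = []
    variable = set(
        sim.truth.loc[
            sim.truth.cls.isin(["panc_tissueA", "panc_tissueB"]), "gene_id"
        ]
    )
    for t in range(n_tissues):
        gene_rates: dict[str, dict[str, float]] = {}
        for row in sim.truth.itertuples(index=False):
            if row.gene_id in variable:
                panc = float(rng.uniform(0, 2 * config.panc_rate))
                mrna = config.basal_mrna * (
                    1 + (config.panc_effect - 1) * panc / config.panc_rate
                )
                gene_rates[row.gene_id] = {
                    "up_antisense": panc,
                    "up_sense": 0.0,
                    "down_sense": mrna,
                    "down_antisense": 0.0,
                }
            else:
                gene_rates[row.gene_id] = config.quadrant_rates(row.cls, "A")
            rows.append(
                {
                    "tissue": t,
                    "gene_id": row.gene_id,
                    "panc_rate": gene_rates[row.gene_id]["up_antisense"],
                    "mrna_rate": gene_rates[row.gene_id]["down_sense"],
                }
            )
        per_tissue_reads.append(
            simulate_reads(config, "panel", sim, gene_rates=gene_rates, rng=rng)
        )
    return sim, per_tissue_reads, pd.DataFrame(rows)


def write_outputs(
    sim: SimulatedData,
    reads_by_tissue: Mapping[str, Sequence[StrandedRead]],
    outdir: str | Path,
) -> None:
    """FASTA, BED12 annotation, per-tissue BED6 reads, truth TSV, config echo."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome.sequence, outdir / "genome.fa")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in sim.genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with open(outdir / "annotation.bed", "w") as fh:
        for g in sim.genes:
            left, right = g.left, g.right
            fh.write(
                f"{g.chrom}\t{left}\t{right}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{left}\t{right}\t0\t1\t{right - left},\t0,\n"
            )
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    from .io_prep import write_bed6

    for tissue, reads in reads_by_tissue.items():
        write_bed6(reads, outdir / f"reads_{tissue}.bed")
    cfg = asdict(sim.config)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
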