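"""Input handling: read trimming, 5'-end deduplication, and format adapters.

All genomic coordinates are 0-based half-open internally.  A stranded read is
keyed by the genomic coordinate of its 5'-most base (``pos5``): for a plus-strand
read this is the leftmost base, for a minus-strand read the rightmost.  This
5'-end keying is used consistently downstream (deduplication, window membership,
promoter quantification), because the biological signal of interest is where
transcripts *start*, not which bases they cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")


class MalformedRecordError(ValueError):
    """A record violates its format contract (named in the message)."""


class ValidationError(ValueError):
    """Input data violates an invariant (coordinates, strands, duplicates)."""


# ---------------------------------------------------------------------------
# raw reads and trimming
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawRead:
    """An unmapped sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise MalformedRecordError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


def trim_reads(
    reads: Iterable[RawRead],
    qual_min: int = 20,
    max_len: int = 50,
    min_len: int = 20,
    mode: str = "first_low",
) -> Iterator[RawRead]:
    """Quality-trim reads from the 3' end and enforce length bounds.

    The retained span never contains a base below ``qual_min`` (Phred 20 =
    99% accuracy).  Two trimming behaviours are offered:

    * ``first_low`` (default): truncate at the 5'-most base with quality below
      ``qual_min``, keeping the prefix before it.  Guarantees a clean span.
    * ``trailing``: strip only the maximal low-quality suffix; internal
      low-quality bases then still cause truncation at the first one so the
      post-condition holds (equivalent to ``first_low`` unless the read ends
      in a low-quality run preceded only by good bases).

    Surviving reads are then capped at ``max_len`` from the 3' end and dropped
    if shorter than ``min_len``.  Adaptor clipping is assumed done upstream.
    """
    if mode not in ("first_low", "trailing"):
        raise ValueError(f"unknown trim mode {mode!r}")
    for read in reads:
        quals = read.qualities
        if mode == "trailing":
            end = len(quals)
            while end > 0 and quals[end - 1] < qual_min:
                end -= 1
            quals = quals[:end]
        cut = len(quals)
        for i, q in enumerate(quals):
            if q < qual_min:
                cut = i
                break
        cut = min(cut, max_len)
        if cut < min_len:
            continue
        yield RawRead(read.id, read.sequence[:cut], read.qualities[:cut])


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a FASTQ file as :class:`RawRead` records (Biopython parser)."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield RawRead(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> int:
    """Write reads to FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# mapped stranded reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class StrandedRead:
    """A mapped read keyed by the genomic coordinate of its 5'-most base."""

    chrom: str
    strand: str  # '+' or '-'
    pos5: int
    length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.length < 1:
            raise ValidationError(f"non-positive read length {self.length}")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the covered interval (inclusive)."""
        return self.pos5 if self.strand == "+" else self.pos5 - self.length + 1

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate, exclusive."""
        return self.pos5 + self.length if self.strand == "+" else self.pos5 + 1

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.chrom, self.strand, self.pos5)


def deduplicate(reads: Iterable[StrandedRead]) -> list[StrandedRead]:
    """Collapse reads sharing a (chrom, strand, 5'-position) key to one read.

    The retained representative is the longest read at the key; ties keep the
    first encountered.  The output is sorted by (chrom, pos5, strand), so the
    operation is idempotent and deterministic.
    """
    best: dict[tuple[str, str, int], StrandedRead] = {}
    for r in reads:
        cur = best.get(r.key)
        if cur is None or r.length > cur.length:
            best[r.key] = r
    out = sorted(best.values(), key=lambda r: (r.chrom, r.pos5, r.strand))
    return out


def read_bed6(path: str | Path) -> list[StrandedRead]:
    """Load read 5'-intervals from a BED6 file (chrom start end name score strand)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}"
                )
            chrom, start, end, _name, _score, strand = fields[:6]
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise ValidationError(f"{path}:{lineno}: empty interval")
            pos5 = start_i if strand == "+" else end_i - 1
            reads.append(StrandedRead(chrom, strand, pos5, end_i - start_i))
    return reads


def write_bed6(reads: Iterable[StrandedRead], path: str | Path) -> int:
    """Write reads as BED6; names are sequential, score is read length."""
    n = 0
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t{r.length}\t{r.strand}\n"
            )
            n += 1
    return n


def read_bam(path: str | Path) -> list[StrandedRead]:
    """Adapter for coordinate-sorted BAM/SAM of mapped reads (pysam)."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path)) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            length = aln.reference_length or aln.query_length
            pos5 = aln.reference_start if strand == "+" else aln.reference_end - 1
            reads.append(StrandedRead(aln.reference_name, strand, pos5, length))
    return reads


# ---------------------------------------------------------------------------
# gene models and genome assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene with its strand-aware transcription start site.

    ``tss`` is the 0-based coordinate of the 5'-most transcribed base in gene
    orientation: the interval start for '+' genes, interval end - 1 for '-'
    genes (so for minus-strand genes ``tss > end`` numerically).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in ("protein_coding", "other"):
            raise ValidationError(
                f"gene {self.gene_id}: biotype must be protein_coding or other"
            )

    @property
    def left(self) -> int:
        return min(self.tss, self.end)

    @property
    def right(self) -> int:
        return max(self.tss, self.end) + (0 if self.strand == "+" else 1)


def _gene_from_bed_fields(fields: Sequence[str], lineno: int, path: str) -> GeneModel:
    chrom, start, end, name, _score, strand = fields[:6]
    start_i, end_i = int(start), int(end)
    if strand not in ("+", "-"):
        raise ValidationError(f"{path}:{lineno}: unknown strand {strand!r}")
    if end_i <= start_i:
        raise ValidationError(f"{path}:{lineno}: empty gene interval")
    tss = start_i if strand == "+" else end_i - 1
    other_end = end_i if strand == "+" else start_i
    return GeneModel(name, chrom, strand, tss, other_end)


def load_genes(
    path: str | Path,
    format: str = "bed12",
    chrom_sizes: Mapping[str, int] | None = None,
    biotype: str = "protein_coding",
) -> list[GeneModel]:
    """Load gene models from BED12/BED6 or GTF.

    TSS is derived from strand (start for '+', end-1 for '-').  Duplicate gene
    ids are rejected; coordinates outside a supplied ``chrom_sizes`` mapping
    raise a :class:`ValidationError` naming the line.
    """
    genes: list[GeneModel] = []
    if format in ("bed12", "bed6", "bed"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise MalformedRecordError(
                        f"{path}:{lineno}: expected >=6 BED columns"
                    )
                g = _gene_from_bed_fields(fields, lineno, str(path))
                genes.append(
                    GeneModel(g.gene_id, g.chrom, g.strand, g.tss, g.end, biotype)
                )
                if chrom_sizes is not None:
                    size = chrom_sizes.get(g.chrom)
                    if size is None or g.right > size:
                        raise ValidationError(
                            f"{path}:{lineno}: gene {g.gene_id} outside chromosome"
                        )
    elif format == "gtf":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True, disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        for feat in db.features_of_type("gene"):
            if feat.strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}: gene at {feat.seqid}:{feat.start}: unknown strand"
                )
            gid = feat.attributes.get("gene_id", [feat.id])[0]
            # GTF is 1-based inclusive; convert to 0-based half-open
            start0, end0 = feat.start - 1, feat.end
            bt = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
            bt = "protein_coding" if bt == "protein_coding" else "other"
            tss = start0 if feat.strand == "+" else end0 - 1
            other_end = end0 if feat.strand == "+" else start0
            genes.append(GeneModel(gid, feat.seqid, feat.strand, tss, other_end, bt))
    else:
        raise ValueError(f"unknown gene format {format!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicated gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def write_genes_bed6(genes: Iterable[GeneModel], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.left}\t{g.right}\t{g.gene_id}\t0\t{g.strand}\n")
            n += 1
    return n


@dataclass
class GenomeAssembly:
    """Chromosome sizes plus (optionally) the nucleotide sequences."""

    chrom_sizes: dict[str, int]
    sequence: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the top-strand sequence of [start, end), clipped to bounds."""
        seq = self.sequence[chrom]
        return seq[max(0, start): min(len(seq), end)]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls({k: len(v) for k, v in seqs.items()}, seqs)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeAssembly":
        sizes = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
        return cls(sizes)

    def validate_reads(self, reads: Iterable[StrandedRead]) -> None:
        for r in reads:
            size = self.chrom_sizes.get(r.chrom)
            if size is None:
                raise ValidationError(f"read on unknown chromosome {r.chrom!r}")
            if r.start < 0 or r.end > size:
                raise ValidationError(
                    f"read at {r.chrom}:{r.start}-{r.end} outside chromosome"
                )


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
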