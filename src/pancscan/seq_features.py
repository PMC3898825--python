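"""Promoter sequence characterization.

Implements the Gardiner-Garden-Frommer CpG-island definition (length >= 200
bp, G+C fraction > 0.5, observed/expected CpG > 0.6), six/three-frame longest
open-reading-frame scanning, sliding-window hexamer (CCGCCG / CGGCGG)
frequency profiles around TSSs, and maximal in-phase trinucleotide-repeat
run statistics (CCG upstream / CGG downstream of head-to-head promoters).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_prep import GeneModel, GenomeAssembly, ValidationError
from .peaks_tss import AdjustedGene

STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CGIInterval:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float


def cgi_stats(seq: str) -> tuple[float, float]:
    """(GC fraction, observed/expected CpG) of a sequence; N is neither C nor G.

    obs/exp = CpG_count * length / (C_count * G_count); 0 when C or G absent.
    """
    n = len(seq)
    if n == 0:
        return 0.0, 0.0
    c = seq.count("C")
    g = seq.count("G")
    cpg = seq.count("CG")
    gc = (c + g) / n
    oe = (cpg * n / (c * g)) if c and g else 0.0
    return gc, oe


def _window_qualifies(
    c_cum: np.ndarray, g_cum: np.ndarray, cpg_cum: np.ndarray,
    s: int, e: int, min_gc: float, min_oe: float,
) -> bool:
    n = e - s
    c = int(c_cum[e] - c_cum[s])
    g = int(g_cum[e] - g_cum[s])
    # CpG dinucleotides fully inside [s, e)
    cpg = int(cpg_cum[max(e - 1, s)] - cpg_cum[s])
    if (c + g) / n <= min_gc:
        return False
    if c == 0 or g == 0:
        return False
    return cpg * n / (c * g) > min_oe


def find_cgis(
    seq: str,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    chrom: str = "seq",
) -> list[CGIInterval]:
    """CpG islands under the Gardiner-Garden-Frommer criteria.

    Seed windows of ``min_len`` bp at every offset are screened against all
    three criteria; bases covered by any qualifying seed are merged into
    maximal runs, and each run is re-verified as a whole.  A merged run that
    fails re-verification (possible because the criteria are not closed under
    union) is trimmed greedily from whichever end restores the criteria
    fastest until it passes.  Island ends are snapped to C/G bases, so an
    island is anchored to its CpG-rich core: a 198-bp (CG) run embedded in
    A's is rejected by the length criterion rather than rescued by absorbing
    flanking A's into a 200-bp window.
    """
    seq = seq.upper()
    n = len(seq)
    if n < min_len:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cpg = np.zeros(n, dtype=bool)
    if n > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    c_cum = np.concatenate([[0], np.cumsum(is_c)])
    g_cum = np.concatenate([[0], np.cumsum(is_g)])
    cpg_cum = np.concatenate([[0], np.cumsum(is_cpg)])

    w = min_len
    starts = np.arange(0, n - w + 1)
    c_w = c_cum[starts + w] - c_cum[starts]
    g_w = g_cum[starts + w] - g_cum[starts]
    cpg_w = cpg_cum[starts + w - 1] - cpg_cum[starts]
    gc_ok = (c_w + g_w) / w > min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(c_w * g_w > 0, cpg_w * w / np.maximum(c_w * g_w, 1), 0.0)
    qual = gc_ok & (oe > min_oe) & (c_w > 0) & (g_w > 0)

    # merge qualifying seed windows into maximal covered runs
    runs: list[tuple[int, int]] = []
    for s in np.nonzero(qual)[0]:
        s = int(s)
        e = s + w
        if runs and s <= runs[-1][1]:
            runs[-1] = (runs[-1][0], e)
        else:
            runs.append((s, e))

    is_cg = is_c | is_g
    out: list[CGIInterval] = []
    for s, e in runs:
        s, e = _trim_to_valid(
            is_cg, c_cum, g_cum, cpg_cum, s, e, min_len, min_gc, min_oe
        )
        if s is None:
            continue
        gc, oe_v = cgi_stats(seq[s:e])
        out.append(CGIInterval(chrom, s, e, gc, oe_v))
    return out


def _trim_to_valid(is_cg, c_cum, g_cum, cpg_cum, s, e, min_len, min_gc, min_oe):
    """Greedy end-trim until the interval satisfies all three criteria.

    Ends are first snapped inward to the nearest C/G base, anchoring the
    island to its CpG-rich core before each verification step.
    """
    while True:
        while s < e and not is_cg[s]:
            s += 1
        while e > s and not is_cg[e - 1]:
            e -= 1
        if e - s < min_len:
            break
        if _window_qualifies(c_cum, g_cum, cpg_cum, s, e, min_gc, min_oe):
            return s, e
        # drop the end whose flanking min_len window is weaker
        left_ok = _window_qualifies(
            c_cum, g_cum, cpg_cum, s, s + min_len, min_gc, min_oe
        )
        right_ok = _window_qualifies(
            c_cum, g_cum, cpg_cum, e - min_len, e, min_gc, min_oe
        )
        if left_ok and not right_ok:
            e -= 1
        elif right_ok and not left_ok:
            s += 1
        else:
            e -= 1
    return None, None


def load_cgis_bed(path: str) -> list[CGIInterval]:
    """External CpG-island track (BED3+); stats fields set to NaN."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            out.append(
                CGIInterval(
                    fields[0], int(fields[1]), int(fields[2]),
                    float("nan"), float("nan"),
                )
            )
    return out


def promoter_interval(gene: GeneModel, tss: int, span: int = 1000) -> tuple[int, int]:
    """Genomic [start, end) covering [-span, +span) around a TSS, gene-oriented."""
    if gene.strand == "+":
        return tss - span, tss + span
    return tss - span + 1, tss + span + 1


def cgi_overlap_fraction(
    genes: Sequence[AdjustedGene],
    cgis: Sequence[CGIInterval],
    promoter_span: int = 1000,
) -> float:
    """Percent of genes whose promoter overlaps >= 1 bp of a CpG island."""
    if not genes:
        raise ValidationError("empty gene set for CGI overlap")
    by_chrom: dict[str, list[CGIInterval]] = {}
    for c in cgis:
        by_chrom.setdefault(c.chrom, []).append(c)
    n_hit = 0
    for g in genes:
        s, e = promoter_interval(g.gene, g.adjusted_tss, promoter_span)
        for c in by_chrom.get(g.gene.chrom, []):
            if c.start < e and s < c.end:
                n_hit += 1
                break
    return 100.0 * n_hit / len(genes)


# ---------------------------------------------------------------------------
# open reading frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrfResult:
    sequence_id: str
    longest_orf_nt: int
    frame: int  # 0-2 on the scanned strand; -1 when no ORF
    strand_searched: str  # 'given' or 'both'


def _longest_orf_one_strand(seq: str, include_stop: bool) -> tuple[int, int]:
    """(longest ORF length in nt, frame) over the three frames of one strand."""
    best = 0
    best_frame = -1
    for frame in range(3):
        open_start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i: i + 3]
            if codon == "ATG" and open_start is None:
                open_start = i
            elif codon in STOP_CODONS and open_start is not None:
                length = i + 3 - open_start
                if not include_stop:
                    length -= 3
                if length > best:
                    best, best_frame = length, frame
                open_start = None
    return best, best_frame


def longest_orf(
    seq: str,
    strands: str = "given",
    include_stop: bool = True,
    sequence_id: str = "seq",
) -> OrfResult:
    """Longest START..STOP span over 3 frames (6 when ``strands='both'``).

    An ORF begins with ATG and ends with the first in-frame stop codon; the
    reported length is in nucleotides, including the stop codon by default
    (``include_stop=False`` reports the ATG..last-sense-codon span).  Returns
    0 when no complete ORF exists.
    """
    seq = seq.upper()
    best, frame = _longest_orf_one_strand(seq, include_stop)
    if strands == "both":
        rc_best, rc_frame = _longest_orf_one_strand(revcomp(seq), include_stop)
        if rc_best > best:
            best, frame = rc_best, rc_frame
    elif strands != "given":
        raise ValueError(f"strands must be 'given' or 'both', got {strands!r}")
    return OrfResult(sequence_id, best, frame if best else -1, strands)


# ---------------------------------------------------------------------------
# hexamer profiles and repeat runs
# ---------------------------------------------------------------------------


@dataclass
class HexamerProfile:
    motif: str
    window_starts: np.ndarray  # relative to the TSS
    values: np.ndarray  # mean occurrences per sequence per window
    n_sequences: int
    window: int = 100


def count_overlapping(seq: str, motif: str) -> int:
    """Number of (possibly overlapping) occurrences of ``motif`` in ``seq``."""
    n = 0
    i = seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


def _occurrence_starts(seq: str, motif: str) -> list[int]:
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def hexamer_profile(
    seqs: Sequence[str],
    motif: str,
    window: int = 100,
    span: int = 1000,
) -> HexamerProfile:
    """Mean motif-occurrence counts per fixed window around aligned TSSs.

    All sequences must be ``2 * span`` bp, TSS-anchored and gene-oriented
    (position ``span`` in the string is the TSS).  Overlapping occurrences
    are counted; an occurrence belongs to the window containing its start,
    so window sums conserve the total occurrence count.
    """
    if not seqs:
        raise ValidationError("empty sequence set for hexamer profile")
    length = 2 * span
    n_bins = length // window
    counts = np.zeros(n_bins)
    for s in seqs:
        if len(s) != length:
            raise ValidationError(
                f"sequence length {len(s)} != expected {length}"
            )
        for i in _occurrence_starts(s.upper(), motif):
            counts[i // window] += 1
    return HexamerProfile(
        motif,
        np.arange(-span, span, window),
        counts / len(seqs),
        len(seqs),
        window,
    )


def both_hexamer_fraction(
    seqs: Mapping[str, str] | Sequence[str],
    motif_a: str = "CCGCCG",
    motif_b: str = "CGGCGG",
) -> float:
    """Percent of promoters containing at least one of each motif."""
    values = list(seqs.values()) if isinstance(seqs, Mapping) else list(seqs)
    if not values:
        raise ValidationError("empty sequence set")
    n = sum(1 for s in values if motif_a in s.upper() and motif_b in s.upper())
    return 100.0 * n / len(values)


@dataclass(frozen=True)
class RepeatRun:
    unit: str
    start: int
    n_units: int


@dataclass
class RepeatRunStats:
    unit: str
    mean_units: float  # NaN when no runs
    max_units: int
    runs: list[RepeatRun]


def repeat_run_stats(seqs: Iterable[str], unit: str) -> RepeatRunStats:
    """Maximal in-phase tandem runs of a trinucleotide unit, pooled over seqs.

    A run is maximal when it cannot be extended by another copy of the unit in
    the same phase on either side; single occurrences count as runs of one.
    The mean is taken per run over all runs found (interpretation documented
    in the methods note).
    """
    if len(unit) != 3:
        raise ValueError(f"repeat unit must be a trinucleotide, got {unit!r}")
    pat = re.compile(f"(?:{re.escape(unit)})+")
    runs: list[RepeatRun] = []
    for seq in seqs:
        for m in pat.finditer(seq.upper()):
            runs.append(RepeatRun(unit, m.start(), len(m.group()) // 3))
    if not runs:
        return RepeatRunStats(unit, float("nan"), 0, runs)
    counts = [r.n_units for r in runs]
    return RepeatRunStats(unit, sum(counts) / len(counts), max(counts), runs)


def extract_promoters(
    genome: GenomeAssembly,
    genes: Sequence[AdjustedGene],
    span: int = 1000,
) -> dict[str, str]:
    """Gene-oriented +/-span promoter sequences keyed by gene id.

    The returned string reads 5'->3' in gene orientation with the TSS at
    position ``span`` (minus-strand promoters are reverse-complemented).
    Genes whose window runs off the chromosome are skipped.
    """
    out: dict[str, str] = {}
    for g in genes:
        s, e = promoter_interval(g.gene, g.adjusted_tss, span)
        size = genome.chrom_sizes[g.gene.chrom]
        if s < 0 or e > size:
            continue
        seq = genome.fetch(g.gene.chrom, s, e)
        out[g.gene_id] = seq if g.gene.strand == "+" else revcomp(seq)
    return out
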