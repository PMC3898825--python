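# Methods

This note records what each pipeline stage computes and why the
non-obvious design choices were made.  Conventions throughout: 0-based
half-open genomic intervals; a read is represented by the position of its
5′-most base (`pos5`); *sense* means the read strand equals the gene strand.

## Read preparation

Raw reads are quality-trimmed so the retained span contains no base below
Phred 20 (99% base-call accuracy): the read is truncated at the 5′-most
low-quality base, capped at 50 nt from the 3′ end, and dropped below 20 nt.
Mapped reads are deduplicated by their `(chrom, strand, pos5)` key, keeping
the longest read per key.  Keying on the 5′ end rather than the full span
is deliberate: downstream quantification counts *transcript starts*, and a
PCR stack of identical starts should count once.

## Coverage fractions

Per-strand coverage is the union of full read spans, merged into maximal
disjoint intervals.  A base is *transcribed* if covered on either strand
and *bidirectionally transcribed* if covered on both; unidirectional is the
difference, so `unidirectional + bidirectional = transcribed` holds exactly
in base counts, not just within rounding.  A separate 100-bp window screen
reports `log2(plus/minus)` read ratios for windows with reads on both
strands and more than 300 summed read-bp on the dominant strand.

## Enrichment regions and TSS adjustment

A generic peak caller is replaced by a fully specified Poisson scan: 5′-end
counts in fixed 50-bp bins are tested against a genome-wide Poisson rate
(strand reads / total bins), Benjamini–Hochberg-controlled at FDR 0.05
across occupied bins, and significant bins whose spans lie ≤ 100 bp apart
are merged.  Regions are tightened to their extreme member 5′ ends and must
contain ≥ 5 reads.  The region's strand-aware 5′ end is its minimum member
position on `+`, maximum on `-`.

An annotated TSS is adjusted to a region 5′ end on the gene's strand within
±1,000 bp.  When several regions qualify, the **furthest-upstream**
candidate in gene orientation is chosen, not the nearest to the annotation.
Rationale: at moderate depth the Poisson scan fragments one transcript into
several regions along the gene body; nearest-to-annotation then latches
onto a body fragment whenever the annotation drifts downstream, while the
transcript's true start is by definition its 5′-most enrichment.  On
synthetic data with offsets uniform in ±800 bp this rule recovers 100% of
true starts where nearest-to-annotation recovers ~65–75%.

A *minus–plus pitch* is a divergent adjacency in sorted order — a
minus-strand region immediately followed by a plus-strand one with 5′-end
gap ≤ 2,000 bp — marking a candidate bidirectional promoter.

## Promoter quadrants and RPKM

Each gene's ±1 kb TSS neighbourhood splits into four quadrants
(upstream/downstream × sense/antisense) by read 5′-end membership in the
gene-oriented half-open windows `[-1000, 0)` and `[0, +1000)`; the TSS base
is position 0 of the downstream window, and every read in the neighbourhood
lands in exactly one quadrant.  Upstream-antisense measures the pancRNA,
downstream-sense the mRNA promoter activity.

`RPKM = count / (window_kb × total_mapped / 10⁶)`.  Windows clipped by a
chromosome edge use their actual width in the denominator and are flagged.

Metagene profiles bin read 5′ ends around aligned adjusted TSSs,
normalized per gene.  Reads recorded as TSS-adjustment evidence are
excluded from the profile so the adjustment cannot manufacture its own
peak at position 0.

## Classification

Head-to-head coding–coding promoters (divergent protein-coding TSSs within
1 kb) are removed mutually before pancRNA calling, since the opposite
strand's mRNA would contaminate the antisense window.  Candidates are
ranked by upstream-antisense RPKM (ties broken lexicographically by gene
id).  The antisense-position conditions are scale-invariant ratio tests:
condition 1 when upstream ≥ 5 × downstream antisense (including the
`down = 0, up > 0` limit), condition 2 when upstream ≤ downstream / 2,
condition 3 otherwise (including `up = down = 0`).  A pancRNA is
tissue-specific when its RPKM is strictly above 0.3 in one tissue and
strictly below 0.1 in the other.  Coupling between pancRNA and mRNA is
measured as the per-gene Pearson r across ≥ 3 tissue samples; zero-variance
vectors yield an explicit "undefined" result rather than an exception.

## Sequence features

CpG islands follow the Gardiner–Garden–Frommer criteria (length ≥ 200 bp,
GC > 0.5, observed/expected CpG > 0.6 with
`O/E = CpG × length / (C × G)`).  The scan seeds with all 200-bp windows at
1-bp step, merges qualifying seeds into maximal runs, and re-verifies each
run as a whole, trimming greedily from the weaker end when a merged run
fails (the criteria are not closed under union).  Island ends are snapped
inward to C/G bases, anchoring each island to its CpG-rich core; a 198-bp
`(CG)` run embedded in A's is therefore rejected by the length criterion
instead of being rescued by 200-bp windows that absorb flanking A's.

ORFs are `ATG … first in-frame stop` spans over three frames (six with
`strands="both"`), reported in nucleotides including the stop codon.
Hexamer profiles count possibly-overlapping motif occurrences in
non-overlapping 100-bp windows across TSS-anchored ±1 kb promoter strings;
an occurrence belongs to the window containing its start, so window sums
conserve total counts and the CCGCCG profile of a set equals the mirrored
CGGCGG profile of its reverse complement.  Repeat statistics report maximal
in-phase runs of a trinucleotide unit; the mean is **per run** over all
runs found (single occurrences count as runs of one), which dilutes
planted long runs with incidental singletons in GC-rich sequence — the
max statistic is the more sensitive recovery check.

## Synthetic data

The generator plants five gene classes (tissue-A pancRNA, tissue-B
pancRNA, constitutive, overlapping sense–antisense, silent) on a 1-Mb
chromosome with per-quadrant Poisson read counts, GC-rich (0.60) promoters
carrying `(CCG)n`/`(CGG)n` runs at pancRNA genes, AT-rich (0.30) promoters
elsewhere, annotated TSSs offset uniformly within ±800 bp of the truth, a
deterministic both-strand tiled region sized to 1% of the genome, and
sparse per-strand background.  pancRNA→mRNA coupling is multiplicative:
`mRNA = basal × (1 + (effect − 1) × panc / panc_rate)`, so pancRNA genes
keep basal mRNA expression in the tissue where the pancRNA is off.

Two modelling choices matter for interpretation:

* **5′ pile-up representation.**  After 5′-end deduplication a cap-site
  pile-up of identical starts would collapse to a single read and the TSS
  would be undetectable.  The generator therefore plants the transcript's
  5′ boundary as a contiguous run of distinct start positions beginning at
  the true TSS (`tss_peak_fraction` of downstream-sense reads), which is
  exactly the deduplicated footprint of such a pile-up.
* **Library-scale RPKM.**  The simulated chromosome is a slice of a
  notionally genome-wide library (`library_size`, default 2 × 10⁷ mapped
  reads).  Quantification normalizes RPKM against that library size, so a
  planted 20-read promoter quadrant is RPKM 1.0 and the 0.3 / 0.1
  tissue-specificity thresholds operate at the scale they were designed
  for.  Normalizing against the raw slice (~3 × 10⁴ reads) would make a
  single background read RPKM ≈ 34 and reduce the thresholds to a
  1-read-versus-0-reads test.

The generator calls no analysis code; every recovery property is checked
in the test suite.  The planted both-strand fraction is benchmarked with
the overlapping sense–antisense class disabled, because SAT gene overlap
adds a stochastic both-strand contribution that is not part of the fixed
planted truth.

## Scale and limitations

Default problem sizes (1-Mb genome, 200 genes, ~3 × 10⁴ deduplicated reads
per tissue) are chosen so the full pipeline and benchmark run in seconds
on one CPU.  The package does not model splicing, sequencing error, or
cross-species orthology; real-data use expects mapped, adapter-clipped
stranded reads in BED6 or BAM.
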