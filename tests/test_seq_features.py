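"""CpG islands, ORFs, hexamer profiles, and repeat runs."""

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pancscan.io_prep import GeneModel, GenomeAssembly, ValidationError
from pancscan.peaks_tss import AdjustedGene
from pancscan.seq_features import (
    both_hexamer_fraction,
    cgi_overlap_fraction,
    cgi_stats,
    count_overlapping,
    extract_promoters,
    find_cgis,
    hexamer_profile,
    longest_orf,
    promoter_interval,
    repeat_run_stats,
    revcomp,
    CGIInterval,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


# ------------------------------------------------------------ CpG islands


def test_cg_repeat_is_one_perfect_island():
    (isl,) = find_cgis("CG" * 150)
    assert (isl.start, isl.end) == (0, 300)
    assert isl.gc_fraction == pytest.approx(1.0)
    assert isl.obs_exp_cpg == pytest.approx(2.0)


def test_poly_a_has_no_island():
    assert find_cgis("A" * 1000) == []


def test_short_cg_run_fails_length_criterion():
    assert find_cgis("A" * 400 + "CG" * 99 + "A" * 400) == []


def test_islands_reverify_criteria():
    rng = np.random.default_rng(0)
    for _ in range(20):
        # GC-rich noise likely to contain borderline islands
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=2000))
        for isl in find_cgis(seq):
            assert isl.end - isl.start >= 200
            gc, oe = cgi_stats(seq[isl.start: isl.end])
            assert gc > 0.5 and oe > 0.6


def brute_force_qualifying_bases(seq, min_len=200, min_gc=0.5, min_oe=0.6):
    """Bases covered by any qualifying min_len substring (string counting)."""
    covered = set()
    for s in range(len(seq) - min_len + 1):
        w = seq[s: s + min_len]
        c, g = w.count("C"), w.count("G")
        if (c + g) / min_len <= min_gc or c == 0 or g == 0:
            continue
        if w.count("CG") * min_len / (c * g) > min_oe:
            covered.update(range(s, s + min_len))
    return covered


def test_island_seeds_match_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=1500))
        covered = brute_force_qualifying_bases(seq)
        islands = find_cgis(seq)
        # every emitted island lies inside the qualifying-seed cover and is
        # anchored to C/G bases at both ends
        for isl in islands:
            assert set(range(isl.start, isl.end)) <= covered
            assert seq[isl.start] in "CG" and seq[isl.end - 1] in "CG"


def test_sequence_shorter_than_min_len():
    assert find_cgis("CG" * 50) == []


def test_cgi_stats_empty_and_no_cg():
    assert cgi_stats("") == (0.0, 0.0)
    gc, oe = cgi_stats("ATAT")
    assert gc == 0.0 and oe == 0.0


# ------------------------------------------------------------ CGI overlap


def make_adjusted(gene_id, strand, tss, chrom="chr1"):
    end = tss + 2000 if strand == "+" else tss - 2000
    return AdjustedGene(GeneModel(gene_id, chrom, strand, tss, end), tss, "reference")


def test_cgi_overlap_half():
    genes = [make_adjusted("a", "+", 5000), make_adjusted("b", "+", 50_000)]
    cgis = [CGIInterval("chr1", 4500, 4800, 0.6, 0.7)]
    assert cgi_overlap_fraction(genes, cgis) == pytest.approx(50.0)


def test_cgi_overlap_all_and_one_bp_rule():
    genes = [make_adjusted("a", "+", 5000)]
    # promoter [4000, 6000); island ending exactly at 4001 overlaps 1 bp
    cgis = [CGIInterval("chr1", 3800, 4001, 0.6, 0.7)]
    assert cgi_overlap_fraction(genes, cgis) == pytest.approx(100.0)
    cgis = [CGIInterval("chr1", 3800, 4000, 0.6, 0.7)]
    assert cgi_overlap_fraction(genes, cgis) == pytest.approx(0.0)


def test_cgi_overlap_empty_gene_set_rejected():
    with pytest.raises(ValidationError):
        cgi_overlap_fraction([], [])


def test_promoter_interval_orientation():
    plus = GeneModel("a", "c", "+", 5000, 7000)
    minus = GeneModel("b", "c", "-", 5000, 3000)
    assert promoter_interval(plus, 5000, 1000) == (4000, 6000)
    assert promoter_interval(minus, 5000, 1000) == (4001, 6001)


# ------------------------------------------------------------ ORFs


def test_orf_examples():
    assert longest_orf("ATGAAATAG").longest_orf_nt == 9
    assert longest_orf("AAACCC").longest_orf_nt == 0
    assert longest_orf("ATGATGTGA").longest_orf_nt == 9


def test_orf_exclude_stop():
    assert longest_orf("ATGAAATAG", include_stop=False).longest_orf_nt == 6


def test_orf_both_strands():
    # revcomp of ATGAAATAG is CTATTTCAT: ORF only on the reverse strand
    assert longest_orf("CTATTTCAT").longest_orf_nt == 0
    assert longest_orf("CTATTTCAT", strands="both").longest_orf_nt == 9


def brute_force_orf(seq):
    """All-pairs scan: every ATG with its first in-frame stop, max span."""
    best = 0
    for i in range(len(seq) - 2):
        if seq[i: i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j: j + 3] in ("TAA", "TAG", "TGA"):
                best = max(best, j + 3 - i)
                break
    return best


@given(dna)
@settings(derandomize=True, max_examples=150)
def test_orf_matches_brute_force(seq):
    assert longest_orf(seq).longest_orf_nt == brute_force_orf(seq)


@given(dna)
@settings(derandomize=True, max_examples=80)
def test_orf_both_strands_is_max_of_strands(seq):
    fwd = longest_orf(seq).longest_orf_nt
    rev = longest_orf(revcomp(seq)).longest_orf_nt
    assert longest_orf(seq, strands="both").longest_orf_nt == max(fwd, rev)


# ------------------------------------------------------------ hexamers


def test_hexamer_single_occurrence_profile():
    span, window = 1000, 100
    seq = list("A" * 2 * span)
    seq[span + 50: span + 56] = "CCGCCG"
    prof = hexamer_profile(["".join(seq)], "CCGCCG", window, span)
    idx = list(prof.window_starts).index(0)
    assert prof.values[idx] == pytest.approx(1.0)
    assert prof.values.sum() == pytest.approx(1.0)


def test_hexamer_absent_motif_all_zero():
    prof = hexamer_profile(["A" * 2000], "CCGCCG")
    assert prof.values.sum() == 0


def test_hexamer_overlapping_occurrences():
    assert count_overlapping("CCGCCGCCG", "CCGCCG") == 2
    seq = "A" * 1000 + "CCGCCGCCG" + "A" * 991
    prof = hexamer_profile([seq], "CCGCCG")
    idx = list(prof.window_starts).index(0)
    assert prof.values[idx] == pytest.approx(2.0)


def test_hexamer_length_mismatch_rejected():
    with pytest.raises(ValidationError):
        hexamer_profile(["A" * 1999], "CCGCCG")


def test_hexamer_mass_conservation_random():
    rng = np.random.default_rng(2)
    seqs = [
        "".join(rng.choice(list("ACG"), p=[0.2, 0.4, 0.4], size=2000))
        for _ in range(10)
    ]
    prof = hexamer_profile(seqs, "CCGCCG")
    total = sum(count_overlapping(s, "CCGCCG") for s in seqs)
    assert prof.values.sum() * prof.n_sequences == pytest.approx(total)


def test_hexamer_revcomp_symmetry():
    """CCGCCG occurrences on S equal CGGCGG occurrences on revcomp(S)."""
    rng = np.random.default_rng(3)
    seqs = [
        "".join(rng.choice(list("ACG"), p=[0.2, 0.4, 0.4], size=2000))
        for _ in range(10)
    ]
    fwd = hexamer_profile(seqs, "CCGCCG")
    rev = hexamer_profile([revcomp(s) for s in seqs], "CGGCGG")
    # total occurrence counts match exactly
    assert fwd.values.sum() == pytest.approx(rev.values.sum())


def test_hexamer_revcomp_window_mirror():
    # motif placed away from window boundaries: per-window mirror is exact
    seq = list("A" * 2000)
    seq[1150: 1156] = "CCGCCG"
    seq[340: 346] = "CCGCCG"
    seq = "".join(seq)
    fwd = hexamer_profile([seq], "CCGCCG")
    rev = hexamer_profile([revcomp(seq)], "CGGCGG")
    np.testing.assert_allclose(fwd.values, rev.values[::-1])


def test_both_hexamer_fraction():
    with_both = "CCGCCG" + "A" * 100 + "CGGCGG"
    only_a = "CCGCCG" + "A" * 100
    assert both_hexamer_fraction([with_both, only_a, "AAAA", "TTTT"]) == 25.0
    with pytest.raises(ValidationError):
        both_hexamer_fraction([])


# ------------------------------------------------------------ repeat runs


def test_repeat_single_maximal_run():
    stats = repeat_run_stats(["AACCGCCGCCGAA"], "CCG")
    assert len(stats.runs) == 1
    assert stats.runs[0].n_units == 3
    assert stats.mean_units == 3.0 and stats.max_units == 3


def test_repeat_two_single_unit_runs():
    stats = repeat_run_stats(["CCGACCG"], "CCG")
    assert [r.n_units for r in stats.runs] == [1, 1]
    assert stats.mean_units == 1.0


def test_repeat_empty_gives_nan():
    stats = repeat_run_stats([""], "CCG")
    assert math.isnan(stats.mean_units) and stats.max_units == 0


def test_repeat_unit_must_be_trinucleotide():
    with pytest.raises(ValueError):
        repeat_run_stats(["ACGT"], "CG")


@given(st.integers(1, 30))
@settings(derandomize=True, max_examples=30)
def test_repeat_pure_run_length(k):
    stats = repeat_run_stats(["AT" + "CCG" * k + "AT"], "CCG")
    assert len(stats.runs) == 1 and stats.runs[0].n_units == k


def test_repeat_regex_agrees_with_manual_scan():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("CG"), size=600))
    stats = repeat_run_stats([seq], "CCG")
    manual = [len(m.group()) // 3 for m in re.finditer("(?:CCG)+", seq)]
    assert sorted(r.n_units for r in stats.runs) == sorted(manual)


# ------------------------------------------------------------ extraction


def test_extract_promoters_orientation_and_skipping():
    seq = "A" * 5000 + "C" * 5000
    genome = GenomeAssembly({"chr1": 10_000}, {"chr1": seq})
    plus = make_adjusted("p", "+", 5000)
    minus = make_adjusted("m", "-", 5000)
    edge = make_adjusted("e", "+", 500)  # window runs off the chromosome
    out = extract_promoters(genome, [plus, minus, edge], span=1000)
    assert set(out) == {"p", "m"}
    assert out["p"] == "A" * 1000 + "C" * 1000
    # minus-strand promoter: reverse complement, TSS at index 1000
    assert out["m"] == "G" * 1001 + "T" * 999
    assert len(out["m"]) == 2000
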