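"""Metric panel: Nx oracles, alignment blocks, misassembly detection, rates."""

import random

import edlib
import pytest

from hga.evaluate import (
    align_contigs,
    detect_misassemblies,
    evaluate_assembly,
    expected_mismatch_total,
    genome_fraction_and_duplication,
    n50,
    na50,
    ng50,
    rates_per_100kbp,
    select_blocks,
    AlignmentBlock,
)
from hga.io_seq import Contig, ContigSet, revcomp
from hga.simulate import SimConfig, simulate_genome

from conftest import random_dna


def brute_nx(lengths, target):
    best = 0
    for cand in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= cand) >= target:
            best = cand
            break
    return best


# -- Nx statistics -----------------------------------------------------------

def test_n50_examples():
    assert n50([100, 50, 30, 20]) == 100
    assert n50([5, 5, 5, 5]) == 5
    with pytest.raises(ValueError):
        n50([])


def test_ng50_examples():
    # by definition: cumulative sums 100,150,180,200 first reach 200 at L=20
    assert ng50([100, 50, 30, 20], 400) == 20
    assert ng50([100, 50, 30, 20], 10_000) == 0


def test_nx_against_brute_force_oracle():
    rng = random.Random(7)
    for _ in range(200):
        lengths = [rng.randint(1, 500) for _ in range(rng.randint(1, 30))]
        assert n50(lengths) == brute_nx(lengths, sum(lengths) / 2)
        genome_len = rng.randint(1, 2 * sum(lengths))
        assert ng50(lengths, genome_len) == brute_nx(lengths, genome_len / 2)


# -- alignment ---------------------------------------------------------------

@pytest.fixture(scope="module")
def reference():
    rng = random.Random(42)
    return ContigSet([Contig("refA", random_dna(rng, 5000)),
                      Contig("refB", random_dna(rng, 3000))])


def test_exact_substring_single_full_block(reference):
    contig = ContigSet([Contig("c", reference[0].seq[1000:2000])])
    blocks = align_contigs(contig, reference)
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.qstart, b.qend) == (0, 1000)
    assert (b.ref_id, b.rstart, b.rend, b.strand) == ("refA", 1000, 2000, "+")
    assert b.mismatches == 0 and b.indels == 0


def test_reverse_complement_block_minus_strand(reference):
    contig = ContigSet([Contig("c", revcomp(reference[0].seq[1000:2000]))])
    blocks = align_contigs(contig, reference)
    assert len(blocks) == 1
    assert blocks[0].strand == "-"
    assert (blocks[0].rstart, blocks[0].rend) == (1000, 2000)


def test_planted_substitutions_counted_against_dp_oracle(reference):
    rng = random.Random(3)
    seq = list(reference[0].seq[500:1500])
    positions = rng.sample(range(40, 960), 5)
    for p in positions:
        seq[p] = next(b for b in "ACGT" if b != seq[p])
    contig = ContigSet([Contig("c", "".join(seq))])
    blocks = align_contigs(contig, reference)
    assert len(blocks) == 1
    # independent oracle: full dynamic-programming alignment of the pair
    oracle = edlib.align("".join(seq), reference[0].seq[500:1500], mode="NW")
    assert blocks[0].mismatches == oracle["editDistance"] == 5


# -- misassemblies -----------------------------------------------------------

def test_strand_flip_chimera_is_one_global(reference):
    ref = reference[0].seq
    chimera = ref[0:500] + revcomp(ref[2000:2500])
    blocks = select_blocks(align_contigs(ContigSet([Contig("c", chimera)]),
                                         reference))["c"]
    glob, loc, bps = detect_misassemblies(blocks)
    assert (glob, loc) == (1, 0)
    assert bps[0][2] == "global"


def test_cross_replicon_chimera_is_one_global(reference):
    chimera = reference[0].seq[0:500] + reference[1].seq[0:500]
    blocks = select_blocks(align_contigs(ContigSet([Contig("c", chimera)]),
                                         reference))["c"]
    glob, loc, _ = detect_misassemblies(blocks)
    assert (glob, loc) == (1, 0)


def test_colinear_contig_no_misassembly(reference):
    contig = ContigSet([Contig("c", reference[0].seq[100:2100])])
    blocks = select_blocks(align_contigs(contig, reference))["c"]
    assert detect_misassemblies(blocks)[:2] == (0, 0)


def test_relocation_chimera_distance_classes(reference):
    ref = reference[0].seq
    # 400 bp skip: local (85 < d <= 1000); 2000 bp skip: global
    local_c = ref[0:500] + ref[900:1400]
    global_c = ref[0:500] + ref[2500:3000]
    for seq, expect in ((local_c, (0, 1)), (global_c, (1, 0))):
        blocks = select_blocks(align_contigs(ContigSet([Contig("c", seq)]),
                                             reference))["c"]
        assert detect_misassemblies(blocks)[:2] == expect


# -- rates and fractions -----------------------------------------------------

def test_rates_arithmetic():
    blocks = [AlignmentBlock("c", 0, 1000, "r", 0, 1000, "+", 2, 0)]
    mp, ip = rates_per_100kbp(blocks)
    assert mp == pytest.approx(200.0)
    assert ip == 0.0
    with pytest.raises(ValueError):
        rates_per_100kbp([])


def test_expected_mismatch_total_worked_example():
    # 5 Mbp genome, full genome fraction, MP100K = 5 -> 250 mismatches
    assert expected_mismatch_total(5_000_000, 100.0, 5.0) == pytest.approx(250.0)


def test_genome_fraction_and_duplication(reference):
    full = ContigSet([Contig("c", reference[0].seq),
                      Contig("d", reference[1].seq)])
    blocks = align_contigs(full, reference)
    frac, dup = genome_fraction_and_duplication(blocks, reference)
    assert frac == pytest.approx(100.0)
    assert dup == pytest.approx(1.0)
    doubled = ContigSet([Contig("c1", reference[0].seq),
                         Contig("c2", reference[0].seq),
                         Contig("d1", reference[1].seq),
                         Contig("d2", reference[1].seq)])
    frac, dup = genome_fraction_and_duplication(
        align_contigs(doubled, reference), reference)
    assert frac == pytest.approx(100.0)
    assert dup == pytest.approx(2.0)
    half = ContigSet([Contig("c", reference[0].seq[:2500])])
    frac, dup = genome_fraction_and_duplication(
        align_contigs(half, reference), reference)
    assert frac == pytest.approx(2500 / 8000 * 100)
    assert dup == pytest.approx(1.0)


# -- composite report --------------------------------------------------------

def test_perfect_assembly_report(reference):
    contigs = ContigSet([Contig(c.id + "_asm", c.seq) for c in reference])
    report = evaluate_assembly(contigs, reference)
    assert report.genome_fraction == pytest.approx(100.0)
    assert report.misassemblies_global == report.misassemblies_local == 0
    assert report.mp100k == 0.0 and report.ip100k == 0.0
    assert report.n50 == report.na50 == 5000
    assert report.unaligned_len == 0


def test_chimera_na50_breaks_at_breakpoint(reference):
    ref = reference[0].seq
    chimera = ContigSet([Contig("c", ref[0:500] + revcomp(ref[2000:2500]))])
    assert na50(chimera, reference) == 500


def test_unaligned_length_counts_planted_random_contig(reference):
    rng = random.Random(77)
    junk = random_dna(rng, 600)
    contigs = ContigSet([Contig("good", reference[0].seq[0:2000]),
                         Contig("junk", junk)])
    report = evaluate_assembly(contigs, reference)
    assert report.unaligned_len == 600


def test_report_invariants_on_random_simulated_assemblies():
    """na50 <= n50, nga50 <= ng50, bounded fractions, on random fragmentations."""
    rng = random.Random(123)
    for trial in range(25):
        cfg = SimConfig(genome_len=4000, coverage=10, read_len=100,
                        err_sub=0.0, paired=False, seed=trial)
        ref = simulate_genome(cfg)
        genome = ref[0].seq
        pieces = []
        pos = 0
        while pos < 3900:
            end = min(4000, pos + rng.randint(250, 1200))
            seq = genome[pos:end]
            if rng.random() < 0.3:
                seq = revcomp(seq)
            pieces.append(Contig(f"c{pos}", seq))
            pos = end - rng.randint(0, 50)
        report = evaluate_assembly(ContigSet(pieces), ref)
        assert report.na50 <= report.n50
        assert report.nga50 <= report.ng50
        assert 0 <= report.genome_fraction <= 100
        if report.genome_fraction > 0:
            assert report.duplication_ratio >= 1.0


def test_planted_error_rate_recovery(reference):
    """s planted substitutions over G aligned bases give mp100k ~ s*1e5/G."""
    rng = random.Random(9)
    s = 60
    seq = list(reference[0].seq)
    for p in rng.sample(range(50, 4950), s):
        seq[p] = next(b for b in "ACGT" if b != seq[p])
    contigs = ContigSet([Contig("c", "".join(seq))])
    report = evaluate_assembly(contigs, reference)
    expected = s * 100_000 / 5000
    assert abs(report.mp100k - expected) <= 0.2 * expected
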