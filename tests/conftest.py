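import random

import pytest

from hga.io_seq import Contig, ContigSet, ReadSet, SeqRecord
from hga.simulate import SimConfig, simulate_genome, simulate_reads


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20_240_901)


@pytest.fixture
def small_genome(rng):
    """Repeat-free 2 kb single-replicon reference."""
    return ContigSet([Contig("chr1", random_dna(rng, 2000))])


def tiling_reads(genome: str, read_len: int, step: int) -> ReadSet:
    """Deterministic error-free reads tiling a sequence."""
    records = []
    i = 0
    pos = 0
    while pos + read_len <= len(genome):
        records.append(SeqRecord(f"t{i}", genome[pos : pos + read_len]))
        pos += step
        i += 1
    records.append(SeqRecord("tlast", genome[-read_len:]))
    return ReadSet(records)


@pytest.fixture
def ideal_readset(small_genome):
    cfg = SimConfig(
        genome_len=2000, coverage=50, read_len=100,
        err_sub=0.0, err_indel=0.0, paired=False, seed=3,
    )
    return simulate_reads(small_genome, cfg)
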