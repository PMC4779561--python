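"""Synthetic reference genomes and error-bearing short reads.

The generator emulates a single short-insert high-coverage Illumina library
(100-250 bp reads at ~100-200x) over a bacterial-scale reference that may
consist of several replicons (chromosome plus plasmids) and may carry
planted exact repeats longer than the read length — the structure that makes
de Bruijn assembly fragment.  The error model is deliberately simple:
i.i.d. substitutions to a uniformly chosen different base and single-base
indels, with constant 'I' quality strings.  Reads are sampled uniformly; a
fragment that would run off a replicon end is resampled (no circularity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_seq import Contig, ContigSet, ReadSet, SeqRecord, revcomp

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    """Raised for inconsistent simulation settings."""


@dataclass
class SimConfig:
    """Parameters of a simulated genome + library.

    Attributes
    ----------
    genome_len
        Total reference length in bases (ignored if *replicons* is given).
    replicons
        Optional list of (name, length) pairs for multi-replicon genomes.
    repeat_spec
        List of (repeat_len, copies): each entry plants *copies* exact
        occurrences of one random repeat unit, non-overlapping.
    gc
        Target GC fraction of the random (non-repeat) sequence.
    read_len, coverage
        Read length L and fold coverage C; the library has
        round(genome_len * C / L) reads (rounded to pair parity).
    err_sub, err_indel
        Per-base substitution and indel rates.
    paired, insert_mean, insert_sd
        Paired-end mode with normally distributed insert (fragment) size.
    seed
        Seed for all randomness; identical seeds give identical output.
    """

    genome_len: int = 100_000
    replicons: Optional[Sequence[tuple[str, int]]] = None
    repeat_spec: Sequence[tuple[int, int]] = field(default_factory=list)
    gc: float = 0.5
    read_len: int = 100
    coverage: float = 100.0
    err_sub: float = 0.01
    err_indel: float = 0.0
    paired: bool = True
    insert_mean: int = 300
    insert_sd: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise SimConfigError("coverage must be > 0")
        if not (0 <= self.err_sub < 1 and 0 <= self.err_indel < 1):
            raise SimConfigError("error rates must be in [0, 1)")
        if not 0 < self.gc < 1:
            raise SimConfigError("gc must be in (0, 1)")
        if self.paired and self.insert_mean < self.read_len:
            raise SimConfigError(
                f"insert_mean ({self.insert_mean}) must be >= read_len "
                f"({self.read_len}) in paired mode"
            )

    def replicon_list(self) -> list[tuple[str, int]]:
        if self.replicons:
            return [(str(n), int(l)) for n, l in self.replicons]
        return [("chr1", self.genome_len)]

    @property
    def total_genome_len(self) -> int:
        return sum(l for _, l in self.replicon_list())


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    at, gcp = (1 - gc) / 2, gc / 2
    codes = rng.choice(4, size=n, p=[at, gcp, gcp, at])
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genome(cfg: SimConfig) -> ContigSet:
    """Generate the reference replicons with planted exact repeats.

    Repeat placements are recorded in ``ContigSet.metadata['repeats']`` as
    (replicon, family, copy, start, end) tuples.
    """
    rng = np.random.default_rng([int(cfg.seed), 0])
    replicons = cfg.replicon_list()
    total_repeat = sum(l * c for l, c in cfg.repeat_spec)
    if total_repeat > cfg.total_genome_len:
        raise SimConfigError(
            f"repeats total {total_repeat} bases but genome is only "
            f"{cfg.total_genome_len}"
        )
    seqs = {name: list(_random_seq(rng, length, cfg.gc)) for name, length in replicons}
    placements: list[tuple[str, int, int, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name, _ in replicons}
    names = [n for n, _ in replicons]
    lens = np.array([l for _, l in replicons], dtype=float)
    weights = lens / lens.sum()
    for fam, (rep_len, copies) in enumerate(cfg.repeat_spec):
        unit = _random_seq(rng, rep_len, cfg.gc)
        for copy in range(copies):
            for _attempt in range(1000):
                name = names[rng.choice(len(names), p=weights)]
                length = dict(replicons)[name]
                if length < rep_len:
                    continue
                start = int(rng.integers(0, length - rep_len + 1))
                end = start + rep_len
                if any(s < end and start < e for s, e in occupied[name]):
                    continue
                seqs[name][start:end] = unit
                occupied[name].append((start, end))
                placements.append((name, fam, copy, start, end))
                break
            else:
                raise SimConfigError(
                    f"could not place repeat family {fam} copy {copy} "
                    "without overlap"
                )
    contigs = [Contig(name, "".join(seqs[name])) for name, _ in replicons]
    out = ContigSet(contigs)
    out.metadata["repeats"] = placements
    out.metadata["config"] = cfg
    return out


def _apply_errors(
    rng: np.random.Generator, seq: str, err_sub: float, err_indel: float
) -> str:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = codes.size
    if err_sub > 0:
        hits = np.nonzero(rng.random(n) < err_sub)[0]
        if hits.size:
            # shift by 1..3 within the base alphabet: always a different base
            idx = np.searchsorted(_BASES, codes[hits])
            codes[hits] = _BASES[(idx + rng.integers(1, 4, hits.size)) % 4]
    out = codes.tobytes().decode("ascii")
    if err_indel > 0:
        hits = np.nonzero(rng.random(n) < err_indel)[0]
        for pos in hits[::-1]:
            if rng.random() < 0.5:
                out = out[:pos] + out[pos + 1 :]  # deletion
            else:
                ins = "ACGT"[rng.integers(0, 4)]
                out = out[:pos] + ins + out[pos:]
    return out


def simulate_reads(reference: ContigSet, cfg: SimConfig) -> ReadSet:
    """Sample uniform-coverage reads from the reference.

    Start positions are uniform over each replicon (proportional to its
    length); orientation is reverse-complemented with probability 0.5.
    With zero error rates every read is an exact substring of a replicon or
    its reverse complement.  Read origins (replicon, start, end, strand)
    are recorded in ``ReadSet.metadata['origins']``, parallel to records.
    """
    rng = np.random.default_rng([int(cfg.seed), 1])
    L = cfg.read_len
    names = [c.id for c in reference]
    seqs = {c.id: c.seq for c in reference}
    lens = np.array([len(c) for c in reference], dtype=float)
    if L > lens.min():
        raise SimConfigError(
            f"read_len {L} exceeds shortest replicon ({int(lens.min())})"
        )
    total_len = int(lens.sum())
    n_reads = int(round(total_len * cfg.coverage / L))
    if cfg.paired:
        n_pairs = max(1, int(round(total_len * cfg.coverage / (2 * L))))
        n_reads = 2 * n_pairs
    else:
        n_pairs = max(1, n_reads)
        n_reads = n_pairs
    weights = lens / lens.sum()
    pad = 8 if cfg.err_indel > 0 else 0

    records: list[SeqRecord] = []
    origins: list[tuple[str, int, int, str]] = []
    repl_idx = rng.choice(len(names), size=n_pairs, p=weights)
    flips = rng.random(n_pairs) < 0.5
    if cfg.paired:
        inserts = np.clip(
            np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n_pairs)).astype(int),
            L,
            None,
        )
    for i in range(n_pairs):
        name = names[repl_idx[i]]
        seq = seqs[name]
        rl = len(seq)
        if cfg.paired:
            ins = min(int(inserts[i]), rl)
            start = int(rng.integers(0, rl - ins + 1))
            frag = seq[start : start + ins]
            r1, r2 = frag[:L], revcomp(frag[-L:])
            o1 = (name, start, start + L, "+")
            o2 = (name, start + ins - L, start + ins, "-")
            if flips[i]:
                r1, r2 = revcomp(frag[-L:]), frag[:L]
                o1, o2 = o2, o1
            for mate, (r, o) in enumerate(((r1, o1), (r2, o2)), start=1):
                r = _apply_errors(rng, r, cfg.err_sub, cfg.err_indel)
                if pad:
                    r = (r + seq[:pad])[:L] if len(r) < L else r[:L]
                records.append(
                    SeqRecord(f"read{i}/{mate}", r, "I" * len(r), mate)
                )
                origins.append(o)
        else:
            start = int(rng.integers(0, rl - L - pad + 1)) if rl > L + pad else 0
            raw = seq[start : start + L + pad]
            strand = "-" if flips[i] else "+"
            r = raw if strand == "+" else revcomp(raw)
            r = _apply_errors(rng, r, cfg.err_sub, cfg.err_indel)
            r = r[:L]
            records.append(SeqRecord(f"read{i}", r, "I" * len(r)))
            origins.append((name, start, start + L + pad, strand))
    out = ReadSet(records, paired=cfg.paired)
    out.metadata["origins"] = origins
    out.metadata["config"] = cfg
    return out
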