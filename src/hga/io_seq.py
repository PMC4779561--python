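"""FASTA/FASTQ readers and writers plus the in-memory sequence containers.

All sequences are stored uppercase over the alphabet ``{A, C, G, T, N}``.
Paired-end data is always held interleaved (R1 then R2 for each pair) no
matter how it arrived on disk; this makes pair-preserving partitioning a
simple matter of slicing by pair index.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


class SequenceFormatError(ValueError):
    """Raised on malformed records or illegal characters."""


def _clean_seq(seq: str, where: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise SequenceFormatError(
            f"{where}: illegal character {seq[pos]!r} at position {pos}"
        )
    return seq


@dataclass
class SeqRecord:
    """A single read or sequence with optional quality and mate tag."""

    id: str
    seq: str
    qual: Optional[str] = None
    mate: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise SequenceFormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if self.mate not in (None, 1, 2):
            raise ValueError(f"mate tag must be 1 or 2, got {self.mate!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def id_stem(self) -> str:
        """Identifier with a trailing /1 or /2 mate suffix stripped."""
        if self.id.endswith(("/1", "/2")):
            return self.id[:-2]
        return self.id


@dataclass
class Contig:
    """A named contig with provenance (which partition/stage produced it)."""

    id: str
    seq: str
    partition: Optional[int] = None
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        self.seq = _clean_seq(self.seq, f"contig {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ContigSet:
    """An ordered collection of contigs."""

    contigs: list[Contig] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __getitem__(self, i: int) -> Contig:
        return self.contigs[i]

    def lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    @property
    def total_len(self) -> int:
        return sum(len(c) for c in self.contigs)

    def sequences(self) -> list[str]:
        return [c.seq for c in self.contigs]


@dataclass
class ReadSet:
    """An ordered read collection; paired reads are interleaved R1,R2."""

    records: list[SeqRecord] = field(default_factory=list)
    paired: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.paired and len(self.records) % 2 != 0:
            raise SequenceFormatError(
                "paired ReadSet must contain an even number of records"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def read_len_mean(self) -> float:
        if not self.records:
            return 0.0
        return self.total_bases / len(self.records)

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def pairs(self) -> Iterator[tuple[SeqRecord, ...]]:
        """Yield pairing units: (R1, R2) tuples if paired, else singletons."""
        if self.paired:
            it = iter(self.records)
            for r1 in it:
                yield (r1, next(it))
        else:
            for r in self.records:
                yield (r,)


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_fastq_file(path: PathLike, mate: Optional[int]) -> list[SeqRecord]:
    records = []
    with _open_text(path) as handle:
        try:
            for idx, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                rid = title.split()[0] if title else f"read{idx}"
                m = mate
                if m is None and rid.endswith(("/1", "/2")):
                    m = int(rid[-1])
                try:
                    records.append(
                        SeqRecord(rid, _clean_seq(seq, f"record {idx}"), qual, m)
                    )
                except SequenceFormatError as exc:
                    raise SequenceFormatError(f"{path}: {exc}") from exc
        except ValueError as exc:
            if isinstance(exc, SequenceFormatError):
                raise
            raise SequenceFormatError(
                f"{path}: malformed FASTQ near record {len(records)}: {exc}"
            ) from exc
    return records


def read_fastq(
    path: PathLike,
    path2: Optional[PathLike] = None,
    interleaved: bool = False,
) -> ReadSet:
    """Load FASTQ reads (optionally gzipped).

    Parameters
    ----------
    path
        FASTQ file; for paired data either the R1 file (with *path2*) or an
        interleaved file (with ``interleaved=True``).
    path2
        Optional R2 file; records are interleaved with R1 by position and
        must match 1:1 by id stem.
    interleaved
        Treat *path* as interleaved paired data.
    """
    if path2 is not None:
        r1 = _parse_fastq_file(path, mate=1)
        r2 = _parse_fastq_file(path2, mate=2)
        if len(r1) != len(r2):
            raise SequenceFormatError(
                f"paired files have {len(r1)} vs {len(r2)} records"
            )
        records: list[SeqRecord] = []
        for a, b in zip(r1, r2):
            if a.id_stem != b.id_stem:
                raise SequenceFormatError(
                    f"mate id mismatch: {a.id!r} vs {b.id!r}"
                )
            records.append(a)
            records.append(b)
        return ReadSet(records, paired=True)

    records = _parse_fastq_file(path, mate=None)
    if interleaved:
        for i, rec in enumerate(records):
            if rec.mate is None:
                rec.mate = 1 if i % 2 == 0 else 2
        return ReadSet(records, paired=True)
    return ReadSet(records, paired=False)


def read_fasta(path: PathLike) -> ContigSet:
    """Load a (possibly line-wrapped, possibly gzipped) FASTA file."""
    contigs = []
    with _open_text(path) as handle:
        for idx, (title, seq) in enumerate(SimpleFastaParser(handle)):
            cid = title.split()[0] if title else f"seq{idx}"
            try:
                contigs.append(Contig(cid, seq))
            except SequenceFormatError as exc:
                raise SequenceFormatError(f"{path}: {exc}") from exc
    return ContigSet(contigs)


def write_fasta(contigs: Union[ContigSet, Iterable[Contig]], path: PathLike,
                wrap: int = 70) -> None:
    """Write contigs as FASTA, wrapped at *wrap* columns."""
    with _open_text(path, "wt") as out:
        for c in contigs:
            out.write(f">{c.id}\n")
            for i in range(0, len(c.seq), wrap):
                out.write(c.seq[i : i + wrap])
                out.write("\n")


def write_fastq(reads: ReadSet, path: PathLike) -> None:
    """Write reads as 4-line FASTQ (Phred+33; missing quality becomes 'I')."""
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r)
            out.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
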