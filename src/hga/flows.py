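"""The hierarchical assembly flows.

Four flows are orchestrated over the partition and assembler modules:

* ``basic``        — B(kmer, c): assemble the whole read set once.
* ``merged``       — M(kmer, p, c): assemble each of p disjoint partitions
  and take the plain multiset union of their contigs (no deduplication —
  duplicate contigs carry Px multiplicity into re-assembly, which is where
  the branch support comes from).
* ``combined``     — C(kmer, p, c): assemble the merged contigs together as
  long reads at k=31, yielding a deduplicated consensus set.
* ``hga_merged`` / ``hga_combined`` — HGA(kmer, contigs): re-assemble the
  whole read set with the stage-2 contigs injected as protected, highly
  weighted seeds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .dbg import AssemblyOpts, assemble
from .evaluate import EvalReport, evaluate_assembly
from .io_seq import Contig, ContigSet, ReadSet, SeqRecord
from .partition import partition_reads

logger = logging.getLogger(__name__)

FLOWS = ("basic", "merged", "combined", "hga_merged", "hga_combined")

# k-mer regimes that work well for ~100 bp ("hiseq") and ~250 bp ("miseq")
# reads: short k for the partition (preprocessing) assemblies, medium/long k
# for the re-assembly.
PRESETS = {
    "hiseq": {"k_pre_values": (21, 31), "k_re_values": (31, 41, 51)},
    "miseq": {"k_pre_values": (21, 31), "k_re_values": (61, 71, 81)},
}


@dataclass
class FlowSpec:
    """Descriptor of one assembly flow.

    ``basic`` requires p=1 and ignores ``k_re``.  ``k_combine`` (default 31)
    and ``expected_cov_combine`` (default p) parametrize the contig
    combining assembly.
    """

    flow: str = "hga_merged"
    p: int = 4
    k_pre: int = 21
    k_re: int = 41
    k_combine: int = 31
    expected_cov_combine: Optional[int] = None
    min_cov: float = 10.0
    genome_len_hint: Optional[int] = None
    seed_weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.flow not in FLOWS:
            raise ValueError(f"unknown flow {self.flow!r}; expected one of {FLOWS}")
        if self.flow == "basic" and self.p != 1:
            raise ValueError("the basic flow requires p=1")
        if self.p < 1:
            raise ValueError("p must be >= 1")

    @property
    def expected_cov(self) -> int:
        return self.expected_cov_combine if self.expected_cov_combine else self.p


def run_basic(reads: ReadSet, k: int, **opt_kwargs) -> ContigSet:
    """B(kmer, c): one seedless assembly of the whole read set."""
    if len(reads) == 0:
        logger.warning("empty read set: empty basic assembly")
        return ContigSet([])
    return assemble(reads, AssemblyOpts(k=k, **opt_kwargs))


def merge_contigs(per_partition: Sequence[ContigSet]) -> ContigSet:
    """M flow: pure multiset union with partition provenance, no dedup."""
    if len(per_partition) == 0:
        raise ValueError("merge_contigs needs at least one contig set")
    merged = []
    for pid, cset in enumerate(per_partition):
        for c in cset:
            merged.append(
                Contig(f"p{pid}_{c.id}", c.seq, partition=pid, stage="merged")
            )
    return ContigSet(merged)


def combine_contigs(
    per_partition: Sequence[ContigSet],
    k_combine: int = 31,
    expected_cov: Optional[int] = None,
) -> ContigSet:
    """C flow: assemble all partitions' contigs together as long reads.

    Every contig k-mer matters, so no abundance cutoff is applied
    (min_kmer_count=1); the expected coverage (defaulting to the number of
    partitions) maps to a bubble support threshold: a variant arm is only
    collapsed when fewer than expected_cov/2 partitions support it.
    """
    if len(per_partition) == 0:
        raise ValueError("combine_contigs needs at least one contig set")
    if expected_cov is None:
        expected_cov = len(per_partition)
    merged = merge_contigs(per_partition)
    usable = [c for c in merged if len(c) >= k_combine]
    if not usable:
        logger.warning(
            "all contigs shorter than k_combine=%d: empty combined set", k_combine
        )
        return ContigSet([])
    # contigs re-enter the assembler as long unpaired reads
    pseudo_reads = ReadSet([SeqRecord(c.id, c.seq) for c in usable])
    opts = AssemblyOpts(
        k=k_combine,
        min_kmer_count=1,
        pop_min_keep=expected_cov / 2,
    )
    combined = assemble(pseudo_reads, opts)
    for c in combined:
        c.stage = "combined"
    return combined


def run_hga(reads: ReadSet, spec: FlowSpec, intermediates: Optional[dict] = None) -> ContigSet:
    """Run a full flow per *spec* and return the final contig set.

    ``basic`` assembles everything once at ``k_pre``.  The hierarchical
    flows partition the reads, assemble each partition at ``k_pre``, merge
    or combine the partition contigs, and (for the hga_* flows) re-assemble
    the whole read set at ``k_re`` seeded with the stage-2 contigs.  If an
    *intermediates* dict is supplied the per-stage contig sets are stored
    into it under 'partitions', 'stage2'.
    """
    if spec.flow == "basic":
        return run_basic(reads, spec.k_pre)
    parts = partition_reads(
        reads, spec.p, min_cov=spec.min_cov, genome_len_hint=spec.genome_len_hint
    )
    part_contigs: list[ContigSet] = []
    for pid, part in enumerate(parts):
        contigs = assemble(part, AssemblyOpts(k=spec.k_pre))
        if len(contigs) == 0:
            raise RuntimeError(
                f"partition {pid} produced no contigs at k={spec.k_pre}; "
                "all partitions are required for support"
            )
        for c in contigs:
            c.partition = pid
            c.stage = "partition"
        part_contigs.append(contigs)
        logger.info("partition %d/%d: %d contigs", pid + 1, spec.p, len(contigs))
    if spec.flow in ("merged", "hga_merged"):
        stage2 = merge_contigs(part_contigs)
    else:
        stage2 = combine_contigs(part_contigs, spec.k_combine, spec.expected_cov)
    if intermediates is not None:
        intermediates["partitions"] = part_contigs
        intermediates["stage2"] = stage2
    if spec.flow in ("merged", "combined"):
        return stage2
    logger.info("re-assembling %d reads with %d seed contigs at k=%d",
                len(reads), len(stage2), spec.k_re)
    return assemble(
        reads,
        AssemblyOpts(k=spec.k_re, seed_weight=spec.seed_weight),
        seeds=stage2,
    )


@dataclass
class GridRow:
    spec: FlowSpec
    report: EvalReport
    best: bool = False


def grid_search(
    reads: ReadSet,
    reference: ContigSet,
    p_values: Sequence[int],
    k_pre_values: Sequence[int],
    k_re_values: Sequence[int],
    flows: Sequence[str] = ("hga_merged", "hga_combined"),
    genome_len_hint: Optional[int] = None,
) -> list[GridRow]:
    """Exhaustive cartesian sweep; the best row by N50 is flagged.

    Ties on N50 are broken in favour of fewer contigs.
    """
    if not (p_values and k_pre_values and k_re_values and flows):
        raise ValueError("all grids must be nonempty")
    rows: list[GridRow] = []
    for flow, p, k_pre, k_re in itertools.product(
        flows, p_values, k_pre_values, k_re_values
    ):
        spec = FlowSpec(
            flow=flow, p=p, k_pre=k_pre, k_re=k_re,
            genome_len_hint=genome_len_hint,
        )
        contigs = run_hga(reads, spec)
        rows.append(GridRow(spec, evaluate_assembly(contigs, reference)))
    best = max(
        range(len(rows)),
        key=lambda i: (rows[i].report.n50, -rows[i].report.num_contigs, -i),
    )
    rows[best].best = True
    return rows
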