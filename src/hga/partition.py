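"""Split a read set into p disjoint equal-size partitions.

Assignment is a deterministic round-robin over pairing units (pair i goes to
partition i mod p), which keeps mates together, needs no random seed, and
gives every partition near-uniform coverage.  The only constraint carried
over from the hierarchical method is that each partition should retain at
least ~10x coverage; when a genome length hint is available the constraint
is enforced, otherwise it is skipped with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from .io_seq import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 10.0


class PartitionError(ValueError):
    """Raised when the requested split violates the coverage constraint."""


@dataclass
class PartitionPlan:
    """Read-index -> partition assignment with coverage bookkeeping."""

    p: int
    assignment: list[int]
    per_partition_coverage: Optional[float]

    def indices(self, part: int) -> list[int]:
        return [i for i, a in enumerate(self.assignment) if a == part]


def plan_partition(
    reads: ReadSet,
    p: int,
    min_cov: float = DEFAULT_MIN_COVERAGE,
    genome_len_hint: Optional[int] = None,
) -> PartitionPlan:
    """Compute the round-robin assignment and check the coverage floor."""
    if p < 1:
        raise PartitionError(f"p must be >= 1, got {p}")
    per_cov: Optional[float] = None
    if genome_len_hint:
        total_cov = reads.total_bases / genome_len_hint
        per_cov = total_cov / p
        if per_cov < min_cov:
            max_p = max(1, math.floor(total_cov / min_cov))
            raise PartitionError(
                f"{p} partitions would give {per_cov:.2f}x coverage each, "
                f"below the {min_cov:g}x floor; at most {max_p} partitions "
                f"are admissible for this dataset"
            )
    else:
        logger.warning(
            "no genome length hint: skipping the >=%gx per-partition "
            "coverage check", min_cov,
        )
    assignment: list[int] = []
    unit = 2 if reads.paired else 1
    n_units = len(reads.records) // unit
    for i in range(n_units):
        assignment.extend([i % p] * unit)
    return PartitionPlan(p, assignment, per_cov)


def partition_reads(
    reads: ReadSet,
    p: int,
    min_cov: float = DEFAULT_MIN_COVERAGE,
    genome_len_hint: Optional[int] = None,
) -> list[ReadSet]:
    """Split *reads* into p disjoint partitions of (near-)equal size.

    Partitions differ in size by at most one pairing unit; mates always
    land in the same partition.  Raises :class:`PartitionError` if the
    per-partition coverage would fall below *min_cov* (only checkable when
    *genome_len_hint* is given).
    """
    plan = plan_partition(reads, p, min_cov, genome_len_hint)
    buckets: list[list] = [[] for _ in range(p)]
    for idx, part in enumerate(plan.assignment):
        buckets[part].append(reads.records[idx])
    return [ReadSet(b, paired=reads.paired) for b in buckets]
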