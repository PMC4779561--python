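"""Canned study conditions for validating the hierarchical method.

Two desk-scale synthetic scenarios are defined once and reused by the test
suite and the results-reproduction script:

* the *ideal case*: error-free 50x single-end reads over a repeat-free
  20 kb genome, where any k should reconstruct the genome as one contig;
* the *repeat scenario*: a 100 kb genome with planted exact repeats
  (2 x 300 bp and 2 x 800 bp, both longer than the reads) sequenced as
  100x paired 100 bp reads with a 1% substitution rate — the regime in
  which hierarchical assembly should beat the basic flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median
from typing import Optional, Sequence

from .dbg import AssemblyOpts, assemble
from .evaluate import EvalReport, evaluate_assembly
from .flows import combine_contigs, merge_contigs, run_basic
from .io_seq import ContigSet, ReadSet
from .partition import partition_reads
from .simulate import SimConfig, simulate_genome, simulate_reads

IDEAL_CONFIG = dict(
    genome_len=20_000, coverage=50.0, read_len=100,
    err_sub=0.0, err_indel=0.0, paired=False,
)

REPEAT_CONFIG = dict(
    genome_len=100_000, repeat_spec=((300, 2), (800, 2)),
    coverage=100.0, read_len=100, err_sub=0.01, err_indel=0.0,
    paired=True, insert_mean=300, insert_sd=30,
)

BASIC_KS = (21, 31, 41)
HGA_P = 4
HGA_K_PRE = 21
HGA_K_RE = 41


def ideal_case(k: int, seed: int = 7) -> EvalReport:
    """Assemble the ideal-case scenario at one k and evaluate it."""
    cfg = SimConfig(seed=seed, **IDEAL_CONFIG)
    reference = simulate_genome(cfg)
    reads = simulate_reads(reference, cfg)
    contigs = assemble(reads, AssemblyOpts(k=k))
    return evaluate_assembly(contigs, reference)


@dataclass
class FlowTrial:
    """Per-seed outcomes of the repeat-scenario flow comparison."""

    seed: int
    err_sub: float
    basic_na50: dict[int, int]          # k -> NA50
    basic_mp100k: float                 # at k = HGA_K_PRE
    partition_mp100k: list[float]
    hga_merged_na50: Optional[int] = None
    hga_combined_na50: Optional[int] = None

    @property
    def best_basic_na50(self) -> int:
        return max(self.basic_na50.values())

    @property
    def mean_partition_mp100k(self) -> float:
        return mean(self.partition_mp100k)


def flows_trial(
    seed: int,
    err_sub: float = 0.01,
    flows: Sequence[str] = ("merged",),
    basic_ks: Sequence[int] = BASIC_KS,
) -> FlowTrial:
    """Run basic + partition + HGA flows on one simulated replicate."""
    cfg = SimConfig(seed=seed, **{**REPEAT_CONFIG, "err_sub": err_sub})
    reference = simulate_genome(cfg)
    reads = simulate_reads(reference, cfg)
    glen = cfg.total_genome_len

    basic_na50: dict[int, int] = {}
    basic_mp = 0.0
    for k in basic_ks:
        report = evaluate_assembly(run_basic(reads, k), reference)
        basic_na50[k] = report.na50
        if k == HGA_K_PRE:
            basic_mp = report.mp100k

    parts = partition_reads(reads, HGA_P, genome_len_hint=glen)
    part_contigs: list[ContigSet] = []
    part_mp: list[float] = []
    for part in parts:
        contigs = assemble(part, AssemblyOpts(k=HGA_K_PRE))
        part_contigs.append(contigs)
        part_mp.append(evaluate_assembly(contigs, reference).mp100k)

    trial = FlowTrial(seed, err_sub, basic_na50, basic_mp, part_mp)
    if "merged" in flows:
        seeds_m = merge_contigs(part_contigs)
        hga = assemble(reads, AssemblyOpts(k=HGA_K_RE), seeds=seeds_m)
        trial.hga_merged_na50 = evaluate_assembly(hga, reference).na50
    if "combined" in flows:
        seeds_c = combine_contigs(part_contigs, k_combine=31, expected_cov=HGA_P)
        hga = assemble(reads, AssemblyOpts(k=HGA_K_RE), seeds=seeds_c)
        trial.hga_combined_na50 = evaluate_assembly(hga, reference).na50
    return trial


@dataclass
class FlowSummary:
    """Medians over replicate trials."""

    n_trials: int
    median_best_basic_na50: float
    median_hga_merged_na50: Optional[float]
    median_hga_combined_na50: Optional[float]
    median_basic_mp100k: float
    median_mean_partition_mp100k: float


def summarize(trials: Sequence[FlowTrial]) -> FlowSummary:
    merged = [t.hga_merged_na50 for t in trials if t.hga_merged_na50 is not None]
    combined = [t.hga_combined_na50 for t in trials if t.hga_combined_na50 is not None]
    return FlowSummary(
        n_trials=len(trials),
        median_best_basic_na50=median(t.best_basic_na50 for t in trials),
        median_hga_merged_na50=median(merged) if merged else None,
        median_hga_combined_na50=median(combined) if combined else None,
        median_basic_mp100k=median(t.basic_mp100k for t in trials),
        median_mean_partition_mp100k=median(t.mean_partition_mp100k for t in trials),
    )
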