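"""Reference-based assembly evaluation (QUAST-style metric panel).

Contigs are aligned to the reference by exact-anchor chaining: all shared
21-mers are collected, grouped into colinear chains per diagonal band, and
each chain is scored with a full edit-distance alignment (edlib) across its
span.  From the per-contig alignment blocks the module derives the usual
panel: N50/NG50, NA50/NGA50 (after breaking contigs at misassembly
breakpoints), genome fraction, duplication ratio, global/local
misassemblies, mismatches and indels per 100 kbp, and unaligned length.

Thresholds follow the published QUAST conventions: adjacent blocks of one
contig on different replicons, different strands, or with a coordinate
inconsistency above 1 kb count as a global misassembly; an inconsistency in
(85 bp, 1 kb] on the same replicon/strand counts as a local one.  Blocks
shorter than 65 bp or more than 5% divergent are discarded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .io_seq import ContigSet, revcomp

logger = logging.getLogger(__name__)

ANCHOR_K = 21
MIN_BLOCK_LEN = 65
MAX_BLOCK_DIV = 0.05
LOCAL_GAP_MAX = 1000
LOCAL_GAP_MIN = 85

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentBlock:
    """One colinear contig-to-reference alignment segment.

    Intervals are 0-based half-open; for strand '-', increasing contig
    coordinate corresponds to decreasing reference coordinate.
    """

    contig_id: str
    qstart: int
    qend: int
    ref_id: str
    rstart: int
    rend: int
    strand: str
    mismatches: int
    indels: int
    indel_bases: int = 0

    @property
    def qlen(self) -> int:
        return self.qend - self.qstart

    @property
    def rlen(self) -> int:
        return self.rend - self.rstart

    @property
    def score(self) -> int:
        return self.qlen - self.mismatches - self.indel_bases


@dataclass
class EvalReport:
    """Full assembly metric panel."""

    num_contigs: int
    total_len: int
    n50: int
    ng50: int
    na50: int
    nga50: int
    genome_fraction: float
    duplication_ratio: float
    misassemblies_global: int
    misassemblies_local: int
    mp100k: float
    ip100k: float
    unaligned_len: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# -- Nx statistics ----------------------------------------------------------

def _nx(lengths: Sequence[int], target: float) -> int:
    """Largest L such that lengths >= L sum to >= target (0 if never)."""
    total = 0
    for length in sorted(lengths, reverse=True):
        total += length
        if total >= target:
            return length
    return 0


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L cover half the assembly."""
    lengths = list(lengths)
    if not lengths or any(l <= 0 for l in lengths):
        raise ValueError("n50 requires a nonempty list of positive lengths")
    return _nx(lengths, sum(lengths) / 2)


def ng50(lengths: Sequence[int], genome_len: int) -> int:
    """Like N50 but against half the *genome* length; 0 when unreachable."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    lengths = list(lengths)
    if not lengths:
        return 0
    return _nx(lengths, genome_len / 2)


# -- alignment --------------------------------------------------------------

def _parse_cigar(cigar: str) -> tuple[int, int, int]:
    """(mismatch_bases_upper_bound_aware, indel_events, indel_bases).

    With edlib's extended CIGAR mismatches come from 'X' runs; if a plain
    'M' CIGAR ever appears, mismatches are recovered by the caller from
    editDistance - indel_bases.
    """
    mismatches = indel_events = indel_bases = 0
    for num, op in _CIGAR_RE.findall(cigar or ""):
        n = int(num)
        if op == "X":
            mismatches += n
        elif op in "ID":
            indel_events += 1
            indel_bases += n
    return mismatches, indel_events, indel_bases


def _chain_hits(
    hits: list[tuple[int, int]], max_gap: int = 1200, band: int = 60
) -> list[list[tuple[int, int]]]:
    """Group anchor hits (q, r) into colinear chains per diagonal band."""
    chains: list[list[tuple[int, int]]] = []
    hits = sorted(hits, key=lambda h: (h[1] - h[0], h[0]))
    cur: list[tuple[int, int]] = []
    for q, r in hits:
        if cur:
            pq, pr = cur[-1]
            same_band = abs((r - q) - (pr - pq)) <= band
            if same_band and 0 <= q - pq <= max_gap:
                cur.append((q, r))
                continue
            chains.append(cur)
        cur = [(q, r)]
    if cur:
        chains.append(cur)
    # merge colinear chains split by the diagonal sort (q-sorted second pass)
    chains.sort(key=lambda c: c[0][0])
    return chains


def _ref_index(reference: ContigSet, k: int, max_occ: int = 64) -> dict:
    index: dict[str, list[tuple[str, int]]] = {}
    for contig in reference:
        seq = contig.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            occ = index.setdefault(kmer, [])
            if len(occ) < max_occ:
                occ.append((contig.id, i))
    return index


def align_contigs(
    contigs: ContigSet,
    reference: ContigSet,
    anchor_k: int = ANCHOR_K,
    max_div: float = MAX_BLOCK_DIV,
) -> list[AlignmentBlock]:
    """All candidate alignment blocks of every contig against the reference.

    Each contig may yield several blocks (chimeras, repeats); blocks below
    65 bp or above *max_div* divergence are discarded.  Use
    :func:`select_blocks` to reduce candidates to one tiling per contig.
    """
    if len(contigs) == 0 or len(reference) == 0:
        return []
    index = _ref_index(reference, anchor_k)
    ref_seqs = {c.id: c.seq for c in reference}
    blocks: list[AlignmentBlock] = []
    for contig in contigs:
        for strand in "+-":
            query = contig.seq if strand == "+" else revcomp(contig.seq)
            qlen = len(query)
            per_ref: dict[str, list[tuple[int, int]]] = {}
            for i in range(qlen - anchor_k + 1):
                for rid, rpos in index.get(query[i : i + anchor_k], ()):
                    per_ref.setdefault(rid, []).append((i, rpos))
            for rid, hits in sorted(per_ref.items()):
                for chain in _chain_hits(hits):
                    qs = chain[0][0]
                    qe = chain[-1][0] + anchor_k
                    rs = min(r for _, r in chain)
                    re_ = max(r for _, r in chain) + anchor_k
                    if qe - qs < MIN_BLOCK_LEN:
                        continue
                    aln = edlib.align(
                        query[qs:qe], ref_seqs[rid][rs:re_], mode="NW", task="path"
                    )
                    dist = aln["editDistance"]
                    if dist > max_div * max(qe - qs, re_ - rs):
                        continue
                    mism, ind_ev, ind_b = _parse_cigar(aln.get("cigar"))
                    if mism + ind_b < dist:  # plain-M cigar fallback
                        mism = dist - ind_b
                    if strand == "+":
                        b_qs, b_qe = qs, qe
                    else:
                        b_qs, b_qe = qlen - qe, qlen - qs
                    blocks.append(
                        AlignmentBlock(
                            contig.id, b_qs, b_qe, rid, rs, re_, strand,
                            mism, ind_ev, ind_b,
                        )
                    )
    return blocks


def select_blocks(blocks: list[AlignmentBlock]) -> dict[str, list[AlignmentBlock]]:
    """Greedy best-scoring non-overlapping tiling per contig.

    Candidates are taken in decreasing score order (ties: leftmost reference
    position), rejecting any block that overlaps an already chosen block by
    more than 20 bp on the contig.  Returns contig_id -> blocks sorted by
    contig coordinate.
    """
    by_contig: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_contig.setdefault(b.contig_id, []).append(b)
    out: dict[str, list[AlignmentBlock]] = {}
    for cid, cand in by_contig.items():
        cand.sort(key=lambda b: (-b.score, b.ref_id, b.rstart, b.strand, b.qstart))
        chosen: list[AlignmentBlock] = []
        for b in cand:
            overlap = sum(
                max(0, min(b.qend, c.qend) - max(b.qstart, c.qstart))
                for c in chosen
            )
            if overlap <= 20:
                chosen.append(b)
        chosen.sort(key=lambda b: b.qstart)
        if chosen:
            out[cid] = chosen
    return out


# -- misassemblies ----------------------------------------------------------

def detect_misassemblies(
    blocks: Sequence[AlignmentBlock],
    local_gap_max: int = LOCAL_GAP_MAX,
) -> tuple[int, int, list[tuple[str, int, str]]]:
    """Classify junctions between adjacent blocks of one contig.

    Returns (global_count, local_count, breakpoints) where each breakpoint
    is (contig_id, contig_position, kind).  A junction is *global* when the
    flanks map to different replicons, different strands, or with a
    reference-coordinate inconsistency > *local_gap_max*; it is *local*
    when the inconsistency is in (85, local_gap_max].
    """
    glob = loc = 0
    breakpoints: list[tuple[str, int, str]] = []
    ordered = sorted(blocks, key=lambda b: b.qstart)
    for b1, b2 in zip(ordered, ordered[1:]):
        pos = b2.qstart
        if b1.ref_id != b2.ref_id or b1.strand != b2.strand:
            glob += 1
            breakpoints.append((b1.contig_id, pos, "global"))
            continue
        qgap = b2.qstart - b1.qend
        if b1.strand == "+":
            rgap = b2.rstart - b1.rend
        else:
            rgap = b1.rstart - b2.rend
        inconsistency = abs(rgap - qgap)
        if inconsistency > local_gap_max:
            glob += 1
            breakpoints.append((b1.contig_id, pos, "global"))
        elif inconsistency > LOCAL_GAP_MIN:
            loc += 1
            breakpoints.append((b1.contig_id, pos, "local"))
    return glob, loc, breakpoints


# -- rates and coverage ------------------------------------------------------

def rates_per_100kbp(blocks: Sequence[AlignmentBlock]) -> tuple[float, float]:
    """(mismatches, indel events) per 100 kbp of aligned assembly bases."""
    aligned = sum(b.qlen for b in blocks)
    if aligned <= 0:
        raise ValueError("rates are undefined with zero aligned bases")
    mism = sum(b.mismatches for b in blocks)
    ind = sum(b.indels for b in blocks)
    return mism * 100_000 / aligned, ind * 100_000 / aligned


def expected_mismatch_total(
    genome_len: int, genome_fraction: float, mp100k: float
) -> float:
    """Total mismatches implied by an MP100K rate over the aligned genome.

    ``genome_len`` in bases, ``genome_fraction`` in percent: a 5 Mbp genome
    fully covered at MP100K = 5 implies 250 mismatches.
    """
    return genome_len / 100_000 * (genome_fraction / 100.0) * mp100k


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def genome_fraction_and_duplication(
    blocks: Sequence[AlignmentBlock], reference: ContigSet
) -> tuple[float, float]:
    """(genome fraction in percent, duplication ratio).

    Fraction: covered reference positions / reference length * 100.
    Duplication: total aligned assembly bases per covered reference
    position (>= 1 whenever anything aligns).
    """
    ref_len = reference.total_len
    per_ref: dict[str, list[tuple[int, int]]] = {}
    aligned_ref_bases = 0
    for b in blocks:
        per_ref.setdefault(b.ref_id, []).append((b.rstart, b.rend))
        aligned_ref_bases += b.rlen
    covered = sum(
        e - s for ivals in per_ref.values() for s, e in _merge_intervals(ivals)
    )
    if covered == 0 or ref_len == 0:
        return 0.0, 0.0
    return covered / ref_len * 100.0, aligned_ref_bases / covered


# -- composite --------------------------------------------------------------

def _aligned_fragments(
    selected: dict[str, list[AlignmentBlock]], local_gap_max: int = LOCAL_GAP_MAX
) -> list[int]:
    """Contig fragment lengths after breaking at misassembly breakpoints."""
    fragments: list[int] = []
    for cid, blocks in selected.items():
        _, _, breakpoints = detect_misassemblies(blocks, local_gap_max)
        cuts = {pos for _, pos, _ in breakpoints}
        start = blocks[0].qstart
        prev_end = blocks[0].qend
        for b in blocks[1:]:
            if b.qstart in cuts:
                fragments.append(prev_end - start)
                start = b.qstart
            prev_end = b.qend
        fragments.append(prev_end - start)
    return fragments


def na50(contigs: ContigSet, reference: ContigSet) -> int:
    """N50 of aligned contig fragments (contigs broken at misassemblies)."""
    selected = select_blocks(align_contigs(contigs, reference))
    fragments = _aligned_fragments(selected)
    if not fragments:
        return 0
    return _nx(fragments, contigs.total_len / 2)


def evaluate_assembly(
    contigs: ContigSet,
    reference: ContigSet,
    min_contig_len: int = 200,
) -> EvalReport:
    """Compute the full metric panel for *contigs* against *reference*."""
    kept = ContigSet([c for c in contigs if len(c) >= min_contig_len])
    genome_len = reference.total_len
    if len(kept) == 0:
        return EvalReport(0, 0, 0, 0, 0, 0, 0.0, 0.0, 0, 0, 0.0, 0.0, 0)
    lengths = kept.lengths()
    total = kept.total_len
    selected = select_blocks(align_contigs(kept, reference))
    flat = [b for blocks in selected.values() for b in blocks]

    glob = loc = 0
    for blocks in selected.values():
        gl, lo, _ = detect_misassemblies(blocks)
        glob += gl
        loc += lo
    fragments = _aligned_fragments(selected)
    na50_val = _nx(fragments, total / 2) if fragments else 0
    nga50_val = _nx(fragments, genome_len / 2) if fragments else 0

    if flat:
        mp100k, ip100k = rates_per_100kbp(flat)
    else:
        mp100k = ip100k = 0.0
    fraction, duplication = genome_fraction_and_duplication(flat, reference)

    aligned_q = 0
    for cid, blocks in selected.items():
        aligned_q += sum(
            e - s for s, e in _merge_intervals([(b.qstart, b.qend) for b in blocks])
        )
    unaligned = total - aligned_q

    return EvalReport(
        num_contigs=len(kept),
        total_len=total,
        n50=n50(lengths),
        ng50=ng50(lengths, genome_len),
        na50=na50_val,
        nga50=nga50_val,
        genome_fraction=fraction,
        duplication_ratio=duplication,
        misassemblies_global=glob,
        misassemblies_local=loc,
        mp100k=mp100k,
        ip100k=ip100k,
        unaligned_len=unaligned,
    )
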