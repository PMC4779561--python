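"""Internal de Bruijn graph assembler.

The graph is edge-centric: k-mers are edges between (k-1)-mer nodes, and
every k-mer is stored canonically (lexicographic minimum of the k-mer and
its reverse complement) together with both oriented forms, so that degree
queries are plain dict lookups.  Cleaning removes short low-multiplicity
dead-end unitigs (tips) and pops near-identical parallel paths (bubbles);
edges contributed by seed contigs are *protected* and never removed.

Seeding implements contig-guided re-assembly: k-mers of the seed contigs are
injected with a high multiplicity, marked protected, and recorded as
*threads* — per-node (incoming k-mer -> outgoing k-mer) resolutions that let
unitig extension read through branch nodes which a seed contig traverses
unambiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import edlib

from .io_seq import Contig, ContigSet, ReadSet, revcomp
from .kmers import KmerTable, count_canonical

logger = logging.getLogger(__name__)

_BASES = "ACGT"

# sentinel marking a seed-thread junction crossed inconsistently by seeds
_AMBIGUOUS = ""


def count_kmers(reads: ReadSet | Iterable[str], k: int) -> KmerTable:
    """Count canonical k-mers over all N-free read windows.

    k must be odd (an even k admits reverse-complement palindromes, which
    make the canonical representative ambiguous).
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    seqs = reads.sequences() if isinstance(reads, ReadSet) else list(reads)
    return count_canonical(seqs, k)


@dataclass
class AssemblyOpts:
    """Tunable assembly parameters.

    Attributes
    ----------
    k
        k-mer size (odd).
    min_kmer_count
        k-mers seen fewer times are dropped before graph construction
        (2 for reads, 1 when assembling contigs).
    tip_len_factor
        tips shorter than ``tip_len_factor * k`` bases are clipping
        candidates.
    bubble_max_div
        maximum fractional divergence (and length difference) between two
        bubble arms for the lower-multiplicity arm to be removed.
    min_contig_len
        shortest emitted contig; defaults to ``2 * k``.
    seed_weight
        multiplicity given to each seed-contig k-mer occurrence; ``None``
        selects the median multiplicity of the retained read k-mers, 0
        disables seeding entirely.
    pop_min_keep
        when set, a bubble arm is only removed if its mean multiplicity is
        below this value (support threshold used by contig combining).
    """

    k: int = 31
    min_kmer_count: int = 2
    tip_len_factor: float = 2.0
    bubble_max_div: float = 0.05
    min_contig_len: Optional[int] = None
    seed_weight: Optional[float] = None
    pop_min_keep: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 3:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if self.min_kmer_count < 0 or self.tip_len_factor < 0 or self.bubble_max_div < 0:
            raise ValueError("thresholds must be >= 0")

    @property
    def effective_min_contig_len(self) -> int:
        return self.min_contig_len if self.min_contig_len is not None else 2 * self.k

    @property
    def tip_len(self) -> int:
        return int(self.tip_len_factor * self.k)


class DBGraph:
    """De Bruijn graph over canonical k-mers with multiplicities."""

    def __init__(
        self,
        k: int,
        multiplicities: Optional[Mapping[str, float]] = None,
        protected: Optional[Iterable[str]] = None,
    ) -> None:
        self.k = k
        self._mult: dict[str, float] = {}
        self._map: dict[str, str] = {}  # oriented k-mer -> canonical key
        self._protected: set[str] = set()
        if multiplicities:
            for km, c in multiplicities.items():
                self.add_edge(km, c)
        if protected:
            for km in protected:
                self.protect(km)

    # -- edge bookkeeping -------------------------------------------------
    @staticmethod
    def canon(kmer: str) -> str:
        return min(kmer, revcomp(kmer))

    def add_edge(self, kmer: str, mult: float, protected: bool = False) -> None:
        if len(kmer) != self.k:
            raise ValueError(f"edge length {len(kmer)} != k={self.k}")
        c = self.canon(kmer)
        self._mult[c] = self._mult.get(c, 0) + mult
        self._map[kmer] = c
        self._map[revcomp(kmer)] = c
        if protected:
            self._protected.add(c)

    def remove_edge(self, kmer: str) -> None:
        c = self._map.pop(kmer)
        self._map.pop(revcomp(kmer), None)
        del self._mult[c]
        self._protected.discard(c)

    def protect(self, kmer: str) -> None:
        c = self.canon(kmer)
        if c in self._mult:
            self._protected.add(c)

    def has_edge(self, kmer: str) -> bool:
        return kmer in self._map

    def mult(self, kmer: str) -> float:
        return self._mult[self._map[kmer]]

    def set_mult(self, kmer: str, value: float) -> None:
        self._mult[self._map[kmer]] = value

    def is_protected(self, kmer: str) -> bool:
        return self._map.get(kmer) in self._protected

    @property
    def edges(self) -> dict[str, float]:
        """Canonical k-mer -> multiplicity."""
        return self._mult

    @property
    def protected(self) -> set[str]:
        return self._protected

    @property
    def num_edges(self) -> int:
        return len(self._mult)

    def nodes(self) -> set[str]:
        """Canonical (k-1)-mers incident to at least one edge."""
        out: set[str] = set()
        for km in self._mult:
            for o in (km, revcomp(km)):
                out.add(self.canon(o[:-1]))
                out.add(self.canon(o[1:]))
        return out

    # -- oriented adjacency ------------------------------------------------
    def out_edges(self, node: str) -> list[str]:
        return [node + b for b in _BASES if node + b in self._map]

    def in_edges(self, node: str) -> list[str]:
        return [b + node for b in _BASES if b + node in self._map]

    def outdeg(self, node: str) -> int:
        return sum(1 for b in _BASES if node + b in self._map)

    def indeg(self, node: str) -> int:
        return sum(1 for b in _BASES if b + node in self._map)


def build_graph(table: KmerTable, min_count: int = 2) -> DBGraph:
    """Graph whose edges are exactly the k-mers with count >= min_count."""
    return DBGraph(table.k, table.filter(min_count))


def _walk_to_str(walk: list[str]) -> str:
    return walk[0] + "".join(e[-1] for e in walk[1:])


def _unitig_from(g: DBGraph, start: str) -> list[str]:
    """Maximal non-branching oriented walk through *start*."""
    walk = [start]
    seen = {g.canon(start)}
    e = start
    while True:  # extend right
        v = e[1:]
        if g.outdeg(v) != 1 or g.indeg(v) != 1:
            break
        nxt = g.out_edges(v)[0]
        c = g.canon(nxt)
        if c in seen:
            break
        walk.append(nxt)
        seen.add(c)
        e = nxt
    e = start
    while True:  # extend left
        v = e[:-1]
        if g.indeg(v) != 1 or g.outdeg(v) != 1:
            break
        prv = g.in_edges(v)[0]
        c = g.canon(prv)
        if c in seen:
            break
        walk.insert(0, prv)
        seen.add(c)
        e = prv
    return walk


def _all_unitigs(g: DBGraph) -> list[list[str]]:
    used: set[str] = set()
    out = []
    for km in sorted(g.edges):
        if km in used:
            continue
        walk = _unitig_from(g, km)
        for e in walk:
            used.add(g.canon(e))
        out.append(walk)
    return out


def _mean_mult(g: DBGraph, walk: list[str]) -> float:
    return sum(g.mult(e) for e in walk) / len(walk)


def clip_tips(g: DBGraph, max_tip_len: Optional[int] = None) -> DBGraph:
    """Remove short, weak dead-end spurs; iterates to a fixpoint.

    A unitig is a tip when exactly one of its ends is a dead end, its
    sequence is shorter than *max_tip_len* (default 2k) bases, and its mean
    multiplicity is strictly below the strongest sibling edge at the
    junction it hangs off.  Protected edges are never removed.
    """
    if max_tip_len is None:
        max_tip_len = 2 * g.k
    changed = True
    while changed:
        changed = False
        for walk in _all_unitigs(g):
            if not all(g.has_edge(e) for e in walk):
                continue  # partially removed earlier this sweep
            if g.k + len(walk) - 1 >= max_tip_len:
                continue
            if any(g.is_protected(e) for e in walk):
                continue
            start_v, end_v = walk[0][:-1], walk[-1][1:]
            dead_start = g.indeg(start_v) == 0
            dead_end = g.outdeg(end_v) == 0
            if dead_start == dead_end:
                continue  # isolated contig or internal unitig
            if dead_end:
                junction, attach = start_v, walk[0]
                siblings = [e for e in g.out_edges(junction) if e != attach]
                siblings += g.in_edges(junction)
            else:
                junction, attach = end_v, walk[-1]
                siblings = [e for e in g.in_edges(junction) if e != attach]
                siblings += g.out_edges(junction)
            if not siblings:
                continue
            if _mean_mult(g, walk) < max(g.mult(e) for e in siblings):
                for e in walk:
                    if g.has_edge(e):
                        g.remove_edge(e)
                changed = True
    return g


def _walk_arm(g: DBGraph, first: str, cap: int) -> tuple[str, list[str]]:
    """Follow a unitig from *first*; return (end node, oriented edges)."""
    path = [first]
    seen = {g.canon(first)}
    e = first
    while len(path) < cap:
        v = e[1:]
        if g.outdeg(v) != 1 or g.indeg(v) != 1:
            break
        nxt = g.out_edges(v)[0]
        c = g.canon(nxt)
        if c in seen:
            break
        path.append(nxt)
        seen.add(c)
        e = nxt
    return path[-1][1:], path


def pop_bubbles(
    g: DBGraph,
    max_div: float = 0.05,
    min_keep: Optional[float] = None,
) -> DBGraph:
    """Collapse two-arm bubbles onto the higher-multiplicity arm.

    Two vertex-disjoint unitig arms leaving one node and rejoining at
    another are a bubble when their length difference and edit divergence
    are both <= *max_div* (as a fraction of the longer arm).  The arm with
    the lower mean multiplicity is removed and its multiplicity added to
    the survivor; ties keep the lexicographically smaller arm sequence.
    Protected arms are never removed; with *min_keep* set, arms at or above
    that multiplicity are kept regardless (partition-support threshold).
    """
    cap = max(3 * g.k, 150)
    for _round in range(20):
        changed = False
        nodes: set[str] = set()
        for km in g.edges:
            nodes.add(km[:-1])
            nodes.add(revcomp(km)[:-1])
        for v in sorted(nodes):
            outs = g.out_edges(v)
            if len(outs) < 2:
                continue
            arms = [_walk_arm(g, e, cap) for e in sorted(outs)]
            popped = False
            for i in range(len(arms)):
                for j in range(i + 1, len(arms)):
                    end_a, arm_a = arms[i]
                    end_b, arm_b = arms[j]
                    if end_a != end_b:
                        continue
                    if not all(g.has_edge(e) for e in arm_a + arm_b):
                        continue
                    seq_a, seq_b = _walk_to_str(arm_a), _walk_to_str(arm_b)
                    longer = max(len(seq_a), len(seq_b))
                    if abs(len(seq_a) - len(seq_b)) > max_div * longer:
                        continue
                    dist = edlib.align(seq_a, seq_b, mode="NW", task="distance")[
                        "editDistance"
                    ]
                    if dist > max_div * longer:
                        continue
                    mult_a, mult_b = _mean_mult(g, arm_a), _mean_mult(g, arm_b)
                    if mult_a < mult_b:
                        loser, keeper, loser_mult = arm_a, arm_b, mult_a
                    elif mult_b < mult_a:
                        loser, keeper, loser_mult = arm_b, arm_a, mult_b
                    elif seq_a <= seq_b:  # tie: keep lexicographically smaller
                        loser, keeper, loser_mult = arm_b, arm_a, mult_b
                    else:
                        loser, keeper, loser_mult = arm_a, arm_b, mult_a
                    if any(g.is_protected(e) for e in loser):
                        continue
                    if min_keep is not None and loser_mult >= min_keep:
                        continue
                    for e in loser:
                        if g.has_edge(e):
                            g.remove_edge(e)
                    for e in keeper:
                        g.set_mult(e, g.mult(e) + loser_mult)
                    changed = True
                    popped = True
                    break
                if popped:
                    break
        if not changed:
            break
    return g


# -- seed threading --------------------------------------------------------

def build_threads(
    seeds: ContigSet, k: int
) -> tuple[dict[str, dict[str, str]], dict[str, dict[str, str]]]:
    """Per-node junction resolutions from seed contig traversals.

    Returns (fwd, rev): ``fwd[node][in_kmer] = out_kmer`` for every internal
    node of every seed contig (both orientations).  Conflicting resolutions
    are marked ambiguous and ignored during extension.
    """
    fwd: dict[str, dict[str, str]] = {}
    rev: dict[str, dict[str, str]] = {}
    for contig in seeds:
        for s in (contig.seq, revcomp(contig.seq)):
            if len(s) <= k or "N" in s:
                continue
            for i in range(len(s) - k):
                v = s[i + 1 : i + k]
                a = s[i : i + k]
                b = s[i + 1 : i + k + 1]
                d = fwd.setdefault(v, {})
                d[a] = b if d.get(a, b) == b else _AMBIGUOUS
                d = rev.setdefault(v, {})
                d[b] = a if d.get(b, a) == a else _AMBIGUOUS
    return fwd, rev


def _extend(
    g: DBGraph,
    start: str,
    threads: Optional[tuple[dict, dict]],
) -> list[str]:
    """Extend both ways from *start*: unitig rule, then seed threading."""
    walk = [start]
    visits = {g.canon(start): 1}

    def step(e: str, forward: bool) -> Optional[str]:
        v = e[1:] if forward else e[:-1]
        if forward:
            if g.outdeg(v) == 1 and g.indeg(v) == 1:
                return g.out_edges(v)[0]
            if threads is not None:
                nxt = threads[0].get(v, {}).get(e)
                if nxt and g.has_edge(nxt):
                    return nxt
        else:
            if g.indeg(v) == 1 and g.outdeg(v) == 1:
                return g.in_edges(v)[0]
            if threads is not None:
                prv = threads[1].get(v, {}).get(e)
                if prv and g.has_edge(prv):
                    return prv
        return None

    e = start
    while True:
        nxt = step(e, forward=True)
        if nxt is None:
            break
        c = g.canon(nxt)
        if visits.get(c, 0) >= 2:  # bounded repeat traversal
            break
        visits[c] = visits.get(c, 0) + 1
        walk.append(nxt)
        e = nxt
    e = start
    while True:
        prv = step(e, forward=False)
        if prv is None:
            break
        c = g.canon(prv)
        if visits.get(c, 0) >= 2:
            break
        visits[c] = visits.get(c, 0) + 1
        walk.insert(0, prv)
        e = prv
    return walk


def extract_contigs(
    g: DBGraph,
    opts: Optional[AssemblyOpts] = None,
    threads: Optional[tuple[dict, dict]] = None,
) -> ContigSet:
    """Emit maximal unitigs (seed-threaded across resolved junctions).

    Each contig is reported once, in canonical orientation, with length
    >= ``opts.min_contig_len``.  Iteration order is sorted, so output is
    fully deterministic.
    """
    if opts is None:
        opts = AssemblyOpts(k=g.k, min_contig_len=2 * g.k)
    min_len = opts.effective_min_contig_len
    used: set[str] = set()
    seqs: list[str] = []
    for km in sorted(g.edges):
        if km in used:
            continue
        walk = _extend(g, km, threads)
        for e in walk:
            used.add(g.canon(e))
        seq = _walk_to_str(walk)
        seq = min(seq, revcomp(seq))
        if len(seq) >= min_len:
            seqs.append(seq)
    seqs = sorted(set(seqs), key=lambda s: (-len(s), s))
    return ContigSet(
        [Contig(f"contig_{i}", s) for i, s in enumerate(seqs)]
    )


def assemble(
    reads: ReadSet,
    opts: AssemblyOpts,
    seeds: Optional[ContigSet] = None,
) -> ContigSet:
    """Full pipeline: count -> (inject seeds) -> build -> clean -> extract.

    When *seeds* are given (and ``opts.seed_weight`` is not 0), every seed
    k-mer occurrence is added with multiplicity ``seed_weight``, its edges
    are protected from cleaning, and unitig extension may read through
    branch nodes that the seeds traverse unambiguously.
    """
    k = opts.k
    usable = [r for r in reads if len(r.seq) >= k]
    if not usable:
        logger.warning("all %d reads shorter than k=%d; empty assembly", len(reads), k)
        return ContigSet([])
    table = count_kmers(reads, k)
    mult: dict[str, float] = table.filter(opts.min_kmer_count)

    threads = None
    protected: set[str] = set()
    if seeds is not None and len(seeds) > 0 and opts.seed_weight != 0:
        weight = opts.seed_weight
        if weight is None:
            weight = max(1.0, table.median_multiplicity(opts.min_kmer_count))
        seed_table = count_canonical(seeds.sequences(), k)
        for km, c in seed_table.items():
            mult[km] = mult.get(km, 0) + c * weight
            protected.add(km)
        threads = build_threads(seeds, k)
        logger.info(
            "seeded %d k-mers from %d contigs at weight %.1f",
            seed_table.n_distinct, len(seeds), weight,
        )

    g = DBGraph(k, mult, protected)
    for _ in range(4):
        before = g.num_edges
        clip_tips(g, opts.tip_len)
        pop_bubbles(g, opts.bubble_max_div, min_keep=opts.pop_min_keep)
        if g.num_edges == before:
            break
    return extract_contigs(g, opts, threads)
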