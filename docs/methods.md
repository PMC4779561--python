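# Methods

## The hierarchical assembly model

Given a single short-insert library with very high coverage C (100–200x for
a bacterial-scale genome), the package implements four assembly flows over
one internal de Bruijn graph (dBG) assembler:

* **B(k, c)** — *basic*: assemble all reads together at k-mer size k.
* **M(k, p, c)** — *merged*: split the reads into p disjoint partitions of
  N/p reads each, assemble every partition independently at k, and take the
  plain multiset union of the partition contigs.
* **C(k, p, c)** — *combined*: additionally assemble the merged contigs
  together (as long unpaired reads) at k=31, producing a deduplicated
  consensus set.
* **HGA(k', contigs)** — *re-assembly*: assemble the whole read set again at
  k', with the merged or combined contigs injected as high-weight,
  protected seed paths.

The rationale is a coverage/complexity trade-off.  Sequencing errors induce
tips and bubbles in the dBG; the number of error structures that survive an
abundance cutoff grows superlinearly with coverage (two independent reads
must repeat the same error at the same position).  Partitioning to ~C/p
coverage therefore yields graphs with far fewer surviving error artifacts,
and the partition contigs — though shorter and gappier — are cleaner.
Re-assembly recovers length: the full read set restores the high coverage,
while the stage-2 contigs protect and weight the true paths at branch
points and bridge coverage gaps.  Merged contigs are deliberately *not*
deduplicated: a contig produced by several partitions enters re-assembly
with multiplicity up to p, which is exactly the branch support that makes
the merged flow the stronger variant.

## The internal assembler

The dBG is edge-centric: k-mers are edges between (k−1)-mer nodes.  Every
k-mer is stored once under its canonical form (lexicographic minimum of the
k-mer and its reverse complement); both oriented forms are indexed so degree
queries are O(1) dict lookups.  k must be odd (even k admits
reverse-complement palindromes whose canonical class is ambiguous); k-mers
containing N are dropped.  Counting packs windows into 2-bit integers (one
uint64 for k ≤ 31, a (hi, lo) pair up to k = 62) with a logarithmic
doubling scheme and aggregates them with a vectorized sort, which keeps a
10⁷-base counting pass at a few seconds; correctness is pinned to a
brute-force Python oracle in the test suite.

Cleaning and extraction:

* **Abundance cutoff** `min_kmer_count` — default 2 for reads (drops
  singleton error k-mers), 1 when the input is contigs (every contig k-mer
  matters).
* **Tip clipping** — a unitig with exactly one dead end, sequence shorter
  than `tip_len_factor * k` (default 2k) bases, and mean multiplicity
  strictly below the strongest sibling edge at its junction is removed;
  iterated to a fixpoint.
* **Bubble popping** — two vertex-disjoint unitig arms sharing both
  endpoints whose length difference and edlib edit divergence are both ≤
  `bubble_max_div` (default 5%) collapse onto the higher-multiplicity arm;
  the loser's mean multiplicity is added to the survivor.  Ties keep the
  lexicographically smaller arm sequence.  A single substitution at k = 21
  makes a 41 bp arm (2.4% divergence), comfortably inside the default; at
  k = 7 the same arm would be 13 bp (7.7%) — the threshold is calibrated to
  the k range the assembler actually uses (k ≥ 15 in practice, 21–41 in the
  canned scenarios).
* **Contig extraction** — maximal unitigs, emitted once in canonical
  orientation, length ≥ `min_contig_len` (default 2k), in sorted edge
  order, so the assembler is fully deterministic and needs no random seed.

**Seeding.**  When seed contigs are given, each seed k-mer occurrence is
added with multiplicity `seed_weight` (default: the median multiplicity of
the retained read k-mers, which makes seed edges competitive at branch
points), marked *protected* (never removed by cleaning), and every internal
seed position is recorded as a per-node junction resolution
(in-k-mer → out-k-mer).  During extraction a walk may read through a branch
node when the seeds traverse it unambiguously.  The resolution context is a
single (k−1)-mer, so seeding bridges coverage gaps and resolves
error-induced branching but deliberately does not phase exact repeats
longer than k — repeats longer than the read length remain the hard floor
on contiguity, as they should.  `seed_weight=0` disables seeding entirely,
which makes the degenerate flow HGA(p=1, merged, k_pre=k_re) reduce exactly
to the basic flow.

**Combining.**  The combined flow assembles the merged contigs with
`min_kmer_count=1` and a bubble support threshold `pop_min_keep = p/2`: a
variant arm supported by at least half the partitions is never collapsed.
This is this package's analog of giving the combining assembler an
"expected coverage" equal to the number of partitions — support, not
sequencing depth, is what the multiplicities mean at this stage.

## Partitioning

Round-robin by pairing unit (pair i → partition i mod p): deterministic,
seed-free, mates always stay together, partition sizes differ by at most
one pair, and coverage per partition is near-uniform.  A partition below
10x coverage is refused (the error message reports the maximum admissible
p); the check requires a genome-length hint and is skipped with a warning
without one.

## Evaluation

The metric panel is recomputed from first principles (not by wrapping an
external evaluator): contigs are aligned by exact 21-mer anchor chaining
per diagonal band, each chain scored with a full edlib alignment across its
span, and a greedy best-score tiling (ties resolved to the leftmost
reference position, so planted repeats land deterministically) selects the
blocks per contig.  Blocks under 65 bp or over 5% divergence are dropped.
Adjacent blocks of one contig flag a **global misassembly** when they map
to different replicons, different strands, or with a reference-coordinate
inconsistency > 1 kb, and a **local misassembly** for inconsistencies in
(85 bp, 1 kb] — the conventional relocation thresholds.  NA50/NGA50 break
contigs at these breakpoints and trim to aligned regions before the Nx
scan (normalized by total assembly / genome length respectively, so
NA50 ≤ N50 and NGA50 ≤ NG50 hold by construction).  MP100K and IP100K are
mismatches and indel *events* per 100 kbp of aligned assembly bases;
genome fraction is the percentage of reference positions covered;
duplication ratio is aligned assembly bases per covered reference
position.  All intervals are 0-based half-open internally.  NG50 follows
the standard definition — the largest L such that contigs ≥ L accumulate
at least half the *genome* length (so [100, 50, 30, 20] against a 400 bp
genome gives 20, reaching the 200-base target only at the last contig).
The contig length floor for evaluation is 200 bp (a desk-scale reduction
of the conventional 500 bp default, proportionate to the 10⁴–10⁵ base
genomes used here); it is configurable.

A small helper exposes the mismatch-budget arithmetic used when reasoning
about contig correctness: a genome of G bases at genome fraction f% and
MP100K m implies `G/100000 * f/100 * m` total mismatches — 250 for a fully
covered 5 Mbp genome at MP100K = 5.  This is why per-100-kbp rates dominate
misassembly counts (typically tens) as a correctness signal for the
re-assembly stage.

## The simulator

`simulate_genome` draws i.i.d. bases at a target GC fraction, optionally as
several replicons (chromosome + plasmids), and plants exact repeat families
at recorded non-overlapping positions.  `simulate_reads` samples fragment
positions uniformly (replicons weighted by length), flips orientation with
probability 0.5, and applies i.i.d. substitutions (to a uniformly chosen
different base) and single-base indels; quality strings are constant 'I'.
Fragments that would overrun a replicon end are resampled — no circularity.
Read count is round(G·C/L), rounded to pair parity; paired fragments are
Normal(insert_mean, insert_sd) clipped below at L.  Defaults (100 bp reads,
100x, 300±30 bp inserts, 1% substitutions) emulate a cleaned high-coverage
HiSeq-style library on a desk-scale genome.

What the simulator does *not* model — and what passing tests therefore do
not demonstrate — includes position- and context-dependent error spectra,
quality-value information (the assembler never reads qualities), GC
coverage bias, chimeric fragments, and biological repeat structure beyond
planted exact copies.  Conclusions transfer qualitatively, not numerically,
to real libraries.

## Study scenarios and problem sizes

Two canned scenarios (`hga.experiments`) drive validation and the
results-reproduction script:

* **Ideal case** — repeat-free 20 kb genome, error-free 50x single-end
  100 bp reads.  Any k in {21, 31, 41} reconstructs the genome as a single
  contig (≥ 99.9% genome fraction, zero misassemblies); read-start taper at
  the linear ends costs a handful of terminal bases under the abundance
  cutoff, which is why the fraction is not exactly 100%.
* **Repeat scenario** — 100 kb genome with planted repeats (2 x 300 bp,
  2 x 800 bp, all longer than the 100 bp reads), 100x paired reads.  With
  1% substitution errors, the basic flow is error-limited (at 100x enough
  coincident-error k-mers survive the abundance cutoff to fragment the
  graph, worst at short k), while 25x partitions assemble cleanly;
  HGA(merged, p=4, k_pre=21, k_re=41) consistently reaches the
  repeat-limited contiguity ceiling and beats the best basic flow severalfold
  in NA50.  With error-free reads every flow hits that ceiling and the
  combined-flow/basic NA50 ratio is 1 — the improvement exists only where
  there are errors to correct, which is the method's central claim.

The scenario sizes (10⁴–10⁵ base genomes, 5 replicate seeds with errors and
3 without) are the package's chosen desk-scale study conditions: large
enough for ~10⁷-base libraries and stable medians, small enough that the
full validation suite runs in minutes on one CPU.

## Known limitations

* Paired-end information is used only to keep mates in one partition;
  there is no scaffolding, gap filling, or insert-size-based repeat
  resolution.
* Seed threading context is one (k−1)-mer: repeats longer than k are not
  phased by seeds.
* The anchor-chaining aligner assumes ≤ ~5% divergence and anchors at
  least every ~1.2 kb; it is an evaluation tool for near-identical
  assemblies, not a general-purpose aligner.
* Indel-heavy error models (err_indel approaching err_sub) shift bubble
  arms' lengths and are cleaned less effectively than substitutions.
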