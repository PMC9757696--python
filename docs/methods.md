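# Methods

This note documents the models, parameters and numerical choices behind
`targetasm`, and what its simulation-based tests do and do not demonstrate.

## Reference database and k-mer index

A reference database is a directory of FASTA files, one per target gene, each
holding one or more homologous nucleotide sequences from related taxa (a
combined single-FASTA layout, with the gene id as the token after the last
`-` in each header, is also accepted). The *target length* of a gene is the
arithmetic mean length of its references; it is the denominator for
recovered-fraction and the T50 statistic.

The index maps every forward-strand k-mer of every reference to the genes it
occurs in, with two statistics per (k-mer, gene) pair: the occurrence count
and the mean fractional position. The fractional position of an occurrence
starting at offset `start` in a reference of length `L` is `start / (L - k)`
(0 when `L = k`), so positions span [0, 1] regardless of reference length.
All homologs of a gene are pooled with equal weight per occurrence; k-mers
containing any base outside A/C/G/T are skipped. The index is forward-strand
only so that positional statistics stay in reference orientation; strand
symmetry is handled on the read side. The whole table is held in RAM — for a
353-gene panel (≤ 2 kb per gene, a few homologs each) it is on the order of
a million entries.

## Read filtering

Reads are classified by exact k-mer sharing: a read is split into k-mers at
offsets 0, step, 2·step, …, its reverse complement likewise, and every k-mer
is looked up in the hash table. A gene whose references share at least
`min_hits` k-mers with the read claims it. Defaults: `k = 31`, `step = 1`,
`min_hits = 1`. Long k-mers with no mismatch tolerance keep the match
specific; raising `step` trades sensitivity for speed and raising `min_hits`
tightens specificity. A read may enter several gene bins (bins are
independent assembly problems). With paired input, a match by either mate
recruits both (pair rescue, on by default): mates reaching past a gene's
flanks improve contiguity. Matched-read sets are independent of input order
and of the number of worker threads; threaded filtering classifies
fixed-size chunks and merges them in submission order, so its output is
identical to the single-threaded run.

## Assembly

Each bin is assembled on a de Bruijn graph at an assembly k (`k = 41` by
default) chosen independently of the filtering k. Nodes are the N-free
k-mers of the bin's reads counted in both orientations; a directed edge u→v
exists when the (k−1)-suffix of u equals the (k−1)-prefix of v (edges are
implicit in the node set, so out-degree is at most 4). Nodes below
`min_count` are pruned; the default is 1 — no pruning — because recovery at
1× depth cannot afford to lose singleton signal. Each node also carries the
mean fractional position of its k-mer on this gene's references (absent for
unreferenced k-mers), computed from an index built at the assembly k over
the gene's homologs only.

The walk starts at the most abundant k-mer (ties: lexicographically
smallest) and extends right, then left, under a shared visit-once
constraint, seeking a long path. At a branch every unvisited neighbour is
scored

    W = count ** (1 - pos_delta)

with `pos_delta` the absolute difference of the two nodes' mean fractional
reference positions, or 1 when either node is unreferenced. A positionally
consistent candidate keeps near-full abundance weight; positional outliers
and unreferenced candidates decay to weight 1, the floor for any count, so
an unreferenced k-mer never outranks a positionally consistent referenced
one yet still extends unbranched regions. Ties on weight are broken by
abundance, then lexicographically — abundance is the only signal at branches
where no candidate is referenced, which at realistic reference divergence
(5% — where only ~a third of truth k-mers match a homolog exactly at k=41)
is the common case; a purely lexicographic tie-break would pick
sequencing-error branches about half the time there.

**Tip-aware backtracking.** A pure greedy walk has a failure mode we observed
at high depth: a sequencing error that reproduces a homolog's base creates a
low-count k-mer that *is* referenced (small positional jump, weight
count^(1−δ) ≈ count) and outweighs the true successor when the latter is
unreferenced (weight 1); if that error sits near a read end, the branch
dead-ends inside the read tail and the contig is truncated mid-gene. The
walk therefore treats dead ends reached within k nodes of the most recent
open branch as tip artifacts: it backtracks to that branch, tries the
next-ranked candidate, and finally keeps the longest completion (first
explored wins ties). Branches left more than k nodes behind are committed
and never reopened, which keeps the walk effectively linear and fully
deterministic. The k-node window matches the maximal span of k-mers a single
read error can corrupt. One consequence: at ragged low-coverage contig tips
the longest branch may come from an erroneous read that reaches furthest,
trading one substitution for a few extra true bases — visible as a small
residual base-error rate concentrated near contig ends.

If the best contig is shorter than `min_length` (default k + 20, a cutoff
suppressing trivial seed-only output), up to 4 further seeds are tried in
decreasing-abundance order; the first contig reaching `min_length` is
returned, otherwise the one visiting the most nodes, or none. One contig per
gene is emitted; disconnected components are not scaffolded and paralogs are
not separated.

## Evaluation

A recovered contig is aligned to its gold-standard sequence with Biopython's
`PairwiseAligner`, semi-global: match +1, mismatch −1, gap open −2, gap
extend −1, end gaps on the contig side free, because contigs are partial by
nature and truth overhang must not count as error. The orientation (forward
or reverse complement) with the higher score is used, making the rates
strand symmetric.

* base-calling error rate = mismatching both-base columns / all both-base
  columns;
* indel error rate = gap columns inside the aligned span / span length.

Rates are reported per gene and as aggregates pooled over genes (total
errors / total aligned length). An alignment covering fewer than 20 bases
yields no rates, and a sequence is *invalid* when unaligned or above a 5%
base-error threshold (configurable; the correct/invalid boundary is a
reporting convention, not a property of the alignment). T50 counts genes
with `recovered_length ≥ 0.5 × target_length`.

## Read simulator

The simulator emulates a controlled verification protocol. Truth sequences
are uniform random DNA with lengths uniform in 400–2000 bp (the longest
targets in Angiosperms353-style panels stay around 2 kb); each gene gets 3
reference homologs derived from the truth by independent per-base
substitution at 5% — congeneric-scale divergence, matching the recommended
practice of building the database from the target's genus or family. Reads
are 150 bp pairs from fragments with Normal(350, 35) insert lengths clamped
to [read length, gene length] and uniform starts;
`round(depth · L / (2 · 150))` pairs per gene give realized coverage within
10% of nominal from 5× up. Sequencing errors are independent per-base
substitutions at 0.5% with uniform alternative bases and constant quality
strings. Every read id records its gene of origin, so filtering purity is
auditable. All outputs are reproducible bit-for-bit from the configuration
seed (two independent RNG streams: gene family and reads).

The model deliberately omits empirical quality profiles, indel read errors
(available as a config extension, off by default), PCR duplicates,
contamination, organelle background and paralogy. Tests passing on this
simulator therefore demonstrate the pipeline's algorithmic correctness and
its depth–accuracy behavior, not robustness to every artifact of real
libraries — in particular, paralog separation is explicitly out of scope.

## Verification protocol and measured behavior

The acceptance suite runs a 353-gene simulated family through the full
pipeline at depths 1/5/10/20/50× (fixed seed) and asserts the qualitative
depth-gradient: aggregate base-calling and indel error rates non-increasing
with depth, valid recovered genes non-decreasing, and aggregate base error
below 1% at 10× and deeper. `scripts/acceptance.py` recomputes the
10/20/50× runs from scratch for any seed and reports the worst-depth
aggregate base error in percent. Problem sizes (353 genes, ≤ 2 kb, depths to
50×) were chosen to mirror a realistic panel while keeping a full run in the
minutes range on one CPU.

## Known limitations

* Single contig per gene: fragmented coverage (very low depth) yields the
  longest fragment only.
* Chimeric joins between a gene's forward and reverse-complement graph
  chains are not explicitly forbidden; they require a (k−1)-base sequence
  coincidence and are vanishingly rare at k = 41, but short assembly k on
  short repeats could produce them.
* The positional prior assumes references are collinear with the target
  (no rearrangement); exon/intron structure is not modeled — for genomic
  reads against CDS references, recovered sequences follow the reference
  coordinate system only where exact k-mers anchor.
* Memory grows with total reference length; very large reference sets
  should be thinned to the nearest relatives, which also sharpens the
  positional prior.
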