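# Methods

`hicphase` reconstructs chromosome-scale, haplotype-resolved scaffolds
from two inputs: a diploid assembly sequence graph (GFA1) and Hi-C
paired-end reads. It also provides the reverse direction — a
reference-free switch/hamming evaluation of any phased assembly pair
from Hi-C reads alone — and a seeded synthetic-data generator used to
validate the whole pipeline against known truth.

## The model

A diploid assembly graph G = (N, E) is bidirected: every node carries a
DNA sequence walkable in either orientation, and an edge
(a, +, b, +) is identical to its mirror (b, −, a, −). Heterozygous
variation appears as *bubbles*: a source/sink pair of oriented nodes
whose interior branches (alleles) carry the two haplotypes' sequences.
Long-range Hi-C contacts connect loci megabases apart on the *same*
chromosome copy, so read pairs anchored in two alleles reveal which
alleles co-occur on one haplotype — within a component and across
components.

The pipeline is:

1. **Bubble detection** (`bubbles`). Minimal superbubbles are found on
   the doubled directed view of the bidirected graph with a
   single-source frontier expansion: a vertex is admitted only when all
   of its parents have been visited, and the walk reports the first
   moment the frontier collapses to a single exit. Candidates are
   deduplicated against reverse-complement mirrors and filtered to the
   innermost set, so reported interiors are pairwise disjoint. Alleles
   are the distinct interior source→sink paths; bubbles whose alleles
   are not vertex-disjoint, or which exceed `max_alleles` (default 16)
   paths, are flagged complex, kept in the graph through their longest
   branch, and excluded from phasing.
2. **Bubble chains** (`bubbles.chain_bubbles`). Each component's
   backbone (non-interior nodes plus one virtual edge per bubble) is
   walked from its lexicographically smallest endpoint, yielding the
   ordered bubbles and the homozygous linking segments between them.
   A branch in the backbone that is not itself a bubble truncates the
   chain with a warning rather than guessing a path.
3. **k-mer Hi-C mapping** (`hic_map`). Every node-internal canonical
   k-mer (k = 31 by default; strand-folded because Hi-C reads arrive on
   arbitrary strands) is censused across the whole graph; k-mers
   occurring at exactly one location become barcodes — for one allele
   of one bubble, or for one homozygous node. Requiring *global*
   uniqueness rather than mere distinctness between a bubble's two
   alleles keeps repeats from attracting reads. Read ends are assigned
   by exact barcode match with heterozygous priority: hits on exactly
   one allele assign the end to that allele even when the read also
   overlaps flanking homozygous sequence; hits on two alleles, or on
   two homozygous nodes with no allele, are ambiguous and the whole
   pair is discarded — counts feed hard thresholds, so no fractional
   assignment is made. Counting is order-independent; each counted pair
   also records the exact hit coordinates of both ends for the
   scaffolder's contig-end bookkeeping.
4. **Chain phasing** (`phase`). For every bubble pair of a chain with
   link evidence (all pairs, not only adjacent — Hi-C is long-range),
   the two consistent allele pairings are scored: cis = the better
   pairing's summed support, trans = the other's. Pairs are processed
   greedily by descending margin |cis − trans| and join their phase
   groups through union–find with relative-phase parity only when
   max(cis, trans) is *strictly* greater than `min_support` (default
   5 read pairs). An earlier join is never overturned; conflicting
   pairs are skipped and counted. Groups become phase blocks; within a
   block the leading bubble's first allele defines haplotype 1, an
   arbitrary but deterministic choice (global assignment happens during
   scaffolding). The two haplotype paths share every linking segment
   and select complementary alleles at every phased bubble; sequences
   are spelled by concatenation with edge-overlap trimming.
5. **Phased scaffolding** (`scaffold`). Link counts are re-aggregated
   onto contigs: allele-resolved links carry haplotype identity and
   vote on how two contigs' haplotypes pair up (straight vs cross);
   homozygous-node links are haplotype-blind and are shared at half
   weight, rounded down. The phased scaffold graph has one node per
   oriented haplotype contig; each edge carries its Hi-C coverage e and
   the confidence e/(i + j), where i and j are the summed coverages of
   the other edges at its endpoints (an isolated pair scores the
   defined maximum 1.0). Partitioning into 2 × #chromosomes classes is
   greedy: long contigs (> `long_threshold`, default 10 Mb) first, by
   descending confidence, each contig keeping at most two joined
   neighbours and every accepted edge's confidence at least
   `conf_floor`; remaining contigs attach where their `p` (default 3)
   best-supported neighbours agree on one partition, longest first,
   with singleton partitions casting no veto. Haplotype parity is
   propagated through every join, so the second haplotype's scaffolds
   are derived by relabelling — never re-partitioned. Contigs are then
   ordered by greedy path insertion on head/tail-corner contact density
   and oriented from the end-window support, followed by one correction
   sweep (flips, adjacent swaps). Scaffolds are spelled with 100-N gaps.
6. **Evaluation** (`evaluate`). Heterozygous 31-mers (canonical k-mers
   present exactly once across an assembly's two haplotypes) are
   collapsed into het *sites* — maximal runs of overlapping het k-mers,
   so one variant is one site — and paired across haplotypes by
   co-linear order. Hi-C read pairs anchored on two consecutive sites
   tally same- versus cross-haplotype support; a junction is a switch
   when cross support strictly exceeds 5 pairs and exceeds the same
   support. Switch rate = switches / sites. The hamming rate propagates
   the switch flips along each scaffold and counts minority-label sites
   (minimized over the two global labellings, since haplotype naming is
   arbitrary), which penalizes long switches in proportion to their
   extent. Inputs with no informative read pairs report *not
   evaluable* rather than zero. NG50 is the shortest sequence at half
   an assumed genome size G.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `k` | 31 | nt | barcode k-mer size (odd, 11–31); 31 suits human-scale genomes, smaller values help small synthetic genomes |
| `min_support` | 5 | read pairs | strict lower bound for phasing joins and switch calls (evidence must exceed it) |
| `max_alleles` | 16 | paths | bubble complexity cap |
| `long_threshold` | 10,000,000 | bp | contig length above which a contig seeds partitions in the greedy's first phase |
| `p` | 3 | contigs | neighbours that must agree for a short contig to attach |
| `conf_floor` | 0.2 | — | minimum e/(i+j) to accept a long-contig join |
| `head_frac` | 0.2 | — | terminal window fraction used as orientation evidence |
| `gap_len` | 100 | nt | N-gap between scaffolded contigs |

The confidence floor deserves a note: for a chain of contigs the two
true edges flanking a chain-interior edge already claim about two
thirds of its neighbourhood coverage, so genuine adjacent edges sit
near e/(i+j) ≈ 0.28. A floor of 0.2 still demands that a join carry a
fifth of its neighbourhood's coverage while not splitting chromosomes
at their midpoints; higher values (0.3+) systematically do.

## The synthetic study

`simulate` generates the validation universe: per chromosome a uniform
random reference, with the second haplotype carrying heterozygous SNPs
(rate `snp_rate`, default 0.1%/bp) and structural variants (insertions,
deletions, inversions of 50 bp–10 kb), all spaced at least 2k apart so
each variant region forms a clean bubble. The generated graph mirrors
what a HiFi assembler emits: variants closer than `bubble_span`
(default 4 kb) merge into one haplotype-block bubble whose two branches
carry each haplotype's sequence over the block — assembler unitig
branches span whole haplotype blocks, not single variants, and the
default support threshold (strictly >5 pairs per bubble pair) is only
meaningful at that granularity. With per-variant branches
(`bubble_span=0`, available for unit tests) the expected Hi-C support
between any two bubbles under the d^−α contact model is ~0.3 pairs
regardless of genome size, so a >5 threshold can never fire — a useful
negative control, not a usable study design. Homozygous stretches
between blocks become shared nodes split at `node_split` (50 kb);
`n_breaks` well-separated homozygous stretches per chromosome are cut
with the joining edge omitted, producing the multi-component graph the
scaffolder must reassemble. Which haplotype receives the
lexicographically smaller allele-node name is randomized per bubble so
no evaluation can lean on naming conventions.

Hi-C pairs number depth × G / (2 × read length). Both ends come from
one haplotype copy (probability 1 − `trans_noise`); the genomic
distance follows a d^−α density (α = 1, the standard contact-decay
exponent) truncated to [1 kb, chromosome length], and the second end is
reverse-complemented. Truth tables record haplotype and positions per
pair.

What the generator does **not** emulate: sequencing error by default
(a knob exists), restriction-site structure and religation artifacts,
inter-chromosomal background contacts, assembly errors (misjoins,
collapsed repeats), coverage biases, and polyploidy. Passing tests
therefore demonstrate algorithmic correctness under clean long-range
signal, not robustness to every artifact of real libraries; in real
data the same thresholds act against a noisier background.

## Numerical and implementation choices

- k-mers are packed into 64-bit words (hence k ≤ 31) and processed in
  bulk numpy passes; canonical form is the minimum of the forward and
  reverse-complement codes. A 2^24-entry membership table screens
  queries before binary search, since most read k-mers are not globally
  unique graph k-mers.
- All coordinates are 0-based half-open; conversion happens only at
  format boundaries (GFA/FASTA/FASTQ).
- Determinism: every ordering that touches a dict or a draw is given an
  explicit sort key (bubble ids, contig ids, lexicographic node names);
  ties in the greedy phasing margin break by bubble-id pair; chain
  direction starts at the smaller endpoint; identical inputs give
  byte-identical FASTA output. All simulator randomness derives from
  one mandatory seed.
- Degenerate inputs: components without bubbles pass through as
  unphased contigs; unlinked bubbles become singleton phase blocks;
  partitions whose support graph is disconnected are ordered per piece
  and concatenated by descending length, logged.
- Contig ordering scores an edge by its head/tail *corner* support —
  links whose two representative hit positions fall in the terminal
  20% windows of both contigs — divided by the corner count expected
  under the adjacency hypothesis with 1/d contact decay,
  E(w_a, w_b) = (w_a+w_b)·ln(w_a+w_b) − w_a·ln w_a − w_b·ln w_b.
  Raw whole-contig counts let a long contig's bulk long-range mass
  outvote a short true neighbour; raw corner counts inherit the same
  bias through window size; and a naive per-area density over-rewards
  tiny contigs whose few stray corners sit in a minuscule denominator.
  The expectation-normalized form recovers true adjacency in all three
  regimes (each was an observed failure mode on seeded replicates).

## Problem sizes

The test suite and the acceptance script exercise, as their flagship,
a 5 Mb two-chromosome genome (0.1% het, 20 SVs, 30× noise-free 150 bp
Hi-C, eight graph components) and a 100-replicate order/orientation
study on 400 kb five-contig chromosomes; brute-force oracles run on
≤12-node graphs, 2^8 phasing assignments and ≤6-contig partitions,
where exhaustive enumeration is exact and fast.

## Known limitations

- Polyploid (>2) phasing is not implemented; the data model is
  strictly diploid.
- Complex bubbles are carried but not phased; variation inside them is
  reported homozygous-like.
- The reference-free evaluator needs read pairs anchored on
  *consecutive* het sites; at low depth or sparse heterozygosity many
  junctions carry no evidence and switches there are undetectable (the
  report flags evaluability rather than printing zeros silently).
- The scaffolder does not break misassembled input contigs and does not
  resolve repeats inside gaps; it connects components only.
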