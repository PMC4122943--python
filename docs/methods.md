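# Methods

## The gene-order model

A mitochondrial genome is reduced to a signed circular permutation of gene
labels drawn from the closed 37-gene metazoan vocabulary, plus a CR marker.
Two symmetries are quotiented out, because neither carries biological
information: the rotation of the sequencing origin, and the mirror
(reversed reading direction with all strands flipped, i.e. which strand was
deposited).  Equality, hashing and all comparisons act on the canonical
form (lexicographically least rotation over both mirror images).

The CR is not a gene: it is excluded from the permutation before any
adjacency is formed, so breakpoint counts are comparable across records
with and without an annotated control region.  Its position is retained
separately because proximity of rearrangements to the CR is itself an
observable (the CR is the putative recombination hot spot).

### Breakpoint distance

Each circular order of n genes defines n oriented adjacencies; the
adjacency (a, b) read on one strand is (−b, −a) on the other, so
adjacencies are stored canonically.  The distance between two orders over
the same gene set is the number of adjacencies of one absent from the
other.  It is a symmetric premetric (d(x,x) = 0, d symmetric,
d = 0 ⇒ equal adjacency sets) but not a metric on arrangements — it counts
disrupted junctions, not events.  Closed-form event signatures used
throughout validation: inversion +2, transposition +3, inverse
transposition +3, TDRL ≤ segment + 1.

Duplicated genes (e.g. a second trnE, or a duplicated CR after a TDRL)
must be resolved first: `collapse_duplicates` keeps, per gene, the copy
with more reference-matching signed neighbours, breaking ties by proximity
to the gene's reference neighbours, then by copy index.  This makes the
resolution deterministic and biased toward the copy in ancestral context,
which is the convention that keeps the distance conservative.

### Backbone computation

The backbone is a maximum-cardinality gene subset whose induced circular
signed suborder is identical in the query and the reference.  The search
is exact: any non-empty common suborder contains a gene whose strand
agrees between the two orders in one of the two mirror frames; anchoring
the circle at each such gene reduces the circular problem to a linear
longest-common-subsequence over the remaining 36 elements.  With 2 frames
× ≤ 37 anchors × an O(n²) LCS this is ~10⁵ operations per genome.  Ties
prefer protein-coding and rRNA genes in the backbone (tRNAs are treated as
the mobile class), then a deterministic traceback.  Exactness is tested
against exhaustive subset search on random orders of ≤ 9 genes.

### Event classification

Rearranged genes (the backbone complement) are grouped into maximal blocks
contiguous in the derived order whose members were also contiguous and
co-oriented in the reference (reference positions consecutive, strand
relation uniform).  Per block:

* **inverted** — the strand relation to the reference is −1;
* in place vs moved — the block's immediate neighbours in the derived
  order are compared with its ancestral flanks;
* **local** — a non-inverted move whose genes all belong to one ancestral
  tRNA cluster and whose landing site is adjacent to that cluster.  A tRNA
  cluster is a maximal run of ≥ 2 consecutive tRNAs in the reference; in
  the ancestral arrangement these are I-Q-M, W-C-Y, K-D, A-R-N-S1-E-F and
  T-P.  (trnF belongs to the fourth run by this rule; it sits directly
  after trnE ancestrally.)
* **long-range** — any other move; an inverted in-place block is an
  inversion-only event.

Totals are reported per gene (a moved block of k genes counts as k gene
rearrangements), which is the convention under which per-genome counts add
up across taxa.

A block is **close to the CR** when (1) it contains a tRNA originating in
or landing in the arc between rrnS and nad2 that carries the CR, or
(2) it carries rrnS or nad2 together with ≥ 1 tRNA.  Both clauses are
tRNA-centric; because protein-coding and rRNA genes also move next to the
CR, the default adds a third clause — any block landing immediately
adjacent to the CR qualifies.  The extension can be disabled
(`close_rule_extension=False` / `--close-rule strict`).

## The simulator

`evolve_order` applies n independent events to a reference order:
inversion (reverse + strand-flip a block in place), transposition (move a
block), inverse transposition (move + flip), and TDRL (duplicate a
segment in tandem, then delete one copy of each duplicated gene uniformly
at random; the CR is never deleted, so a TDRL spanning it yields a
duplicated CR, the architecture seen in real CR-duplicated genomes).

Defaults emulate rearrangement-rich wasp mt genomes: blocks of 1–3 genes;
event mix 0.35 inversion / 0.35 transposition / 0.20 inverse transposition
/ 0.10 TDRL, reflecting the observed dominance of inversions and
long-range moves over local (TDRL-type) shuffles in such genomes; TDRL
segments capped at 6 elements, the scale of observed CR duplications.
Transposition destinations exclude the two offsets that recreate the
original circular order, so every drawn event is a real event.

`synthesize_genome` realises any order as an annotated sequence: gene
lengths drawn from typical mt ranges (tRNA 60–75 bp, rRNA 700–1400 bp,
PCG 150–1800 bp), i.i.d. bases at the target A+T fraction (default 0.82,
the middle of the range reported for compact wasp mt genomes), and a CR
(default 1000 bp, within the observed 0.7–3.9 kb range) carrying planted
repeats — tandem arrays, direct/inverted/complementary pairs — at known
coordinates.  `extract_gene_order` inverts the construction exactly.

What the generator does **not** emulate: codon structure and amino-acid
constraint, strand-asymmetric mutation pressure (so synthetic skews are
near zero), tRNA secondary structure, gene overlaps, and sequence
divergence after rearrangement.  Passing tests therefore demonstrate the
correctness of the order arithmetic, the detectors and the I/O, not the
realism of any evolutionary parameter.

All randomness flows from one integer seed through numpy Generator
streams; the benchmark bundle derives per-section child streams from a
root seed sequence and is byte-identical across runs.

## Numerical and convention choices

* Coordinates are 1-based inclusive (GenBank convention) externally;
  origin-wrapping features on circular genomes are one feature with a wrap
  flag, not two.
* Gene-name normalisation uses a versioned synonym table; unknown names
  fail loudly.  tRNA-Leu/tRNA-Ser isotypes are never guessed: they resolve
  from codon/anticodon qualifiers or raise.
* The CR is located from annotation when present, otherwise as the longest
  unannotated interval ≥ 100 bp; a second interval ≥ 50 % of the first is
  flagged as a duplicated-CR candidate (observed duplicated copies are
  ~78 % of the principal copy).
* Skews use exact rational arithmetic before the final float and are
  undefined (null) when the denominator is zero; `N` is excluded from
  counts, other ambiguity codes are rejected.  Per-gene skews default to
  the coding strand, with a major-strand option.
* Repeat scans report maximal exact matches (identity 1.0) found by
  seed-and-extend on shared min_len-mers along (anti)diagonals, verified
  equal to an all-pairs scan; self-overlapping copy pairs are excluded;
  circular sequences are scanned doubled with origin deduplication.
  Tandem detection compares adjacent unit copies at ≥ 0.85 identity,
  refines the array start phase to the cleanest alignment, floors trailing
  partial copies, reports the shortest unit, and scans units up to
  200 bp by default.
* The breakpoint window for repeat/junction co-occurrence defaults to
  ±50 bp and is configurable; no published proximity criterion exists, so
  the default is an order-of-magnitude choice at the scale of a tRNA gene.

## Problem sizes

The test suite and the analysis drivers run entirely on synthetic data:
37-gene orders, genomes of ~15–20 kb, 20 + 20 benchmark arrangements,
1,000 single-event recovery trials, and 200-instance brute-force
cross-checks on ≤ 9-gene toys — sizes at which every oracle
(hand enumeration, exhaustive subset search, all-pairs repeat scan) is
feasible and exact.

## Known limitations

* The backbone criterion maximises retained genes; when an event moves a
  block a shorter distance than its own length, the complementary
  description (the intervening genes moved the other way) is the same
  final order with fewer rearranged genes, and the classifier reports
  that minimal description.  This is inherent ambiguity of the data, not
  an implementation artefact; recovery tests accept any order-equivalent
  single-event explanation.
* Breakpoint counts are not event counts; no attempt is made to
  reconstruct event scenarios (common intervals, reversal distance).
* Repeat detection at identity 1.0 is conservative; diverged repeat
  copies are only visible to the tandem detector, not the pair scanner.
* The close-to-CR rule beyond its tRNA-centric core is a documented
  extension, and "local" classification depends on the cluster definition
  stated above.
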