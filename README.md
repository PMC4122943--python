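# mitorearr

Comparative analysis of mitochondrial gene-order rearrangements, built for
taxa with highly mobile mt genomes such as parasitoid wasps.  Animal mt
genomes carry 37 genes and one A+T-rich control region (CR) on a circular
molecule; lineages differ in how those genes are arranged, and the
differences — inversions, translocations, tandem duplication–random loss
(TDRL) — are candidate phylogenetic characters.  `mitorearr` quantifies
them against the ancestral pancrustacean/hymenopteran arrangement.

## What it computes

A genome is modelled as a **signed circular permutation**: a cyclic sequence
of oriented genes, invariant under rotation and under mirroring (reversed
order, all strands flipped), with the CR tracked positionally but excluded
from the permutation.  On this model the package provides:

* **Breakpoint distance.**  For orders π and σ over the same genes, each
  order defines n oriented adjacencies; an adjacency (a, b) is identified
  with (−b, −a).  The distance is |A(π) \ A(σ)| — the number of gene
  junctions of one genome absent from the other.  One inversion costs 2,
  one transposition or inverse transposition 3, one TDRL at most its
  segment length + 1.
* **Backbone / rearranged-gene partition.**  The backbone is a
  maximum-cardinality gene subset whose induced circular signed suborder
  matches the reference (computed exactly by anchored common-subsequence
  search over both strand frames); its complement is the set of rearranged
  genes.
* **Event classification.**  Rearranged genes are grouped into blocks that
  are contiguous in the derived order and were contiguous and co-oriented
  ancestrally; blocks are classified as inversions (strand flipped relative
  to the backbone frame), local translocations (non-inverted moves within
  one ancestral tRNA cluster — the TDRL signature), or long-range
  movements, and flagged when they occur close to the CR.
* **Shared derived adjacencies** across taxa (potential synapomorphies).
* **Repeat detection**: maximal exact direct and inverted repeats
  (≥ 12 bp), position-wise **complementary** matches (the recombination
  signature flanking duplicated CRs), and tandem arrays with imperfect
  copies; hits binned into the 12–20 / 21–50 / 51–100 / >100 bp classes.
* **Nucleotide composition**: AT-skew = (A − T)/(A + T),
  GC-skew = (G − C)/(G + C), A+T content on the major strand (the strand
  coding the plurality of the 13 protein-coding genes).
* A **gene-order evolution simulator** (inversion / transposition /
  inverse transposition / TDRL) plus a sequence synthesiser with planted
  repeats, so every stage is validated against known ground truth.

Inputs are GenBank flat files (names normalised through a shipped synonym
table) or a plain stanza format: a `>taxon` line followed by signed gene
tokens, e.g. `trnI -trnQ trnM nad2 ... -rrnS CR`.

## Worked example

```python
from mitorearr import (ancestral_order, breakpoint_distance,
                       classify_events, collapse_duplicates)
from mitorearr.synthetic_data import SimConfig, evolve_order

anc = ancestral_order()                      # 37 genes + CR
print(breakpoint_distance(anc, anc))         # 0  (identical arrangements)

hist = evolve_order(anc, SimConfig(seed=1, n_events=1))  # one random event
print(hist.events[0].type)                   # inversion
print(breakpoint_distance(collapse_duplicates(hist.final, anc), anc))  # 2

for ev in classify_events(hist.final, anc):
    print([str(g) for g in ev.genes], ev.inverted, ev.long_range, ev.local)
# ['trnI', 'rrnS'] True False False
```

The distance 0 is the identity case (a genome retaining the ancestral
arrangement); 2 is the exact cost of a single inversion; the classifier
recovers the inverted block — here the trnI/rrnS pair flanking the control
region, flipped in place (neither local nor long-range).

The numbered drivers under `analysis/` run the full study on a synthetic
benchmark and write tables under `results/`:

```bash
python analysis/01_simulate_benchmark.py     # fixture bundle + manifest
python analysis/02_breakpoint_distances.py   # distances + event signatures
python analysis/03_classify_events.py        # event typology vs ground truth
python analysis/04_repeat_scan.py            # repeat landscape + CR arrays
python analysis/05_nucleotide_skews.py       # A+T content and skews
```

`analysis/02` prints, among other things, the single-event distance
signatures (`inversion: [2]`, `transposition: [3]`,
`inverse_transposition: [3]`) and the saturation of the distance with event
count (mean 4.8 → 26.4 breakpoints from 2 to 20 events at the default
seed).

There is also a CLI (`mitorearr breakpoints|events|repeats|skew|simulate|run`)
for running the same stages on user files.

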