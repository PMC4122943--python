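"""Nucleotide composition statistics: A+T content and strand skews.

Strand asymmetry in mt genomes is summarised by two skew statistics,

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed on one strand of a region.  Both lie in [-1, 1] and are
antisymmetric under reverse complementation.  A+T content is reported for
the major strand, the strand encoding the plurality of the 13 protein-coding
genes.  Counts use exact rational arithmetic; floats appear only in the
returned values.  ``N`` is excluded from all counts; other ambiguity codes
are rejected so that upstream annotation errors surface instead of being
coerced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .models import AnnotatedGenome, FeatureClass, GeneLabel

__all__ = [
    "SkewResult",
    "at_gc_skew",
    "at_content",
    "major_strand",
    "per_gene_skew_table",
    "DEFAULT_SKEW_GENES",
]

#: Genes whose skews are tabulated by default: the protein-coding genes
#: observed inverted in at least one rearranged genome, plus both rRNAs.
DEFAULT_SKEW_GENES: tuple[str, ...] = ("nad2", "cox1", "nad6", "cob", "rrnL", "rrnS")


@dataclass(frozen=True)
class SkewResult:
    at_skew: float | None
    gc_skew: float | None
    at_content: float
    region_label: str = ""
    strand_used: int = 1
    length: int = 0


def _counts(seq: str) -> dict[str, int]:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unsupported characters in sequence: {sorted(bad)}")
    return {b: seq.count(b) for b in "ACGT"}


def at_gc_skew(seq: str, region_label: str = "", strand_used: int = 1) -> SkewResult:
    """AT and GC skew of one strand of a sequence.

    A skew is None when its denominator is zero (no A/T or no G/C bases).
    """
    if not seq:
        raise ValueError("empty sequence")
    c = _counts(seq)
    a, t, g, cc = c["A"], c["T"], c["G"], c["C"]
    at = float(Fraction(a - t, a + t)) if a + t else None
    gc = float(Fraction(g - cc, g + cc)) if g + cc else None
    total = a + t + g + cc
    content = float(Fraction(a + t, total)) if total else 0.0
    return SkewResult(at, gc, content, region_label, strand_used, length=len(seq))


def at_content(seq: str) -> float:
    """(A+T)/(A+C+G+T) of a sequence; N is ignored."""
    if not seq:
        raise ValueError("empty sequence")
    c = _counts(seq)
    total = sum(c.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return float(Fraction(c["A"] + c["T"], total))


def major_strand(genome: AnnotatedGenome) -> int:
    """The strand encoding the plurality of the 13 protein-coding genes.

    A tie is broken by the strand opposite to rrnS (ancestrally rrnS sits on
    the minor strand, so its complement is the major strand).
    """
    pcg_strands = [
        f.strand for f in genome.features if f.feature_class is FeatureClass.PCG
    ]
    if not pcg_strands:
        raise ValueError("no protein-coding genes annotated")
    plus = sum(1 for s in pcg_strands if s == 1)
    minus = len(pcg_strands) - plus
    if plus > minus:
        return 1
    if minus > plus:
        return -1
    try:
        return -genome.feature_by_label(GeneLabel("rrnS")).strand
    except KeyError:
        return 1


def per_gene_skew_table(
    genomes: Iterable[AnnotatedGenome],
    genes: Sequence[str] = DEFAULT_SKEW_GENES,
    on_major_strand: bool = False,
) -> pd.DataFrame:
    """Skew table with one row per (taxon, gene).

    By default skews are computed on each gene's coding strand as annotated;
    with ``on_major_strand`` the gene sequence is taken as it reads on the
    genome's major strand instead.  A requested gene missing from a genome
    yields a null row with a warning.
    """
    rows = []
    for genome in genomes:
        major = major_strand(genome) if on_major_strand else None
        for gene in genes:
            label = GeneLabel(gene)
            try:
                feat = genome.feature_by_label(label)
            except KeyError:
                warnings.warn(f"{genome.taxon}: gene {gene} absent", stacklevel=2)
                rows.append(
                    {
                        "taxon": genome.taxon,
                        "region": gene,
                        "strand": None,
                        "length": None,
                        "at_content": None,
                        "at_skew": None,
                        "gc_skew": None,
                    }
                )
                continue
            seq = genome.gene_sequence(label)
            strand = feat.strand
            if on_major_strand and strand != major:
                from .models import reverse_complement

                seq = reverse_complement(seq)
                strand = major
            res = at_gc_skew(seq, region_label=gene, strand_used=strand)
            rows.append(
                {
                    "taxon": genome.taxon,
                    "region": gene,
                    "strand": "+" if strand == 1 else "-",
                    "length": res.length,
                    "at_content": res.at_content,
                    "at_skew": res.at_skew,
                    "gc_skew": res.gc_skew,
                }
            )
    return pd.DataFrame(rows)
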