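"""Core data model for signed circular mitochondrial gene orders.

Animal mt genomes carry a near-universal set of 37 genes (13 protein-coding
genes, 22 tRNAs, 2 rRNAs) plus one large noncoding A+T-rich region (the
control region, CR) on a circular molecule.  Comparative rearrangement
analysis treats a genome as a *signed circular permutation*: a cyclic
sequence of oriented genes.  Two physical facts shape the equality rules:

* the sequencing origin on a circle is arbitrary, so cyclic rotations of an
  arrangement are the same arrangement;
* which strand is deposited in GenBank is arbitrary, so an arrangement and
  its mirror (reversed order, all strands flipped) are the same arrangement.

``SignedGeneOrder`` canonicalises over both symmetries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: The 37 canonical metazoan mt gene names (lowercase, field-standard style).
CANONICAL_GENES: frozenset[str] = frozenset({
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "rrnS", "rrnL",
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG",
    "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
    "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV",
})

#: Sentinel label for the A+T-rich region (control region).
CR = "CR"

_VALID_NAMES = CANONICAL_GENES | {CR}


class FeatureClass(str, enum.Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CR = "CR"


def feature_class_of(name: str) -> FeatureClass:
    """Feature class implied by a canonical gene name."""
    if name == CR:
        return FeatureClass.CR
    if name.startswith("trn"):
        return FeatureClass.TRNA
    if name.startswith("rrn"):
        return FeatureClass.RRNA
    if name.startswith(("nad", "cox", "atp")) or name == "cob":
        return FeatureClass.PCG
    raise ValueError(f"not a canonical mt gene name: {name!r}")


@dataclass(frozen=True, order=True)
class GeneLabel:
    """A canonical gene name plus a copy index distinguishing duplicates.

    ``copy_index`` is 1 for the (usual) single copy; a second annotated copy
    of e.g. trnE gets ``copy_index=2``.
    """

    name: str
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.name not in _VALID_NAMES:
            raise ValueError(f"unknown gene name: {self.name!r}")
        if self.copy_index < 1:
            raise ValueError("copy_index must be a positive integer")

    @property
    def is_cr(self) -> bool:
        return self.name == CR

    @property
    def feature_class(self) -> FeatureClass:
        return feature_class_of(self.name)

    def __str__(self) -> str:
        if self.copy_index == 1:
            return self.name
        return f"{self.name}.{self.copy_index}"

    @classmethod
    def parse(cls, token: str) -> "GeneLabel":
        """Parse ``name`` or ``name.copy_index`` (inverse of ``str``)."""
        if "." in token:
            name, _, idx = token.rpartition(".")
            return cls(name, int(idx))
        return cls(token)


#: One oriented element of a gene order: (label, strand), strand in {+1, -1}.
Element = tuple[GeneLabel, int]


def _check_strand(strand: int) -> int:
    if strand not in (1, -1):
        raise ValueError(f"strand must be +1 or -1, got {strand!r}")
    return strand


def element_str(el: Element) -> str:
    label, strand = el
    return f"-{label}" if strand == -1 else str(label)


def parse_element(token: str) -> Element:
    strand = 1
    if token.startswith("-"):
        strand = -1
        token = token[1:]
    return (GeneLabel.parse(token), strand)


class SignedGeneOrder:
    """A circular arrangement of oriented genes (plus at most one CR marker).

    Equality and hashing are invariant under cyclic rotation and under the
    mirror operation (reverse the list and flip every strand), reflecting
    the arbitrary origin and deposition strand of a circular genome record.
    """

    __slots__ = ("taxon", "elements", "duplicated_cr", "_key")

    def __init__(
        self,
        elements: Iterable[Element],
        taxon: str = "",
        duplicated_cr: bool = False,
    ) -> None:
        elems = tuple((label, _check_strand(strand)) for label, strand in elements)
        if not elems:
            raise ValueError("a gene order cannot be empty")
        seen: set[GeneLabel] = set()
        n_cr = 0
        for label, _ in elems:
            if label.is_cr:
                n_cr += 1
                continue
            if label in seen:
                raise ValueError(f"duplicate element {label} (use distinct copy_index)")
            seen.add(label)
        if n_cr > 1 and not duplicated_cr:
            raise ValueError(
                "more than one CR element; pass duplicated_cr=True if intended"
            )
        self.taxon = taxon
        self.elements = elems
        self.duplicated_cr = duplicated_cr
        self._key: tuple[Element, ...] | None = None

    # -- symmetry handling -------------------------------------------------

    def rotated(self, k: int) -> "SignedGeneOrder":
        """Rotate so that element ``k`` becomes first."""
        n = len(self.elements)
        k %= n
        return SignedGeneOrder(
            self.elements[k:] + self.elements[:k],
            taxon=self.taxon,
            duplicated_cr=self.duplicated_cr,
        )

    def mirrored(self) -> "SignedGeneOrder":
        """Reverse reading direction and flip all strands (same molecule)."""
        return SignedGeneOrder(
            tuple((label, -strand) for label, strand in reversed(self.elements)),
            taxon=self.taxon,
            duplicated_cr=self.duplicated_cr,
        )

    def canonical_key(self) -> tuple[Element, ...]:
        """Lexicographically least rotation over both mirror images."""
        if self._key is None:
            best: tuple[Element, ...] | None = None
            for seq in (self.elements, self.mirrored().elements):
                n = len(seq)
                doubled = seq + seq
                for i in range(n):
                    cand = doubled[i : i + n]
                    ckey = tuple(
                        (label.name, label.copy_index, strand)
                        for label, strand in cand
                    )
                    if best is None or ckey < _as_ckey(best):
                        best = cand
            assert best is not None
            self._key = best
        return self._key

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedGeneOrder):
            return NotImplemented
        return self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    @property
    def genes(self) -> frozenset[GeneLabel]:
        """Non-CR gene labels present."""
        return frozenset(label for label, _ in self.elements if not label.is_cr)

    def without_cr(self) -> "SignedGeneOrder":
        elems = tuple(el for el in self.elements if not el[0].is_cr)
        if not elems:
            raise ValueError("order contains only CR")
        return SignedGeneOrder(elems, taxon=self.taxon)

    def strand_of(self, label: GeneLabel) -> int:
        for lab, strand in self.elements:
            if lab == label:
                return strand
        raise KeyError(label)

    def index_of(self, label: GeneLabel) -> int:
        for i, (lab, _) in enumerate(self.elements):
            if lab == label:
                return i
        raise KeyError(label)

    def __repr__(self) -> str:
        body = " ".join(element_str(el) for el in self.elements)
        return f"SignedGeneOrder({self.taxon!r}: {body})"

    def to_tokens(self) -> list[str]:
        return [element_str(el) for el in self.elements]

    @classmethod
    def from_tokens(
        cls, tokens: Sequence[str], taxon: str = "", duplicated_cr: bool | None = None
    ) -> "SignedGeneOrder":
        elems = [parse_element(t) for t in tokens]
        if duplicated_cr is None:
            duplicated_cr = sum(1 for lab, _ in elems if lab.is_cr) > 1
        return cls(elems, taxon=taxon, duplicated_cr=duplicated_cr)


def _as_ckey(seq: tuple[Element, ...]):
    return tuple((label.name, label.copy_index, strand) for label, strand in seq)


@dataclass(frozen=True)
class Feature:
    """An annotated gene on a genome; coordinates are 1-based inclusive.

    A feature on a circular genome may wrap the origin, in which case
    ``start > end`` and ``wraps`` is True.
    """

    label: GeneLabel
    start: int
    end: int
    strand: int
    feature_class: FeatureClass
    wraps: bool = False

    def __post_init__(self) -> None:
        _check_strand(self.strand)
        if self.start < 1:
            raise ValueError("start must be >= 1 (1-based coordinates)")
        if not self.wraps and self.end < self.start:
            raise ValueError("end < start on a non-wrapping feature")

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def positions(self, genome_length: int) -> range | list[int]:
        """Covered 1-based positions (list when wrapping the origin)."""
        if self.wraps:
            return list(range(self.start, genome_length + 1)) + list(
                range(1, self.end + 1)
            )
        return range(self.start, self.end + 1)


@dataclass
class AnnotatedGenome:
    """A nucleotide sequence plus gene features, circular by default."""

    taxon: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains unsupported characters: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        for f in self.features:
            if f.end > len(self.sequence) and not f.wraps:
                raise ValueError(f"feature {f.label} extends beyond the sequence")
            if f.wraps and not self.circular:
                raise ValueError("origin-wrapping feature on a linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_label(self, label: GeneLabel) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def gene_sequence(self, label: GeneLabel) -> str:
        """Sequence of a feature on its annotated strand (5'->3')."""
        f = self.feature_by_label(label)
        if f.wraps:
            raw = self.sequence[f.start - 1 :] + self.sequence[: f.end]
        else:
            raw = self.sequence[f.start - 1 : f.end]
        return reverse_complement(raw) if f.strand == -1 else raw


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)
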