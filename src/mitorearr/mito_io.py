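"""Input/output for annotated mt genomes and plain gene-order tables.

Two on-disk representations are supported:

* **GenBank flat files** — the deposition format of annotated mt genomes.
  Feature names are normalised to the canonical 37-gene vocabulary through a
  versioned synonym table; unknown names fail loudly rather than being
  silently mis-mapped, because every downstream count depends on them.
* **Gene-order stanza tables** — a minimal plain-text format for signed
  circular orders: a ``>taxon`` line followed by whitespace-separated signed
  tokens (``-`` prefix = minus strand, ``CR`` marks the A+T-rich region).

The ancestral pancrustacean/hymenopteran arrangement, the reference for all
comparisons, is shipped as the built-in fixture ``ANCESTRAL_ORDER``.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .models import (
    CANONICAL_GENES,
    CR,
    AnnotatedGenome,
    Feature,
    FeatureClass,
    GeneLabel,
    SignedGeneOrder,
    feature_class_of,
)

__all__ = [
    "ANCESTRAL_TOKENS",
    "ancestral_order",
    "read_genbank",
    "write_genbank",
    "read_gene_order_table",
    "write_gene_order_table",
    "extract_gene_order",
    "identify_control_region",
    "noncoding_total",
    "to_bed",
    "write_fasta",
]

#: The ancestral pancrustacean/hymenopteran mt arrangement (reading frame of
#: the strand carrying cox1; minus-strand genes carry a ``-`` prefix).
ANCESTRAL_TOKENS: tuple[str, ...] = (
    "trnI", "-trnQ", "trnM", "nad2", "trnW", "-trnC", "-trnY", "cox1",
    "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3", "trnG",
    "nad3", "trnA", "trnR", "trnN", "trnS1", "trnE", "-trnF", "-nad5",
    "-trnH", "-nad4", "-nad4L", "trnT", "-trnP", "nad6", "cob", "trnS2",
    "-nad1", "-trnL1", "-rrnL", "-trnV", "-rrnS", "CR",
)


def ancestral_order() -> SignedGeneOrder:
    """The built-in ancestral reference arrangement (37 genes + CR)."""
    return SignedGeneOrder.from_tokens(ANCESTRAL_TOKENS, taxon="ancestral")


# ---------------------------------------------------------------------------
# synonym table
# ---------------------------------------------------------------------------

_NORM_RE = re.compile(r"[\s\-_()'\".+]")


def _normalise(name: str) -> str:
    return _NORM_RE.sub("", name.lower())


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = (
        resources.files("mitorearr").joinpath("data/gene_synonyms.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, canonical = line.split("\t")
        table[key] = canonical
    return table


_SYNONYMS = _load_synonyms()

# isotype markers for the ambiguous leucine/serine tRNAs (anticodons given
# in both RNA and DNA spelling)
_ISOTYPE_MARKERS = {
    "trnL1": ("cun", "uag", "tag"),
    "trnL2": ("uur", "uaa", "taa"),
    "trnS1": ("agn", "gcu", "gct", "ucu", "tct", "agc"),
    "trnS2": ("ucn", "uga", "tga"),
}


def _resolve_feature_name(qualifiers: dict, feature_type: str) -> str | None:
    """Canonical gene name for a GenBank feature, or None if unmappable."""
    candidates: list[str] = []
    for key in ("gene", "product", "standard_name", "note"):
        candidates.extend(qualifiers.get(key, []))
    if feature_type in ("D-loop", "rep_origin"):
        candidates.append("control region")
    for cand in candidates:
        norm = _normalise(cand)
        if norm in _SYNONYMS:
            return _SYNONYMS[norm]
    # ambiguous leu/ser: resolve isotype from any qualifier text
    joined = _normalise(" ".join(str(v) for vs in qualifiers.values() for v in vs))
    base = None
    for cand in candidates:
        norm = _normalise(cand)
        if norm in ("trnaleu", "trnl", "trnleu"):
            base = "L"
        elif norm in ("trnaser", "trns", "trnser"):
            base = "S"
    if base:
        hits = {
            iso
            for iso, markers in _ISOTYPE_MARKERS.items()
            if iso[3] == base and any(m in joined for m in markers)
        }
        if len(hits) == 1:
            return hits.pop()
        raise ValueError(
            f"cannot resolve tRNA-{'Leu' if base == 'L' else 'Ser'} isotype "
            f"for feature with qualifiers {dict(qualifiers)!r}; annotate the "
            "recognised codon family (e.g. UUR/CUN, AGN/UCN)"
        )
    return None


# ---------------------------------------------------------------------------
# GenBank reader / writer
# ---------------------------------------------------------------------------

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature", "misc_RNA")


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read an annotated mt genome from a GenBank flat file.

    All CDS/tRNA/rRNA (and D-loop / control-region misc_feature) features
    are mapped to canonical labels through the synonym table.  Unmapped
    features are reported with a warning, never silently dropped; duplicate
    gene names get an incremented copy index.
    """
    record = SeqIO.read(str(path), "genbank")
    circular = record.annotations.get("topology", "linear") == "circular"
    seq = str(record.seq).upper()
    length = len(seq)

    features: list[Feature] = []
    unmapped: list[str] = []
    for feat in record.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        name = _resolve_feature_name(feat.qualifiers, feat.type)
        if name is None:
            if feat.type in ("CDS", "tRNA", "rRNA"):
                unmapped.append(f"{feat.type}@{feat.location}")
            continue
        parts = feat.location.parts
        if len(parts) == 2 and int(parts[0].end) == length and int(parts[1].start) == 0:
            start, end, wraps = int(parts[0].start) + 1, int(parts[1].end), True
        else:
            start, end, wraps = int(feat.location.start) + 1, int(feat.location.end), False
        strand = -1 if feat.location.strand == -1 else 1
        fclass = feature_class_of(name)
        features.append(
            Feature(GeneLabel(name), start, end, strand, fclass, wraps=wraps)
        )

    if unmapped:
        warnings.warn(
            f"{path}: unmapped annotated features: {', '.join(unmapped)}",
            stacklevel=2,
        )
    if not any(f.feature_class is not FeatureClass.CR for f in features):
        raise ValueError(f"{path}: no recognizable mt genes")

    # duplicate names -> incremented copy_index, in coordinate order
    features.sort(key=lambda f: (f.start, f.end))
    counts: dict[str, int] = {}
    final: list[Feature] = []
    for f in features:
        n = counts.get(f.label.name, 0) + 1
        counts[f.label.name] = n
        if n > 1:
            warnings.warn(
                f"{path}: duplicate gene {f.label.name}, assigning copy {n}",
                stacklevel=2,
            )
            f = Feature(GeneLabel(f.label.name, n), f.start, f.end, f.strand,
                        f.feature_class, wraps=f.wraps)
        final.append(f)

    return AnnotatedGenome(
        taxon=record.annotations.get("organism", record.id) or record.id,
        sequence=seq,
        features=final,
        circular=circular,
    )


_GB_TYPES = {
    FeatureClass.PCG: "CDS",
    FeatureClass.TRNA: "tRNA",
    FeatureClass.RRNA: "rRNA",
    FeatureClass.CR: "misc_feature",
}


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write an AnnotatedGenome as a GenBank flat file (read_genbank inverts)."""
    locus = re.sub(r"\W+", "_", genome.taxon) or "genome"
    record = SeqRecord(
        Seq(genome.sequence),
        id=locus[:16],
        name=locus[:16],
        description=genome.taxon,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.taxon,
        },
    )
    length = len(genome.sequence)
    for f in sorted(genome.features, key=lambda f: (f.start, f.end)):
        if f.wraps:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, length, strand=f.strand),
                    SimpleLocation(0, f.end, strand=f.strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand=f.strand)
        quals = {"gene": [f.label.name]}
        if f.label.name == CR:
            quals = {"note": ["A+T-rich region"]}
        record.features.append(
            SeqFeature(loc, type=_GB_TYPES[f.feature_class], qualifiers=quals)
        )
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# gene-order stanza tables
# ---------------------------------------------------------------------------


def read_gene_order_table(path: str | Path) -> list[SignedGeneOrder]:
    """Read signed gene orders from a plain-text stanza file.

    Format: a line ``>taxon`` then whitespace-separated signed tokens on the
    following line(s); ``-`` prefix marks the minus strand, token ``CR``
    marks the A+T-rich region.
    """
    orders: list[SignedGeneOrder] = []
    taxon: str | None = None
    tokens: list[tuple[str, int]] = []  # (token, line number)

    def flush() -> None:
        nonlocal taxon, tokens
        if taxon is None:
            return
        if not tokens:
            raise ValueError(f"{path}: stanza {taxon!r} has no gene tokens")
        parsed = []
        for tok, lineno in tokens:
            bare = tok.lstrip("-").partition(".")[0]
            if bare not in CANONICAL_GENES and bare != CR:
                raise ValueError(f"{path}:{lineno}: unknown gene token {tok!r}")
            parsed.append(tok)
        order = SignedGeneOrder.from_tokens(parsed, taxon=taxon)
        if len(order.genes) < 7:
            raise ValueError(
                f"{path}: stanza {taxon!r} is not a mitochondrial gene order "
                f"(only {len(order.genes)} of 37 genes present)"
            )
        orders.append(order)
        taxon, tokens = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                taxon = line[1:].strip()
            else:
                if taxon is None:
                    raise ValueError(f"{path}:{lineno}: tokens before any '>' header")
                tokens.extend((tok, lineno) for tok in line.split())
    flush()
    return orders


def write_gene_order_table(
    orders: Iterable[SignedGeneOrder], path: str | Path
) -> None:
    """Write orders in the stanza format (read_gene_order_table inverts)."""
    with open(path, "w") as fh:
        for order in orders:
            fh.write(f">{order.taxon}\n")
            fh.write(" ".join(order.to_tokens()) + "\n")


# ---------------------------------------------------------------------------
# annotation-derived quantities
# ---------------------------------------------------------------------------


def _coverage(genome: AnnotatedGenome, include_cr: bool = True) -> bytearray:
    """Byte mask over 1..L (index 0 unused): 1 where any feature covers."""
    length = len(genome.sequence)
    mask = bytearray(length + 1)
    for f in genome.features:
        if not include_cr and f.feature_class is FeatureClass.CR:
            continue
        for p in f.positions(length):
            mask[p] = 1
    return mask


def _circular_gaps(mask: bytearray, circular: bool) -> list[tuple[int, int]]:
    """Maximal runs of uncovered positions, as 1-based inclusive intervals.

    On a circular genome a run may wrap the origin (returned with
    start > end).
    """
    length = len(mask) - 1
    uncovered = [p for p in range(1, length + 1) if not mask[p]]
    if not uncovered:
        return []
    if len(uncovered) == length:
        return [(1, length)]
    runs: list[tuple[int, int]] = []
    start = prev = uncovered[0]
    for p in uncovered[1:]:
        if p == prev + 1:
            prev = p
            continue
        runs.append((start, prev))
        start = prev = p
    runs.append((start, prev))
    if circular and len(runs) >= 2:
        first, last = runs[0], runs[-1]
        if first[0] == 1 and last[1] == length:
            runs = runs[1:-1] + [(last[0], first[1])]  # wrap
    return runs


def _interval_length(iv: tuple[int, int], genome_length: int) -> int:
    s, e = iv
    if e >= s:
        return e - s + 1
    return genome_length - s + 1 + e


def identify_control_region(
    genome: AnnotatedGenome, min_len: int = 100, duplicate_fraction: float = 0.5
) -> list[tuple[int, int]]:
    """Locate the A+T-rich region (control region).

    If CR features are annotated, their intervals are returned directly.
    Otherwise the longest unannotated interval is taken as the CR, plus any
    second unannotated interval at least ``duplicate_fraction`` of its
    length as a duplicated-CR candidate.  Returns 1-based inclusive
    ``(start, end)`` intervals, longest first; a wrapping interval has
    start > end.  Empty (with a warning) when no gap reaches ``min_len``.
    """
    annotated = [f for f in genome.features if f.feature_class is FeatureClass.CR]
    if annotated:
        ivs = [
            ((f.start, f.end) if not f.wraps else (f.start, f.end))
            for f in annotated
        ]
        ivs.sort(key=lambda iv: -_interval_length(iv, len(genome.sequence)))
        return ivs

    gaps = _circular_gaps(_coverage(genome), genome.circular)
    L = len(genome.sequence)
    gaps.sort(key=lambda iv: -_interval_length(iv, L))
    if not gaps or _interval_length(gaps[0], L) < min_len:
        warnings.warn(
            f"{genome.taxon}: no unannotated interval >= {min_len} bp; "
            "compact genome, no control region located",
            stacklevel=2,
        )
        return []
    principal_len = _interval_length(gaps[0], L)
    result = [gaps[0]]
    if len(gaps) > 1 and _interval_length(gaps[1], L) >= duplicate_fraction * principal_len:
        result.append(gaps[1])
    return result


def noncoding_total(genome: AnnotatedGenome, exclude_cr: bool = True) -> int:
    """Total unannotated length in bp, optionally excluding the CR interval(s).

    Overlapping features never contribute negative lengths: the count is over
    positions covered by no feature.
    """
    mask = _coverage(genome)
    length = len(genome.sequence)
    if exclude_cr:
        for iv in identify_control_region(genome):
            s, e = iv
            if e >= s:
                rng: Iterable[int] = range(s, e + 1)
            else:
                rng = list(range(s, length + 1)) + list(range(1, e + 1))
            for p in rng:
                mask[p] = 1
    return sum(1 for p in range(1, length + 1) if not mask[p])


def extract_gene_order(genome: AnnotatedGenome) -> SignedGeneOrder:
    """Signed circular gene order implied by the annotation.

    Elements are sorted by start coordinate around the circle; the CR is
    inserted at the position of the (annotated or inferred) control region.
    Overlapping features are permitted; identical start positions are not.
    """
    if len(genome.features) < 2:
        raise ValueError("need at least 2 features to define an order")
    feats = sorted(genome.features, key=lambda f: f.start)
    starts = [f.start for f in feats]
    if len(set(starts)) != len(starts):
        raise ValueError("two features share a start position")

    has_cr_feature = any(f.feature_class is FeatureClass.CR for f in feats)
    entries: list[tuple[int, GeneLabel, int]] = [
        (f.start, f.label, f.strand) for f in feats
    ]
    if not has_cr_feature:
        crs = identify_control_region(genome)
        for i, iv in enumerate(crs, start=1):
            label = GeneLabel(CR, i)
            entries.append((iv[0], label, 1))
    entries.sort(key=lambda t: t[0])
    n_cr = sum(1 for _, label, _ in entries if label.is_cr)
    return SignedGeneOrder(
        [(label, strand) for _, label, strand in entries],
        taxon=genome.taxon,
        duplicated_cr=n_cr > 1,
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def to_bed(genome: AnnotatedGenome, name: str | None = None) -> str:
    """Feature table in BED format (0-based half-open); wrapping features
    are split into two BED lines."""
    chrom = name or re.sub(r"\W+", "_", genome.taxon) or "genome"
    length = len(genome.sequence)
    lines = []
    for f in sorted(genome.features, key=lambda f: (f.start, f.end)):
        strand = "+" if f.strand == 1 else "-"
        if f.wraps:
            lines.append(f"{chrom}\t{f.start - 1}\t{length}\t{f.label}\t0\t{strand}")
            lines.append(f"{chrom}\t0\t{f.end}\t{f.label}\t0\t{strand}")
        else:
            lines.append(f"{chrom}\t{f.start - 1}\t{f.end}\t{f.label}\t0\t{strand}")
    return "\n".join(lines) + "\n"


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    record = SeqRecord(
        Seq(genome.sequence),
        id=re.sub(r"\W+", "_", genome.taxon) or "genome",
        description="",
    )
    SeqIO.write(record, str(path), "fasta")
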