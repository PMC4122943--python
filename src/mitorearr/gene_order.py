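"""Gene-order comparison: adjacencies, breakpoint distance, rearrangement
detection and classification against the ancestral arrangement.

The dissimilarity between two circular signed gene orders is the *breakpoint
count*: the number of oriented gene–gene adjacencies of one order that are
absent from the other.  An adjacency is unoriented as a pair — reading
``a b`` on one strand is the same junction as reading ``-b -a`` on the
other — so each is stored in a canonical form.  The control region is not a
gene and is excluded from the permutation before counting; its position is
retained separately because the proximity of rearrangements to the A+T-rich
region is itself of interest.

Rearranged genes are found by computing the *backbone*: a maximum set of
genes whose induced circular signed suborder matches the reference.  Its
complement is the set of rearranged genes, which are then grouped into
blocks and classified as inversions, long-range movements, or local
translocations (moves confined to one ancestral tRNA gene cluster, the
signature of tandem duplication–random loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .mito_io import ancestral_order
from .models import (
    Element,
    FeatureClass,
    GeneLabel,
    SignedGeneOrder,
)

__all__ = [
    "Adjacency",
    "adjacency_set",
    "collapse_duplicates",
    "breakpoint_distance",
    "BackboneResult",
    "backbone",
    "RearrangementEvent",
    "classify_events",
    "is_close_to_cr",
    "shared_derived_rearrangements",
    "BreakpointMatrix",
    "breakpoint_report",
    "trna_clusters",
    "event_totals",
]


def _elkey(el: Element):
    label, strand = el
    return (label.name, label.copy_index, strand)


@dataclass(frozen=True)
class Adjacency:
    """A canonical oriented junction between two genes.

    ``(a, b)`` and ``(-b, -a)`` denote the same junction read from the two
    strands; the lexicographically smaller representation is stored.
    """

    left: Element
    right: Element

    @classmethod
    def make(cls, left: Element, right: Element) -> "Adjacency":
        flipped = ((right[0], -right[1]), (left[0], -left[1]))
        if (_elkey(flipped[0]), _elkey(flipped[1])) < (_elkey(left), _elkey(right)):
            left, right = flipped
        return cls(left, right)

    def __str__(self) -> str:
        from .models import element_str

        return f"{element_str(self.left)}|{element_str(self.right)}"


def adjacency_set(
    order: SignedGeneOrder, include_cr: bool = False
) -> frozenset[Adjacency]:
    """The n canonical adjacencies of a circular order of n genes.

    The CR is excluded by default (it is not a gene); ``include_cr`` treats
    it as an orderable element instead, for convention-sensitivity checks.
    """
    elems = [
        el for el in order.elements if include_cr or not el[0].is_cr
    ]
    if len(elems) < 3:
        raise ValueError("need at least 3 non-CR genes for a circular adjacency set")
    names = [label.name for label, _ in elems]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(
            f"duplicate genes {dups} present; run collapse_duplicates first"
        )
    n = len(elems)
    return frozenset(
        Adjacency.make(elems[i], elems[(i + 1) % n]) for i in range(n)
    )


def collapse_duplicates(
    order: SignedGeneOrder, ref: SignedGeneOrder | None = None
) -> SignedGeneOrder:
    """Resolve duplicated genes to a single copy each.

    For each duplicated gene the copy with more reference-matching signed
    neighbours is retained; ties go to the copy with the fewest intervening
    genes to its reference neighbours.  Duplicate CR markers collapse to the
    first.  Breakpoint distance is defined on permutations, so this must run
    before any distance computation on a genome with duplications (e.g. a
    second trnE copy).
    """
    if ref is None:
        ref = ancestral_order()
    names = [label.name for label, _ in order.elements]
    dup_names = {n for n in names if names.count(n) > 1}
    if not dup_names:
        return order

    ref_elems = [el for el in ref.elements if not el[0].is_cr]
    ref_adj = {
        (_elkey2(a), _elkey2(b))
        for a, b in _cyclic_pairs(ref_elems)
    }
    ref_adj |= {(_flip2(b), _flip2(a)) for a, b in ref_adj}
    ref_pos = {label.name: i for i, (label, _) in enumerate(ref_elems)}

    non_cr = [el for el in order.elements if not el[0].is_cr]
    n = len(non_cr)

    def neighbour_score(idx: int) -> int:
        here = _elkey2(non_cr[idx])
        prev = _elkey2(non_cr[(idx - 1) % n])
        nxt = _elkey2(non_cr[(idx + 1) % n])
        return int((prev, here) in ref_adj) + int((here, nxt) in ref_adj)

    def proximity(idx: int) -> int:
        # fewest intervening genes to the reference neighbours of this gene
        name = non_cr[idx][0].name
        if name not in ref_pos:
            return n
        rp = ref_pos[name]
        m = len(ref_elems)
        targets = [ref_elems[(rp - 1) % m][0].name, ref_elems[(rp + 1) % m][0].name]
        pos = {lab.name: i for i, (lab, _) in enumerate(non_cr)}
        best = n
        for t in targets:
            if t in pos:
                d = abs(pos[t] - idx)
                best = min(best, min(d, n - d) - 1)
        return best

    keep: dict[str, GeneLabel] = {}
    for name in dup_names:
        if name == "CR":
            continue
        idxs = [i for i, (lab, _) in enumerate(non_cr) if lab.name == name]
        ranked = sorted(
            idxs,
            key=lambda i: (-neighbour_score(i), proximity(i), non_cr[i][0].copy_index),
        )
        keep[name] = non_cr[ranked[0]][0]
        dropped = [str(non_cr[i][0]) for i in ranked[1:]]
        warnings.warn(
            f"{order.taxon or 'order'}: collapsed duplicate {name}, "
            f"kept {non_cr[ranked[0]][0]}, removed {', '.join(dropped)}",
            stacklevel=2,
        )

    out: list[Element] = []
    cr_seen = False
    for label, strand in order.elements:
        if label.is_cr:
            if "CR" in dup_names:
                if cr_seen:
                    continue
                cr_seen = True
            out.append((GeneLabel("CR"), strand))
            continue
        if label.name in keep:
            if label != keep[label.name]:
                continue
            label = GeneLabel(label.name)  # normalise copy index
        out.append((label, strand))
    return SignedGeneOrder(out, taxon=order.taxon)


def _elkey2(el: Element):
    return (el[0].name, el[1])


def _flip2(k):
    return (k[0], -k[1])


def _cyclic_pairs(seq: Sequence[Element]):
    n = len(seq)
    return [(seq[i], seq[(i + 1) % n]) for i in range(n)]


def breakpoint_distance(
    a: SignedGeneOrder, b: SignedGeneOrder, include_cr: bool = False
) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (CR excluded by default).

    Symmetric, because both orders contribute equally many adjacencies.
    Requires equal gene sets after duplicate collapse.
    """
    ga = {lab.name for lab in a.genes}
    gb = {lab.name for lab in b.genes}
    if ga != gb:
        raise ValueError(
            f"gene sets differ: only in {a.taxon or 'a'}: {sorted(ga - gb)}; "
            f"only in {b.taxon or 'b'}: {sorted(gb - ga)}"
        )
    return len(adjacency_set(a, include_cr) - adjacency_set(b, include_cr))


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------


@dataclass
class BackboneResult:
    """Partition of a genome's genes into ancestral backbone and rearranged set."""

    backbone: frozenset[GeneLabel]
    rearranged: frozenset[GeneLabel]
    witness_order: SignedGeneOrder
    #: the query order in the strand frame matched against the reference
    #: (mirrored when the deposited frame was the opposite strand)
    aligned: SignedGeneOrder = field(repr=False, default=None)  # type: ignore[assignment]


def _is_anchor_weight(label: GeneLabel) -> int:
    return 1 if label.feature_class in (FeatureClass.PCG, FeatureClass.RRNA) else 0


def _lcs_subset(a: list[Element], b: list[Element]) -> tuple[int, int, list[Element]]:
    """Max common subsequence of two element lists.

    Maximises (count, PCG+rRNA count); returns (count, weight, subsequence).
    """
    na, nb = len(a), len(b)
    # dp[i][j] = best (count, weight) for a[i:], b[j:]
    dp = [[(0, 0)] * (nb + 1) for _ in range(na + 1)]
    for i in range(na - 1, -1, -1):
        row = dp[i]
        nxt = dp[i + 1]
        for j in range(nb - 1, -1, -1):
            best = max(nxt[j], row[j + 1])
            if a[i] == b[j]:
                c, w = dp[i + 1][j + 1]
                cand = (c + 1, w + _is_anchor_weight(a[i][0]))
                if cand > best:
                    best = cand
            row[j] = best
    # traceback (prefer taking a match, then advancing a)
    out: list[Element] = []
    i = j = 0
    while i < na and j < nb:
        if a[i] == b[j]:
            c, w = dp[i + 1][j + 1]
            if (c + 1, w + _is_anchor_weight(a[i][0])) == dp[i][j]:
                out.append(a[i])
                i += 1
                j += 1
                continue
        if dp[i + 1][j] == dp[i][j]:
            i += 1
        else:
            j += 1
    count, weight = dp[0][0]
    assert len(out) == count
    return count, weight, out


def backbone(order: SignedGeneOrder, ref: SignedGeneOrder) -> BackboneResult:
    """Maximum gene subset whose induced circular signed suborder matches ``ref``.

    Exact: every nonempty common suborder contains some gene whose strand
    agrees between the two orders in one of the two strand frames, so
    anchoring the circular comparison at each such gene and taking the best
    common subsequence over both frames searches all candidates.  Ties
    prefer protein-coding and rRNA genes in the backbone (tRNAs are the
    mobile class).
    """
    a0 = [el for el in order.elements if not el[0].is_cr]
    r0 = [el for el in ref.elements if not el[0].is_cr]
    if {l.name for l, _ in a0} != {l.name for l, _ in r0}:
        raise ValueError("gene sets differ between order and reference")
    _require_permutation(a0, "order")
    _require_permutation(r0, "reference")

    ref_strand = {lab.name: s for lab, s in r0}
    ref_index = {lab.name: i for i, (lab, _) in enumerate(r0)}
    n = len(a0)

    best: tuple[int, int] | None = None
    best_sub: list[Element] = []
    best_frame: list[Element] = []
    for frame in (
        a0,
        [(lab, -s) for lab, s in reversed(a0)],  # mirror
    ):
        for k in range(n):
            g, s = frame[k]
            if ref_strand[g.name] != s:
                continue
            rot_a = frame[k:] + frame[:k]
            ri = ref_index[g.name]
            rot_r = r0[ri:] + r0[:ri]
            c, w, sub = _lcs_subset(
                [_norm_el(e) for e in rot_a[1:]], [_norm_el(e) for e in rot_r[1:]]
            )
            score = (c + 1, w + _is_anchor_weight(g))
            if best is None or score > best:
                best = score
                best_sub = [_norm_el(frame[k])] + sub
                best_frame = frame
    if best is None:
        # no strand-consistent anchor: fall back to a single-gene backbone,
        # which always matches via the mirror symmetry of one element
        g = min(a0, key=_elkey)
        best_sub = [_norm_el(g)]
        best_frame = a0

    bb = frozenset(lab for lab, _ in best_sub)
    rearranged = frozenset(GeneLabel(lab.name) for lab, _ in a0) - bb
    witness = SignedGeneOrder(
        [el for el in best_frame if GeneLabel(el[0].name) in bb] or best_sub,
        taxon=order.taxon,
    )
    aligned = SignedGeneOrder(best_frame, taxon=order.taxon)
    return BackboneResult(bb, rearranged, witness, aligned)


def _norm_el(el: Element) -> Element:
    return (GeneLabel(el[0].name), el[1])


def _require_permutation(elems: list[Element], what: str) -> None:
    names = [lab.name for lab, _ in elems]
    if len(set(names)) != len(names):
        raise ValueError(f"{what} has duplicate genes; run collapse_duplicates first")


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------


@dataclass
class RearrangementEvent:
    """A maximal rearranged block with its classification flags.

    ``local`` and ``long_range`` are mutually exclusive; ``local`` implies
    not inverted (a local translocation is a within-cluster move without
    inversion).  An inverted block that kept its position is an
    inversion-only event (neither local nor long-range).
    """

    genes: tuple[GeneLabel, ...]
    inverted: bool
    long_range: bool
    local: bool
    close_to_cr: bool = False
    taxon: str = ""

    def __post_init__(self) -> None:
        if self.local and self.long_range:
            raise ValueError("local and long_range are mutually exclusive")
        if self.local and self.inverted:
            raise ValueError("a local translocation is by definition not inverted")


def trna_clusters(ref: SignedGeneOrder) -> list[frozenset[GeneLabel]]:
    """Maximal runs of >= 2 consecutive tRNAs in the reference order."""
    elems = [el for el in ref.elements if not el[0].is_cr]
    n = len(elems)
    is_t = [lab.feature_class is FeatureClass.TRNA for lab, _ in elems]
    if all(is_t):
        return [frozenset(GeneLabel(lab.name) for lab, _ in elems)]
    # rotate to start at a non-tRNA so runs do not wrap
    start = next(i for i in range(n) if not is_t[i])
    clusters: list[frozenset[GeneLabel]] = []
    run: list[GeneLabel] = []
    for k in range(n):
        lab, _ = elems[(start + k) % n]
        if lab.feature_class is FeatureClass.TRNA:
            run.append(GeneLabel(lab.name))
        else:
            if len(run) >= 2:
                clusters.append(frozenset(run))
            run = []
    if len(run) >= 2:
        clusters.append(frozenset(run))
    return clusters


def classify_events(
    order: SignedGeneOrder,
    ref: SignedGeneOrder | None = None,
    close_rule_extension: bool = True,
) -> list[RearrangementEvent]:
    """Detect and classify rearrangement events of ``order`` against ``ref``.

    Rearranged genes (the backbone complement) are grouped into maximal
    blocks that are contiguous in ``order`` and were contiguous and
    co-oriented in ``ref``; each block yields one event:

    * ``inverted`` — the block's strand relative to the backbone frame is
      flipped versus the reference;
    * ``local`` — a non-inverted move whose source and destination lie in
      one ancestral tRNA gene cluster;
    * ``long_range`` — any other move; an inverted block that stayed in
      place is an inversion-only event.

    ``order`` may contain a CR marker; it is used for the close-to-CR flag.
    """
    if ref is None:
        ref = ancestral_order()
    order = collapse_duplicates(order, ref)
    res = backbone(order, ref)
    aligned = res.aligned

    # working copies without CR, but remember CR neighbours in the aligned frame
    a_all = list(aligned.elements)
    a = [el for el in a_all if not el[0].is_cr]
    r = [el for el in ref.elements if not el[0].is_cr]
    n = len(a)
    ref_pos = {lab.name: i for i, (lab, _) in enumerate(r)}
    ref_strand = {lab.name: s for lab, s in r}
    rearranged = {lab.name for lab in res.rearranged}

    if not rearranged:
        return []

    # rotate so position 0 is a backbone gene; runs then never wrap
    start = next(i for i in range(n) if a[i][0].name not in rearranged)
    a = a[start:] + a[:start]

    events: list[RearrangementEvent] = []
    i = 0
    while i < n:
        if a[i][0].name not in rearranged:
            i += 1
            continue
        # maximal run of rearranged genes starting at i
        j = i
        while j < n and a[j][0].name in rearranged:
            j += 1
        run = a[i:j]
        # split the run into blocks contiguous & co-oriented in ref
        k = 0
        while k < len(run):
            lab, s = run[k]
            rel = s * ref_strand[lab.name]
            block = [run[k]]
            m = k + 1
            while m < len(run):
                lab2, s2 = run[m]
                if s2 * ref_strand[lab2.name] != rel:
                    break
                if (ref_pos[lab2.name] - ref_pos[block[-1][0].name]) % len(r) != rel % len(r):
                    break
                block.append(run[m])
                m += 1
            events.append(
                _make_event(
                    block, rel == -1, a, n, i + k, m - k, r, ref, order,
                    close_rule_extension,
                )
            )
            k = m
        i = j
    return events


def _make_event(
    block: list[Element],
    inverted: bool,
    a: list[Element],
    n: int,
    bstart: int,
    blen: int,
    r: list[Element],
    ref: SignedGeneOrder,
    order_with_cr: SignedGeneOrder,
    close_rule_extension: bool = True,
) -> RearrangementEvent:
    ref_pos = {lab.name: i for i, (lab, _) in enumerate(r)}
    m = len(r)
    prev_a = a[(bstart - 1) % n][0].name
    next_a = a[(bstart + blen) % n][0].name
    positions = [ref_pos[lab.name] for lab, _ in block]
    lo, hi = (positions[-1], positions[0]) if inverted else (positions[0], positions[-1])
    prev_r = r[(lo - 1) % m][0].name
    next_r = r[(hi + 1) % m][0].name
    in_place = prev_a == prev_r and next_a == next_r
    moved = not in_place

    local = False
    if moved and not inverted:
        block_genes = {GeneLabel(lab.name) for lab, _ in block}
        for cluster in trna_clusters(ref):
            if block_genes <= cluster and (
                GeneLabel(prev_a) in cluster or GeneLabel(next_a) in cluster
            ):
                local = True
                break
    long_range = moved and not local

    event = RearrangementEvent(
        genes=tuple(GeneLabel(lab.name) for lab, _ in block),
        inverted=inverted,
        long_range=long_range,
        local=local,
        taxon=order_with_cr.taxon,
    )
    event.close_to_cr = is_close_to_cr(
        event, order_with_cr, ref, extend_adjacent=close_rule_extension
    )
    return event


def _arc_through_cr(order: SignedGeneOrder) -> set[str] | None:
    """Gene names strictly between rrnS and nad2 on the CR-containing arc."""
    elems = list(order.elements)
    n = len(elems)
    names = [lab.name for lab, _ in elems]
    if "CR" not in names or "rrnS" not in names or "nad2" not in names:
        return None
    i_s, i_n = names.index("rrnS"), names.index("nad2")
    for a, b in ((i_s, i_n), (i_n, i_s)):
        arc = []
        k = (a + 1) % n
        while k != b:
            arc.append(names[k])
            k = (k + 1) % n
        if "CR" in arc:
            return {g for g in arc if g != "CR"}
    return None


def is_close_to_cr(
    event: RearrangementEvent,
    order: SignedGeneOrder,
    ref: SignedGeneOrder,
    extend_adjacent: bool = True,
) -> bool:
    """Whether a rearrangement occurred close to the A+T-rich region.

    True when (1) a tRNA in the event moves out of or into the span between
    the rrnS–nad2 junction (the arc containing the CR), or (2) the block
    carries rrnS or nad2 together with at least one tRNA.  With
    ``extend_adjacent`` (a documented extension covering non-tRNA moves)
    the flag is also set when any gene of the block lands immediately
    adjacent to the CR.
    """
    block_names = {lab.name for lab in event.genes}
    trnas = {g for g in block_names if g.startswith("trn")}

    # rule 2: rrnS or nad2 moving together with a tRNA
    if ({"rrnS", "nad2"} & block_names) and trnas:
        return True

    # rule 1: tRNA origin or destination in the rrnS..nad2 arc through CR
    ref_arc = _arc_through_cr(ref)
    ord_arc = _arc_through_cr(order)
    if trnas:
        if ref_arc and (trnas & ref_arc):
            return True
        if ord_arc and (trnas & ord_arc):
            return True

    # extension: any block gene immediately adjacent to the CR in `order`
    if not extend_adjacent:
        return False
    elems = list(order.elements)
    n = len(elems)
    for i, (lab, _) in enumerate(elems):
        if lab.is_cr:
            for j in (i - 1, i + 1):
                if elems[j % n][0].name in block_names:
                    return True
    return False


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def event_totals(events: Iterable[RearrangementEvent]) -> dict[str, int]:
    """Per-gene event totals (a moved block of k genes counts k).

    Keys: total, close, not_close, inversion, long_range, local.
    """
    totals = dict.fromkeys(
        ("total", "close", "not_close", "inversion", "long_range", "local"), 0
    )
    for ev in events:
        k = len(ev.genes)
        totals["total"] += k
        totals["close" if ev.close_to_cr else "not_close"] += k
        if ev.inverted:
            totals["inversion"] += k
        if ev.long_range:
            totals["long_range"] += k
        if ev.local:
            totals["local"] += k
    return totals


def shared_derived_rearrangements(
    orders: Sequence[SignedGeneOrder], ref: SignedGeneOrder | None = None
) -> dict[Adjacency, list[str]]:
    """Derived adjacencies (absent from ``ref``) shared by >= 2 genomes.

    Shared, derived adjacencies are potential synapomorphies; an empty
    result means gene order carries no grouping signal for these taxa.
    """
    if ref is None:
        ref = ancestral_order()
    if len(orders) < 2:
        raise ValueError("need at least two orders to look for shared rearrangements")
    ref_adj = adjacency_set(ref)
    support: dict[Adjacency, list[str]] = {}
    for order in orders:
        collapsed = collapse_duplicates(order, ref)
        derived = adjacency_set(collapsed) - ref_adj
        for adj in derived:
            support.setdefault(adj, []).append(order.taxon or "?")
    return {adj: taxa for adj, taxa in support.items() if len(taxa) >= 2}


@dataclass
class BreakpointMatrix:
    """Breakpoint counts of each taxon against a reference, plus pairwise."""

    taxa: list[str]
    reference: SignedGeneOrder
    vs_reference: dict[str, int]
    pairwise: dict[tuple[str, str], int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxa,
                "breakpoints": [self.vs_reference[t] for t in self.taxa],
            }
        )

    def summary(self) -> tuple[int, int]:
        vals = list(self.vs_reference.values())
        return (min(vals), max(vals))


def breakpoint_report(
    orders: Sequence[SignedGeneOrder], ref: SignedGeneOrder | None = None
) -> BreakpointMatrix:
    """Breakpoint counts of every order against the reference and pairwise."""
    if ref is None:
        ref = ancestral_order()
    collapsed = [collapse_duplicates(o, ref) for o in orders]
    taxa = [o.taxon or f"taxon{i+1}" for i, o in enumerate(collapsed)]
    vs_ref = {
        t: breakpoint_distance(o, ref) for t, o in zip(taxa, collapsed)
    }
    pairwise: dict[tuple[str, str], int] = {}
    for i, oi in enumerate(collapsed):
        for j, oj in enumerate(collapsed):
            if i < j:
                d = breakpoint_distance(oi, oj)
                pairwise[(taxa[i], taxa[j])] = d
                pairwise[(taxa[j], taxa[i])] = d
    return BreakpointMatrix(taxa, ref, vs_ref, pairwise)
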