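"""Repeat detection in mt genomes and their A+T-rich regions.

Four repeat kinds are distinguished:

* **direct** — a substring occurring again elsewhere on the same strand;
* **inverted** — a substring whose reverse complement occurs elsewhere;
* **complementary** — two segments matching under position-wise Watson–Crick
  complementation *without* reversal (the signature left by recombination
  between strands, e.g. the 10-mer pair flanking a duplicated control
  region);
* **tandem** — adjacent near-identical copies of a unit, the typical
  architecture of the A+T-rich region.

Direct/inverted scans report *maximal exact* matches only: a hit that can be
extended on neither side.  Matches are found by seeding on shared
``min_len``-mers and extending along the (anti)diagonal, which yields exactly
the set an all-pairs scan would.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import AnnotatedGenome, complement, reverse_complement

__all__ = [
    "RepeatHit",
    "RepeatSizeBins",
    "find_repeats",
    "complementary_match_length",
    "find_tandem_arrays",
    "bin_by_size",
    "repeats_near_breakpoints",
    "hits_to_bed",
]


@dataclass(frozen=True)
class RepeatHit:
    """A detected repeat; positions are 1-based starts of the two copies
    (for tandem arrays, ``pos1`` is the array start and ``pos2`` the second
    unit's start)."""

    kind: str  # direct | inverted | complementary | tandem
    pos1: int
    pos2: int
    length: int
    copies: int = 2
    identity: float = 1.0


@dataclass(frozen=True)
class RepeatSizeBins:
    """Repeat counts in the standard size classes (bounds inclusive)."""

    b12_20: int = 0
    b21_50: int = 0
    b51_100: int = 0
    b_gt100: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.b12_20, self.b21_50, self.b51_100, self.b_gt100)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


def _spans_overlap(a1: int, a2: int, b1: int, b2: int) -> bool:
    return a1 <= b2 and b1 <= a2


def find_repeats(
    seq: str,
    min_len: int = 12,
    kinds: Iterable[str] = ("direct", "inverted"),
    circular: bool = False,
) -> list[RepeatHit]:
    """All maximal exact direct and/or inverted repeats of length >= min_len.

    Self-overlapping copy pairs are excluded; each unordered pair is
    reported once.  A circular sequence is scanned via its doubling, with
    origin-spanning duplicates removed.
    """
    if min_len < 4:
        raise ValueError("min_len < 4 would flood the scan with chance seeds")
    seq = seq.upper()
    L = len(seq)
    if L < 2 * min_len:
        return []
    work = seq + seq if circular else seq
    hits: set[RepeatHit] = set()
    kinds = set(kinds)
    if "direct" in kinds:
        hits.update(_direct_maximal(work, min_len))
    if "inverted" in kinds:
        hits.update(_inverted_maximal(work, min_len))
    if circular:
        hits = _dedupe_circular(hits, L)
    return sorted(hits, key=lambda h: (h.pos1, h.pos2, h.kind))


def _seed_index(s: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    return index


def _direct_maximal(s: str, k: int) -> set[RepeatHit]:
    n = len(s)
    found: set[tuple[int, int, int]] = set()  # (start1, start2, length), 0-based
    seen_diag: dict[int, list[tuple[int, int]]] = {}
    for positions in _seed_index(s, k).values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                p1, p2 = positions[ai], positions[bi]
                d = p2 - p1
                covered = False
                for s0, e0 in seen_diag.get(d, ()):
                    if s0 <= p1 and p1 + k <= e0:
                        covered = True
                        break
                if covered:
                    continue
                a, b, length = p1, p2, k
                while a > 0 and b > 0 and s[a - 1] == s[b - 1]:
                    a -= 1
                    b -= 1
                    length += 1
                while b + length < n and s[a + length] == s[b + length]:
                    length += 1
                seen_diag.setdefault(d, []).append((a, a + length))
                if b < a + length:  # overlapping copies
                    continue
                found.add((a, b, length))
    return {
        RepeatHit("direct", a + 1, b + 1, length)
        for a, b, length in found
    }


def _inverted_maximal(s: str, k: int) -> set[RepeatHit]:
    n = len(s)
    index = _seed_index(s, k)
    found: set[tuple[int, int, int]] = set()
    seen_anti: dict[int, list[tuple[int, int]]] = {}
    for word, positions in index.items():
        rc = reverse_complement(word)
        partners = index.get(rc)
        if not partners:
            continue
        for p1 in positions:
            for p2 in partners:
                a, b = min(p1, p2), max(p1, p2)
                anti = a + b  # constant along an inverted-match extension
                covered = False
                for s0, e0 in seen_anti.get(anti, ()):
                    if s0 <= a and a + k <= e0:
                        covered = True
                        break
                if covered:
                    continue
                length = k
                # grow left of a together with right of b
                while a > 0 and b + length < n and s[a - 1] == complement(s[b + length]):
                    a -= 1
                    length += 1
                # grow right of a together with left of b
                while b > 0 and a + length <= b - 1 and s[a + length] == complement(s[b - 1]):
                    b -= 1
                    length += 1
                seen_anti.setdefault(anti, []).append((a, a + length))
                if _spans_overlap(a, a + length - 1, b, b + length - 1):
                    continue
                found.add((a, b, length))
    return {
        RepeatHit("inverted", a + 1, b + 1, length)
        for a, b, length in found
    }


def _dedupe_circular(hits: set[RepeatHit], L: int) -> set[RepeatHit]:
    out: dict[tuple, RepeatHit] = {}
    for h in hits:
        if h.length > L:
            continue
        p1 = (h.pos1 - 1) % L + 1
        p2 = (h.pos2 - 1) % L + 1
        a, b = sorted((p1, p2))
        key = (h.kind, a, b, h.length)
        out.setdefault(key, RepeatHit(h.kind, a, b, h.length, h.copies, h.identity))
    return set(out.values())


def complementary_match_length(s1: str, s2: str) -> int:
    """Longest run where ``s1[i]`` is the Watson–Crick complement of
    ``s2[i]`` (position-wise, no reversal)."""
    if not s1 or not s2:
        raise ValueError("both sequences must be non-empty")
    s1, s2 = s1.upper(), s2.upper()
    best = run = 0
    for c1, c2 in zip(s1, s2):
        if complement(c1) == c2 and c1 != "N":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def _identity(u: str, v: str) -> float:
    assert len(u) == len(v)
    if not u:
        return 0.0
    return sum(a == b for a, b in zip(u, v)) / len(u)


def _array_at(
    seq: str, j: int, u: int, min_identity: float
) -> tuple[int, int, float]:
    """Copies, span (incl. matching prefix of a trailing partial copy) and
    worst adjacent-copy identity of the array of unit ``u`` starting at ``j``."""
    L = len(seq)
    worst = 1.0
    c = 1
    while j + (c + 1) * u <= L:
        ident = _identity(
            seq[j + (c - 1) * u : j + c * u], seq[j + c * u : j + (c + 1) * u]
        )
        if ident < min_identity:
            break
        worst = min(worst, ident)
        c += 1
    span = c * u
    for a, b in zip(seq[j + span : j + span + u], seq[j + span - u : j + span]):
        if a != b:
            break
        span += 1
    return c, span, (worst if c >= 2 else 0.0)


def find_tandem_arrays(
    seq: str,
    min_unit: int = 10,
    min_copies: int = 2,
    min_identity: float = 0.85,
    max_unit: int = 200,
) -> list[RepeatHit]:
    """Arrays of adjacent near-identical unit copies.

    Adjacent copies must agree at >= ``min_identity`` of positions
    (imperfect copies allowed).  The reported copy number floors a trailing
    partial copy.  A perfect array is reported at its shortest unit; the
    harmonic detections at multiples of that unit are suppressed.  Unit
    sizes are scanned up to ``max_unit`` (observed mt control-region units
    are tens of bases).
    """
    seq = seq.upper()
    L = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    arrays: list[RepeatHit] = []
    claimed: list[tuple[int, int, int]] = []  # (start0, end0, unit)
    for u in range(min_unit, min(max_unit, L // min_copies) + 1):
        # vectorised adjacent-window identity for every start position
        eq = (arr[: L - u] == arr[u:]).astype(np.int32)
        window = np.convolve(eq, np.ones(u, dtype=np.int32), mode="valid")
        starts = np.nonzero(window >= np.ceil(min_identity * u))[0]
        si = 0
        while si < len(starts):
            i = int(starts[si])
            if i + 2 * u > L:
                break
            # suppress re-detections of an already-claimed array at a longer
            # unit: anything whose 2-unit window lies mostly inside a claim
            harmonic = any(
                min(i + 2 * u, e0) - max(i, s0) >= u for s0, e0, _ in claimed
            )
            if harmonic:
                si += 1
                continue
            # a window hanging off the array edge can qualify a few bases
            # early; pick the start phase with the cleanest, longest array
            best = None
            for j in range(i, min(i + u, L - 2 * u + 1)):
                c, span, worst = _array_at(seq, j, u, min_identity)
                if c < min_copies:
                    continue
                cand = (c, worst, -j)
                if best is None or cand > best[0]:
                    best = (cand, j, c, span, worst)
            if best is None:
                si += 1
                continue
            _, j, c, span, worst = best
            arrays.append(
                RepeatHit("tandem", j + 1, j + u + 1, u, copies=c, identity=worst)
            )
            claimed.append((j, j + span, u))
            end = j + span
            while si < len(starts) and starts[si] < end:
                si += 1
    return sorted(arrays, key=lambda h: (h.pos1, h.length))


def bin_by_size(hits: Iterable[RepeatHit]) -> RepeatSizeBins:
    """Bin direct/inverted hits of length >= 12 into the standard size classes."""
    b = [0, 0, 0, 0]
    for h in hits:
        if h.kind not in ("direct", "inverted") or h.length < 12:
            continue
        if h.length <= 20:
            b[0] += 1
        elif h.length <= 50:
            b[1] += 1
        elif h.length <= 100:
            b[2] += 1
        else:
            b[3] += 1
    return RepeatSizeBins(*b)


def repeats_near_breakpoints(
    genome: AnnotatedGenome,
    events: Sequence,
    window: int = 50,
    min_len: int = 12,
) -> tuple[pd.DataFrame, RepeatSizeBins]:
    """Count repeats around rearrangement junctions and inside the CR.

    For each event, the junctions flanking the rearranged block are located
    from the annotation and hits with at least one copy intersecting
    ``±window`` around a junction are counted.  The second return value bins
    the hits lying entirely within the A+T-rich region (those are counted
    there regardless of any window).
    """
    from .mito_io import identify_control_region

    hits = find_repeats(genome.sequence, min_len=min_len, circular=genome.circular)
    L = len(genome.sequence)

    def copy_spans(h: RepeatHit) -> list[tuple[int, int]]:
        return [
            (h.pos1, h.pos1 + h.length - 1),
            (h.pos2, h.pos2 + h.length - 1),
        ]

    rows = []
    for idx, ev in enumerate(events):
        feats = []
        for lab in ev.genes:
            try:
                feats.append(genome.feature_by_label(lab))
            except KeyError:
                continue
        if not feats:
            continue
        junctions = (min(f.start for f in feats), max(f.end for f in feats))
        for j in junctions:
            lo, hi = j - window, j + window
            count = sum(
                1
                for h in hits
                if any(_spans_overlap(lo, hi, s, e) for s, e in copy_spans(h))
            )
            rows.append(
                {
                    "taxon": genome.taxon,
                    "event": idx,
                    "genes": "+".join(str(g) for g in ev.genes),
                    "junction": j,
                    "n_repeats": count,
                }
            )
    junction_table = pd.DataFrame(
        rows, columns=["taxon", "event", "genes", "junction", "n_repeats"]
    )

    cr_ivs = identify_control_region(genome)

    def inside_cr(s: int, e: int) -> bool:
        for cs, ce in cr_ivs:
            if ce >= cs:
                if cs <= s and e <= ce:
                    return True
            else:  # wraps the origin
                if s >= cs or e <= ce:
                    return True
        return False

    cr_hits = [
        h
        for h in hits
        if any(inside_cr(s, e) for s, e in copy_spans(h))
    ]
    return junction_table, bin_by_size(cr_hits)


def hits_to_bed(hits: Iterable[RepeatHit], chrom: str = "genome") -> str:
    """Repeat hits as BED (0-based half-open); one line per copy."""
    lines = []
    for h in sorted(hits, key=lambda h: (h.pos1, h.pos2)):
        name = f"{h.kind}:{h.length}:{h.identity:.2f}"
        lines.append(f"{chrom}\t{h.pos1 - 1}\t{h.pos1 - 1 + h.length}\t{name}\t0\t+")
        if h.kind != "tandem":
            strand = "-" if h.kind == "inverted" else "+"
            lines.append(
                f"{chrom}\t{h.pos2 - 1}\t{h.pos2 - 1 + h.length}\t{name}\t0\t{strand}"
            )
    return "\n".join(lines) + ("\n" if lines else "")
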