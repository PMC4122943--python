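"""Gene-order evolution simulator and sequence synthesiser.

Everything downstream of the readers is testable without any database
access: this module evolves signed circular gene orders from the ancestral
arrangement under the four classical rearrangement mechanisms —

* **inversion**: a block is reversed and strand-flipped in place;
* **transposition**: a block moves elsewhere unchanged;
* **inverse transposition**: a block moves and is flipped;
* **TDRL** (tandem duplication–random loss): a segment is duplicated in
  tandem, then one copy of each duplicated gene is deleted at random (the
  CR is never deleted, so a TDRL spanning it leaves a duplicated CR, as
  observed in real genomes) —

and synthesises annotated nucleotide genomes around any order, with A+T-rich
composition and planted repeats of known coordinates, so detector output can
be checked against planted ground truth.

All randomness flows from one integer seed through ``numpy`` Generator
streams; per-fixture streams are derived with ``spawn_key``-style seed
sequences so a benchmark bundle is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .mito_io import ancestral_order, write_gene_order_table, write_genbank
from .models import (
    AnnotatedGenome,
    Element,
    Feature,
    FeatureClass,
    GeneLabel,
    SignedGeneOrder,
    complement,
    reverse_complement,
)

__all__ = [
    "SimConfig",
    "EventRecord",
    "SimHistory",
    "evolve_order",
    "apply_event",
    "synthesize_genome",
    "benchmark_suite",
]

EVENT_TYPES = ("inversion", "transposition", "inverse_transposition", "tdrl")

#: TDRL duplications are bounded at 6 genes (plus the CR when spanned),
#: the scale of observed control-region duplications.
TDRL_MAX_GENES = 6


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulation run.

    Defaults emulate rearrangement-rich parasitoid-wasp mt genomes: small
    moved blocks, inversion and translocation dominating over TDRL, ~82%
    A+T, and a control region of one kilobase.
    """

    seed: int = 0
    n_events: int = 1
    event_weights: dict[str, float] = field(
        default_factory=lambda: {
            "inversion": 0.35,
            "transposition": 0.35,
            "inverse_transposition": 0.20,
            "tdrl": 0.10,
        }
    )
    block_len_max: int = 3
    target_at: float = 0.82
    cr_len: int = 1000
    planted_repeats: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.block_len_max < 1:
            raise ValueError("block_len_max must be >= 1")
        unknown = set(self.event_weights) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")
        total = sum(self.event_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"event weights must sum to 1, got {total}")


@dataclass(frozen=True)
class EventRecord:
    """One applied event, with everything needed to replay it exactly.

    ``start``/``length`` index the block in the pre-event circular element
    list; ``dest`` is the insertion offset within the remainder (moves
    only); ``kept`` records, for each duplicated gene of a TDRL, which copy
    survived (0 = first, 1 = second).  ``block_genes`` snapshots the non-CR
    gene names of the block (the ground truth for recovery tests).
    """

    type: str
    start: int
    length: int
    dest: int = -1
    kept: tuple[int, ...] = ()
    block_genes: tuple[str, ...] = ()
    inverted: bool = False


@dataclass
class SimHistory:
    initial: SignedGeneOrder
    events: list[EventRecord]
    final: SignedGeneOrder

    def replay(self) -> SignedGeneOrder:
        """Re-apply the event log to the initial order."""
        elems = list(self.initial.elements)
        for ev in self.events:
            elems = apply_event(elems, ev)
        n_cr = sum(1 for lab, _ in elems if lab.is_cr)
        return SignedGeneOrder(
            elems, taxon=self.final.taxon, duplicated_cr=n_cr > 1
        )


def _flip(block: Sequence[Element]) -> list[Element]:
    return [(lab, -s) for lab, s in reversed(block)]


def apply_event(elems: Sequence[Element], ev: EventRecord) -> list[Element]:
    """Apply one recorded event to a circular element list (deterministic)."""
    n = len(elems)
    rot = list(elems[ev.start :]) + list(elems[: ev.start])
    block, rest = rot[: ev.length], rot[ev.length :]
    if ev.type == "inversion":
        return _flip(block) + rest
    if ev.type == "transposition":
        return rest[: ev.dest] + block + rest[ev.dest :]
    if ev.type == "inverse_transposition":
        return rest[: ev.dest] + _flip(block) + rest[ev.dest :]
    if ev.type == "tdrl":
        out: list[Element] = []
        ki = iter(ev.kept)
        for idx, el in enumerate(block):
            if el[0].is_cr:
                out.append(el)  # both CR copies survive
                continue
            keep = next(ki)
            if keep == 0:
                out.append(el)
        first = out
        out2: list[Element] = []
        ki = iter(ev.kept)
        for idx, el in enumerate(block):
            if el[0].is_cr:
                out2.append(el)
                continue
            keep = next(ki)
            if keep == 1:
                out2.append(el)
        return first + out2 + rest
    raise ValueError(f"unknown event type {ev.type!r}")


def _draw_event(
    elems: list[Element], rng: np.random.Generator, config: SimConfig
) -> EventRecord:
    n = len(elems)
    types = sorted(config.event_weights)
    probs = np.array([config.event_weights[t] for t in types])
    etype = types[rng.choice(len(types), p=probs / probs.sum())]
    if etype == "tdrl":
        max_len = min(TDRL_MAX_GENES, n - 2)
    else:
        max_len = min(config.block_len_max, n - 2)
    length = int(rng.integers(1, max_len + 1))
    start = int(rng.integers(n))
    rot = elems[start:] + elems[:start]
    block = rot[:length]
    block_genes = tuple(lab.name for lab, _ in block if not lab.is_cr)
    rest_len = n - length

    if etype == "inversion":
        return EventRecord("inversion", start, length, block_genes=block_genes,
                           inverted=True)
    if etype == "transposition":
        # offsets 0 and rest_len recreate the original circular order
        dest = int(rng.integers(1, rest_len))
        return EventRecord("transposition", start, length, dest=dest,
                           block_genes=block_genes)
    if etype == "inverse_transposition":
        dest = int(rng.integers(1, rest_len))
        return EventRecord("inverse_transposition", start, length, dest=dest,
                           block_genes=block_genes, inverted=True)
    # tdrl
    kept = tuple(int(k) for k in rng.integers(0, 2, size=len(block_genes)))
    return EventRecord("tdrl", start, length, kept=kept, block_genes=block_genes)


def evolve_order(
    ref: SignedGeneOrder | None = None,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
) -> SimHistory:
    """Evolve a gene order by ``config.n_events`` random events.

    Deterministic under a fixed ``config.seed`` (or an explicitly supplied
    generator, for callers managing their own streams).
    """
    if ref is None:
        ref = ancestral_order()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elems = list(ref.elements)
    events: list[EventRecord] = []
    for _ in range(config.n_events):
        ev = _draw_event(elems, rng, config)
        elems = apply_event(elems, ev)
        events.append(ev)
    n_cr = sum(1 for lab, _ in elems if lab.is_cr)
    final = SignedGeneOrder(
        elems, taxon=f"{ref.taxon}_sim", duplicated_cr=n_cr > 1
    )
    return SimHistory(initial=ref, events=events, final=final)


# ---------------------------------------------------------------------------
# sequence synthesis
# ---------------------------------------------------------------------------

_LEN_RANGES = {
    FeatureClass.TRNA: (60, 75),
    FeatureClass.RRNA: (700, 1400),
    FeatureClass.PCG: (150, 1800),
}


def _random_seq(rng: np.random.Generator, length: int, target_at: float) -> str:
    p_at = target_at / 2.0
    p_gc = (1.0 - target_at) / 2.0
    bases = rng.choice(np.array(list("ATGC")), size=length,
                       p=[p_at, p_at, p_gc, p_gc])
    return "".join(bases)


def _random_unit(rng: np.random.Generator, length: int, target_at: float) -> str:
    """A repeat unit with no strong internal periodicity or self-complementarity."""
    for _ in range(100):
        u = _random_seq(rng, length, target_at)
        ok = True
        for p in range(4, length // 2 + 1):
            matches = sum(u[i] == u[i - p] for i in range(p, length))
            if matches / (length - p) > 0.7:
                ok = False
                break
        if ok and u != reverse_complement(u):
            return u
    return u  # pragma: no cover - vanishingly unlikely


def _build_cr(
    rng: np.random.Generator, config: SimConfig
) -> str:
    """Control-region sequence with the planted repeat set at known offsets."""
    cr = list(_random_seq(rng, config.cr_len, min(config.target_at + 0.05, 0.95)))
    cursor = 10
    for kind, length, copies in config.planted_repeats:
        if kind == "tandem":
            unit = _random_unit(rng, length, config.target_at)
            needed = length * copies
            if cursor + needed + 10 > config.cr_len:
                raise ValueError("planted repeats exceed cr_len")
            cr[cursor : cursor + needed] = list(unit * copies)
            cursor += needed + 20
        elif kind in ("direct", "inverted", "complementary"):
            motif = _random_unit(rng, length, config.target_at)
            second = {
                "direct": motif,
                "inverted": reverse_complement(motif),
                "complementary": complement(motif),
            }[kind]
            gap = 25
            needed = 2 * length + gap
            if cursor + needed + 10 > config.cr_len:
                raise ValueError("planted repeats exceed cr_len")
            cr[cursor : cursor + length] = list(motif)
            cr[cursor + length + gap : cursor + needed] = list(second)
            cursor += needed + 20
        else:
            raise ValueError(f"unknown planted repeat kind {kind!r}")
    return "".join(cr)


def synthesize_genome(
    order: SignedGeneOrder,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
    taxon: str | None = None,
) -> AnnotatedGenome:
    """Annotated nucleotide genome realising a gene order.

    Gene lengths are drawn from the typical mt ranges (tRNA 60–75 bp,
    rRNA 700–1400 bp, PCG 150–1800 bp), base composition targets
    ``config.target_at``, and each CR element gets ``config.cr_len`` bases
    carrying the planted repeats.  ``extract_gene_order`` inverts this
    construction exactly.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    chunks: list[str] = []
    features: list[Feature] = []
    pos = 1
    for label, strand in order.elements:
        fclass = label.feature_class
        if fclass is FeatureClass.CR:
            seq = _build_cr(rng, config)
        else:
            lo, hi = _LEN_RANGES[fclass]
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)), config.target_at)
        end = pos + len(seq) - 1
        features.append(Feature(label, pos, end, strand, fclass))
        chunks.append(seq)
        pos = end + 1
    return AnnotatedGenome(
        taxon=taxon or order.taxon or "synthetic",
        sequence="".join(chunks),
        features=features,
        circular=True,
    )


# ---------------------------------------------------------------------------
# benchmark bundle
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkSuite:
    ancestral: SignedGeneOrder
    single_event: list[SimHistory]
    multi_event: list[SimHistory]
    genomes: list[AnnotatedGenome]
    manifest: dict[str, str]


def benchmark_suite(seed: int, outdir: str | Path | None = None) -> BenchmarkSuite:
    """A reproducible fixture bundle with ground-truth manifest.

    Contains the ancestral order, 20 single-event orders, 20 multi-event
    orders (5 each at k in {2, 5, 10, 20}), and 5 annotated sequences.
    Byte-identical on disk for equal seeds.
    """
    root = np.random.SeedSequence(seed)
    streams = root.spawn(3)
    anc = ancestral_order()
    manifest: dict[str, str] = {"seed": str(seed)}

    single: list[SimHistory] = []
    rng = np.random.default_rng(streams[0])
    for i in range(20):
        cfg = SimConfig(seed=seed, n_events=1)
        hist = evolve_order(anc, cfg, rng=rng)
        hist.final.taxon = f"single_{i:02d}"
        single.append(hist)
        manifest[f"single_{i:02d}.n_events"] = "1"
        manifest[f"single_{i:02d}.type"] = hist.events[0].type
        manifest[f"single_{i:02d}.block"] = ",".join(hist.events[0].block_genes)

    multi: list[SimHistory] = []
    rng = np.random.default_rng(streams[1])
    idx = 0
    for k in (2, 5, 10, 20):
        for _ in range(5):
            cfg = SimConfig(seed=seed, n_events=k)
            hist = evolve_order(anc, cfg, rng=rng)
            hist.final.taxon = f"multi_{idx:02d}_k{k}"
            multi.append(hist)
            manifest[f"multi_{idx:02d}_k{k}.n_events"] = str(k)
            idx += 1

    genomes: list[AnnotatedGenome] = []
    rng = np.random.default_rng(streams[2])
    for i in range(5):
        cfg = SimConfig(
            seed=seed,
            n_events=i,
            planted_repeats=(("tandem", 50, 5), ("direct", 15, 2)),
            cr_len=600,
        )
        hist = evolve_order(anc, cfg, rng=rng)
        hist.final.taxon = f"genome_{i}"
        genome = synthesize_genome(hist.final, cfg, rng=rng)
        genomes.append(genome)
        manifest[f"genome_{i}.n_events"] = str(i)
        manifest[f"genome_{i}.length"] = str(len(genome.sequence))

    suite = BenchmarkSuite(anc, single, multi, genomes, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_order_table([anc], outdir / "ancestral.tab")
        write_gene_order_table(
            [h.final for h in single], outdir / "single_event.tab"
        )
        write_gene_order_table([h.final for h in multi], outdir / "multi_event.tab")
        for genome in genomes:
            write_genbank(genome, outdir / f"{genome.taxon}.gbk")
        with open(outdir / "manifest.txt", "w") as fh:
            for key in sorted(manifest):
                fh.write(f"{key}={manifest[key]}\n")
    return suite
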