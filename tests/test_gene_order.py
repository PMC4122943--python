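"""Adjacency sets, breakpoint distance, backbone, event classification."""

import itertools
import warnings

import numpy as np
import pytest

from mitorearr.gene_order import (
    adjacency_set,
    backbone,
    breakpoint_distance,
    breakpoint_report,
    classify_events,
    collapse_duplicates,
    event_totals,
    shared_derived_rearrangements,
    trna_clusters,
)
from mitorearr.mito_io import ANCESTRAL_TOKENS
from mitorearr.models import GeneLabel, SignedGeneOrder
from mitorearr.synthetic_data import SimConfig, evolve_order
from tests.conftest import random_toy_order, toy_order


def _variant(tokens, taxon="v"):
    return SignedGeneOrder.from_tokens(tokens, taxon=taxon)


# ---------------------------------------------------------------------- #
# adjacencies and distance
# ---------------------------------------------------------------------- #


def test_adjacency_set_of_three_gene_circle():
    order = toy_order(["cox1", "cox2", "cox3"])
    adjs = adjacency_set(order)
    assert len(adjs) == 3
    assert adjacency_set(order.mirrored()) == adjs


def test_adjacency_cardinality_of_ancestral(anc):
    assert len(adjacency_set(anc)) == 37  # CR excluded


def test_adjacency_set_requires_collapse():
    order = toy_order(["cox1", "cox2", "cox1.2", "cox3"])
    with pytest.raises(ValueError, match="collapse_duplicates"):
        adjacency_set(order)


def test_breakpoint_identity_and_symmetry(anc, rng):
    assert breakpoint_distance(anc, anc) == 0
    for seed in range(10):
        h = evolve_order(anc, SimConfig(seed=seed, n_events=4))
        o = collapse_duplicates(h.final, anc)
        assert breakpoint_distance(o, anc) == breakpoint_distance(anc, o)
        assert breakpoint_distance(o, o) == 0


def test_breakpoint_hand_enumerated_toys():
    base = toy_order(["cox1", "cox2", "cox3", "cob", "nad1"])
    # move the 3rd gene between the 5th and 1st
    moved = toy_order(["cox1", "cox2", "cob", "nad1", "cox3"])
    assert breakpoint_distance(base, moved) == 3
    # invert the (2nd, 3rd) block
    inverted = toy_order(["cox1", "-cox3", "-cox2", "cob", "nad1"])
    assert breakpoint_distance(base, inverted) == 2


def test_breakpoint_zero_implies_equal_adjacency_sets(rng):
    for _ in range(30):
        a = random_toy_order(rng, 7)
        b = random_toy_order(rng, 7)
        if breakpoint_distance(a, b) == 0:
            assert adjacency_set(a) == adjacency_set(b)


def test_breakpoint_unequal_gene_sets_error(anc):
    small = toy_order(["cox1", "cox2", "cox3", "cob", "nad1", "nad2", "nad3"])
    with pytest.raises(ValueError, match="gene sets differ"):
        breakpoint_distance(small, anc)


def test_breakpoint_distance_cr_inclusion_toggle(anc):
    toks = [t for t in ANCESTRAL_TOKENS if t != "CR"] + ["CR"]
    # move CR next to cox1: invisible to the default permutation
    moved_cr = [t for t in ANCESTRAL_TOKENS if t != "CR"]
    i = moved_cr.index("cox1")
    moved_cr = moved_cr[: i + 1] + ["CR"] + moved_cr[i + 1 :]
    order = _variant(moved_cr)
    assert breakpoint_distance(order, anc) == 0
    assert breakpoint_distance(order, anc, include_cr=True) == 3


# ---------------------------------------------------------------------- #
# duplicates
# ---------------------------------------------------------------------- #


def test_collapse_keeps_ancestral_context_copy(anc):
    toks = list(ANCESTRAL_TOKENS)
    j = toks.index("cob")
    order = _variant(toks[: j + 1] + ["trnE.2"] + toks[j + 1 :], taxon="dup")
    with pytest.warns(UserWarning, match="collapsed duplicate trnE"):
        assert collapse_duplicates(order, anc) == anc


def test_collapse_without_duplicates_is_identity(anc):
    assert collapse_duplicates(anc, anc) is anc


def test_tdrl_output_collapses_to_permutation(anc):
    w = {"inversion": 0.0, "transposition": 0.0, "inverse_transposition": 0.0,
         "tdrl": 1.0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(100):
            h = evolve_order(anc, SimConfig(seed=seed, n_events=1, event_weights=w))
            collapsed = collapse_duplicates(h.final, anc)
            names = [lab.name for lab, _ in collapsed.elements if not lab.is_cr]
            assert sorted(names) == sorted({lab.name for lab in anc.genes})


# ---------------------------------------------------------------------- #
# backbone
# ---------------------------------------------------------------------- #


def _brute_backbone_size(order, ref):
    genes = sorted(order.genes)

    def induced(o, subset):
        elems = [el for el in o.elements if el[0] in subset]
        return SignedGeneOrder(elems)

    for r in range(len(genes), 0, -1):
        for combo in itertools.combinations(genes, r):
            s = set(combo)
            if induced(order, s) == induced(ref, s):
                return r
    return 0


def test_backbone_of_identical_orders_is_everything(anc):
    res = backbone(anc, anc)
    assert res.rearranged == frozenset()
    assert res.backbone == anc.genes


def test_backbone_single_transposed_gene_toy():
    base = toy_order(["cox1", "cox2", "cox3", "cob", "nad1", "nad2"])
    moved = toy_order(["cox1", "cox2", "cob", "nad1", "cox3", "nad2"])
    res = backbone(moved, base)
    assert res.rearranged == frozenset({GeneLabel("cox3")})
    assert _brute_backbone_size(moved, base) == len(res.backbone)


def test_backbone_matches_exhaustive_oracle_on_random_orders(rng):
    for _ in range(40):
        n = int(rng.integers(4, 10))
        a = random_toy_order(rng, n)
        b = random_toy_order(rng, n)
        assert len(backbone(a, b).backbone) == _brute_backbone_size(a, b)


def test_backbone_witness_suborder_matches_reference(anc):
    h = evolve_order(anc, SimConfig(seed=17, n_events=3))
    order = collapse_duplicates(h.final, anc)
    res = backbone(order, anc)
    induced_ref = SignedGeneOrder(
        [el for el in anc.elements if not el[0].is_cr and el[0] in res.backbone]
    )
    assert res.witness_order == induced_ref


# ---------------------------------------------------------------------- #
# event classification
# ---------------------------------------------------------------------- #


def test_trna_clusters_of_ancestral(anc):
    clusters = {frozenset(g.name for g in c) for c in trna_clusters(anc)}
    assert {"trnI", "trnQ", "trnM"} in clusters
    assert {"trnW", "trnC", "trnY"} in clusters
    assert {"trnK", "trnD"} in clusters
    assert {"trnT", "trnP"} in clusters
    # the nad3..nad5 junction run: A-R-N-S1-E plus the adjacent trnF
    assert {"trnA", "trnR", "trnN", "trnS1", "trnE", "trnF"} in clusters
    assert len(clusters) == 5


def test_identical_order_yields_no_events(anc):
    assert classify_events(anc, anc) == []


def test_in_place_inversion_event(anc):
    toks = list(ANCESTRAL_TOKENS)
    i = toks.index("trnW")
    order = _variant(toks[:i] + ["trnC", "-trnW"] + toks[i + 2 :])
    (ev,) = classify_events(order, anc)
    assert {g.name for g in ev.genes} == {"trnW", "trnC"}
    assert ev.inverted and not ev.local and not ev.long_range


def test_local_translocation_within_trna_cluster(anc):
    toks = [t for t in ANCESTRAL_TOKENS if t != "trnA"]
    j = toks.index("trnS1")
    order = _variant(toks[: j + 1] + ["trnA"] + toks[j + 1 :])
    (ev,) = classify_events(order, anc)
    assert [g.name for g in ev.genes] == ["trnA"]
    assert ev.local and not ev.inverted and not ev.long_range


def test_long_range_movement_event(anc):
    toks = [t for t in ANCESTRAL_TOKENS if t != "-trnQ"]
    j = toks.index("cox3")
    order = _variant(toks[: j + 1] + ["-trnQ"] + toks[j + 1 :])
    (ev,) = classify_events(order, anc)
    assert [g.name for g in ev.genes] == ["trnQ"]
    assert ev.long_range and not ev.inverted and not ev.local
    # trnQ left the I-Q-M cluster between the rrnS-nad2 junction
    assert ev.close_to_cr


def test_pcg_block_inversion_far_from_cr_not_close(anc):
    # nad6-cob -> cob-nad6: block inversion in place, away from the CR
    toks = list(ANCESTRAL_TOKENS)
    i = toks.index("nad6")
    order = _variant(toks[:i] + ["-cob", "-nad6"] + toks[i + 2 :])
    (ev,) = classify_events(order, anc)
    assert {g.name for g in ev.genes} == {"nad6", "cob"}
    assert ev.inverted and not ev.close_to_cr


def test_event_totals_count_per_gene(anc):
    toks = list(ANCESTRAL_TOKENS)
    i = toks.index("trnW")
    order = _variant(toks[:i] + ["trnC", "-trnW"] + toks[i + 2 :])
    totals = event_totals(classify_events(order, anc))
    assert totals["total"] == 2  # a 2-gene block counts 2 rearrangements
    assert totals["inversion"] == 2
    assert totals["close"] + totals["not_close"] == totals["total"]


# ---------------------------------------------------------------------- #
# shared derived adjacencies
# ---------------------------------------------------------------------- #


def test_identical_derived_orders_share_all_derived_adjacencies(anc):
    h = evolve_order(anc, SimConfig(seed=23, n_events=2))
    o1 = collapse_duplicates(h.final, anc)
    o2 = SignedGeneOrder(o1.elements, taxon="twin")
    shared = shared_derived_rearrangements([o1, o2], anc)
    derived = adjacency_set(o1) - adjacency_set(anc)
    assert set(shared) == set(derived)
    assert all(len(taxa) == 2 for taxa in shared.values())


def test_independent_histories_rarely_share_derived_adjacencies(anc):
    # star phylogeny: independent 2-event histories on 7 taxa
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n_shared = []
        n_derived = []
        for rep in range(20):
            orders = []
            for t in range(7):
                h = evolve_order(anc, SimConfig(seed=1000 * rep + t, n_events=2))
                o = collapse_duplicates(h.final, anc)
                o.taxon = f"t{t}"
                orders.append(o)
            n_shared.append(len(shared_derived_rearrangements(orders, anc)))
            derived = set()
            for o in orders:
                derived |= adjacency_set(o) - adjacency_set(anc)
            n_derived.append(len(derived))
    # chance coincidences (e.g. two taxa healing the same junction) are
    # possible but must be rare relative to the derived adjacencies present
    assert sum(1 for n in n_shared if n == 0) >= 12
    assert sum(n_shared) < 0.1 * sum(n_derived)


# ---------------------------------------------------------------------- #
# reports
# ---------------------------------------------------------------------- #


def test_breakpoint_report_reference_only(anc):
    matrix = breakpoint_report([anc], anc)
    assert list(matrix.vs_reference.values()) == [0]


def test_breakpoint_report_single_inversions_all_two(anc):
    w = {"inversion": 1.0, "transposition": 0.0, "inverse_transposition": 0.0,
         "tdrl": 0.0}
    orders = []
    for seed in range(20):
        h = evolve_order(anc, SimConfig(seed=seed, n_events=1, event_weights=w))
        if not h.events[0].block_genes:  # CR-only inversion moves no gene
            continue
        h.final.taxon = f"s{seed}"
        orders.append(h.final)
    matrix = breakpoint_report(orders, anc)
    assert all(d == 2 for d in matrix.vs_reference.values())
    assert matrix.summary() == (2, 2)
    # pairwise symmetry
    for (x, y), d in matrix.pairwise.items():
        assert matrix.pairwise[(y, x)] == d
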