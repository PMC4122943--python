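"""Repeat detection against brute-force oracles and planted constructions."""

import numpy as np
import pytest

from mitorearr.models import complement, reverse_complement
from mitorearr.repeat_finder import (
    RepeatHit,
    bin_by_size,
    complementary_match_length,
    find_repeats,
    find_tandem_arrays,
    repeats_near_breakpoints,
)


# ---------------------------------------------------------------------- #
# brute-force oracle (all-pairs diagonal scan, independent of the
# seed-and-extend implementation)
# ---------------------------------------------------------------------- #


def brute_force_repeats(s: str, k: int) -> set[tuple]:
    n = len(s)
    out = set()
    # direct: maximal runs along each diagonal d
    for d in range(1, n):
        i = 0
        while i + d < n:
            if s[i] != s[i + d]:
                i += 1
                continue
            j = i
            while j + d < n and s[j] == s[j + d]:
                j += 1
            length = j - i
            if length >= k and d >= length:  # non-overlapping copies
                out.add(("direct", i + 1, i + d + 1, length))
            i = j + 1
    # inverted: maximal runs along each anti-diagonal c = i + j
    for c in range(1, 2 * n - 2):
        lo = max(0, c - n + 1)
        hi = min(c, n - 1)
        i = lo
        while i <= hi:
            j = c - i
            if j < i or s[i] != complement(s[j]):
                i += 1
                continue
            i0 = i
            while i <= hi and c - i >= i and s[i] == complement(s[c - i]):
                i += 1
            i1 = i - 1
            # matched cells (t, c-t) for t in [i0, i1]; as a segment pair:
            a, L = i0, i1 - i0 + 1
            b = c - i1
            if L >= k and a + L - 1 < b:
                out.add(("inverted", a + 1, b + 1, L))
    return out


def _as_tuples(hits):
    return {(h.kind, h.pos1, h.pos2, h.length) for h in hits}


def test_agrees_with_brute_force_on_random_sequences(rng):
    for _ in range(15):
        n = int(rng.integers(80, 401))
        seq = "".join(rng.choice(list("ACGT"), n))
        assert _as_tuples(find_repeats(seq, min_len=8)) == brute_force_repeats(seq, 8)


def test_agrees_with_brute_force_on_at_rich_sequences(rng):
    # AT-rich composition creates many chance seeds; agreement must hold
    for _ in range(5):
        seq = "".join(
            rng.choice(list("ATGC"), 300, p=[0.41, 0.41, 0.09, 0.09])
        )
        assert _as_tuples(find_repeats(seq, min_len=8)) == brute_force_repeats(seq, 8)


def test_planted_direct_duplication_is_the_only_hit(rng):
    seq = list(rng.choice(list("ACGT"), 500))
    motif = "".join(rng.choice(list("ACGT"), 15))
    seq[40:55] = motif
    seq[300:315] = motif
    hits = find_repeats("".join(seq), min_len=12)
    direct = [h for h in hits if h.kind == "direct"]
    assert len(direct) == 1
    assert (direct[0].pos1, direct[0].pos2) == (41, 301)
    assert direct[0].length >= 15  # chance flanking matches may extend it


def test_planted_inverted_repeat(rng):
    seq = list(rng.choice(list("ACGT"), 400))
    motif = "".join(rng.choice(list("ACGT"), 20))
    seq[50:70] = motif
    seq[200:220] = reverse_complement(motif)
    hits = [h for h in find_repeats("".join(seq), min_len=12) if h.kind == "inverted"]
    assert len(hits) == 1
    assert hits[0].length >= 20


def test_short_sequence_has_no_hits():
    assert find_repeats("ACGT" * 3, min_len=12) == []


def test_min_len_floor():
    with pytest.raises(ValueError):
        find_repeats("ACGT" * 100, min_len=3)


def test_inverted_detection_revcomp_invariant(rng):
    seq = "".join(rng.choice(list("ACGT"), 300))
    fwd = {
        (h.length,) for h in find_repeats(seq, min_len=8) if h.kind == "inverted"
    }
    rev = {
        (h.length,)
        for h in find_repeats(reverse_complement(seq), min_len=8)
        if h.kind == "inverted"
    }
    assert fwd == rev


def test_circular_scan_finds_origin_spanning_repeat(rng):
    motif = "".join(rng.choice(list("ACGT"), 15))
    mid = "".join(rng.choice(list("ACGT"), 150))
    # one copy split across the origin
    seq = motif[7:] + mid + motif + "".join(rng.choice(list("ACGT"), 40)) + motif[:7]
    linear = {h.kind for h in find_repeats(seq, min_len=12)}
    circular = find_repeats(seq, min_len=12, circular=True)
    assert "direct" not in linear
    assert any(h.kind == "direct" and h.length >= 15 for h in circular)


# ---------------------------------------------------------------------- #
# complementary matches
# ---------------------------------------------------------------------- #


def test_complementary_ten_mers():
    assert complementary_match_length("AAAAGTATTT", "TTTTCATAAA") == 10


def test_complementary_same_base_is_zero():
    assert complementary_match_length("AAAA", "AAAA") == 0


def test_complementary_of_full_complement(rng):
    s = "".join(rng.choice(list("ACGT"), 37))
    assert complementary_match_length(s, complement(s)) == 37


# ---------------------------------------------------------------------- #
# tandem arrays
# ---------------------------------------------------------------------- #


def test_tandem_array_50bp_20_copies(rng):
    unit = "".join(rng.choice(list("ACGT"), 50))
    seq = "GGATCCGGAT" + unit * 20 + "CCGGAATTGG"
    (arr,) = find_tandem_arrays(seq)
    assert (arr.length, arr.copies) == (50, 20)
    assert arr.identity == 1.0


def test_microsatellite_copy_number_difference(rng):
    unit = "".join(rng.choice(list("ACGT"), 11))
    a = "GG" + unit * 6 + "CATG"
    b = "GG" + unit * 9 + "CATG"
    (ha,) = find_tandem_arrays(a)
    (hb,) = find_tandem_arrays(b)
    assert (ha.length, hb.length) == (11, 11)
    assert (ha.copies, hb.copies) == (6, 9)


def test_imperfect_copies_within_identity_floor(rng):
    unit = "".join(rng.choice(list("ACGT"), 40))
    degraded = unit[:3] + ("A" if unit[3] != "A" else "C") + unit[4:]
    seq = unit + unit + degraded + unit
    (arr,) = find_tandem_arrays(seq, min_unit=10)
    assert arr.length == 40 and arr.copies == 4
    assert arr.identity == pytest.approx(39 / 40)


def test_aperiodic_sequence_has_no_arrays(rng):
    seq = "".join(rng.choice(list("ACGT"), 400))
    assert find_tandem_arrays(seq) == []


# ---------------------------------------------------------------------- #
# bins and breakpoint proximity
# ---------------------------------------------------------------------- #


def test_bin_boundaries():
    hits = [RepeatHit("direct", 1, 500, n) for n in (12, 20, 21, 100, 101)]
    assert bin_by_size(hits).as_tuple() == (2, 1, 1, 1)
    assert bin_by_size([]).as_tuple() == (0, 0, 0, 0)


def test_bin_conservation(rng):
    lengths = rng.integers(12, 300, size=100)
    hits = [RepeatHit("inverted", 1, 1000, int(n)) for n in lengths]
    assert bin_by_size(hits).total == 100


def test_repeats_near_breakpoints_window(anc):
    from mitorearr.gene_order import classify_events
    from mitorearr.mito_io import ANCESTRAL_TOKENS
    from mitorearr.models import SignedGeneOrder
    from mitorearr.synthetic_data import SimConfig, synthesize_genome

    # move trnA out of its cluster, plant a direct repeat next to its new site
    toks = [t for t in ANCESTRAL_TOKENS if t != "trnA"]
    j = toks.index("cox2")
    order = SignedGeneOrder.from_tokens(
        toks[: j + 1] + ["trnA"] + toks[j + 1 :], taxon="plant"
    )
    cfg = SimConfig(seed=40, n_events=0)
    genome = synthesize_genome(order, cfg)
    events = classify_events(order)
    assert any("trnA" in {g.name for g in ev.genes} for ev in events)

    feat = genome.feature_by_label(next(iter(
        [g for ev in events for g in ev.genes if g.name == "trnA"]
    )))
    motif = "TACGGATCGATCGT"  # 14 bp, GC-rich: no chance copies in AT-rich context
    s = list(genome.sequence)
    p1 = feat.start - 25  # 10 bp upstream of the junction at feat.start
    p2 = feat.end + 300
    s[p1 : p1 + 14] = motif
    s[p2 : p2 + 14] = motif
    genome.sequence = "".join(s)

    wide, _ = repeats_near_breakpoints(genome, events, window=50)
    narrow, _ = repeats_near_breakpoints(genome, events, window=5)
    n_wide = int(wide[wide.junction == feat.start].n_repeats.iloc[0])
    n_narrow = int(narrow[narrow.junction == feat.start].n_repeats.iloc[0])
    # the planted copy sits 10 bp out: inside the 50 bp window, outside the
    # 5 bp one; AT-rich background may contribute equally to both
    assert n_wide >= n_narrow + 1


def test_repeat_inside_cr_counts_in_cr_table(anc):
    from mitorearr.synthetic_data import SimConfig, synthesize_genome

    cfg = SimConfig(seed=41, n_events=0, planted_repeats=(("direct", 30, 2),))
    genome = synthesize_genome(anc, cfg)
    _, cr_bins = repeats_near_breakpoints(genome, [], window=50)
    assert cr_bins.b21_50 >= 1
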