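"""Signed gene orders: anchoring, breakpoint distance, segments, ancestry."""

import itertools

import numpy as np
import pytest

from mitoremodel import gene_order as go
from mitoremodel import synth
from mitoremodel.genome_io import AnnotatedMitogenome, GeneFeature, PCGS
from mitoremodel.gene_order import (SignedGeneOrder, anchor_order,
                                    adjacency_set, breakpoint_distance,
                                    rearranged_segments,
                                    infer_ancestral_order, order_from_genome)


def order_of(genes, gid="O", topology="circular"):
    return SignedGeneOrder(gid, tuple(genes), topology)


def brute_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Independent oracle: count adjacencies of `a` conserved in `b` by
    scanning b's consecutive pairs in both strand readings."""

    def pairs(o):
        g = list(o.genes)
        n = len(g)
        ps = [(g[i], g[(i + 1) % n]) for i in range(n)]
        return ps if o.topology == "circular" else ps[:-1]

    conserved = set(pairs(b)) | set(pairs(b.reflected()))
    return sum(1 for p in pairs(a) if p not in conserved)


# anchoring -------------------------------------------------------------------


def test_order_from_genome_matches_feature_order(two_family,
                                                 template_orders):
    _, template_pcg, _ = template_orders
    ancestral = next(g for g in two_family.genomes if g.id == "B1")
    order = order_from_genome(ancestral, classes=("PCG",))
    assert order.genes == template_pcg.genes
    assert order.genes[0] == ("COX1", 1)
    assert order.genes[1][0] == "COX2"  # ancestral neighbor downstream


def test_anchor_reflects_minus_strand_cox1():
    genes = (("ND2", -1), ("ND3", -1), ("COX1", -1))
    anchored = anchor_order(order_of(genes))
    assert anchored.genes == (("COX1", 1), ("ND3", 1), ("ND2", 1))


def test_trna_class_filter(two_family):
    g = next(x for x in two_family.genomes if x.id == "B3")  # all 22 tRNAs
    order = order_from_genome(g, classes=("tRNA",), anchor=None)
    assert len(order.genes) == 22


def test_duplicate_labels_rejected():
    feats = [GeneFeature("COX1", "PCG", 0, 9, 1),
             GeneFeature("COX1", "PCG", 20, 29, 1)]
    g = AnnotatedMitogenome("D", "A" * 40, "circular", feats)
    with pytest.raises(go.GeneOrderError, match="COX1"):
        order_from_genome(g, anchor=None)


def test_anchor_absent_raises():
    with pytest.raises(go.GeneOrderError, match="COX1"):
        anchor_order(order_of((("ND1", 1), ("ND2", 1))))


# adjacencies -----------------------------------------------------------------


def test_adjacency_counts():
    circ = order_of((("a", 1), ("b", 1), ("c", 1)))
    lin = order_of((("a", 1), ("b", 1), ("c", 1)), topology="linear")
    assert len(adjacency_set(circ)) == 3
    assert len(adjacency_set(lin)) == 2


def test_adjacency_identifies_reverse_reading():
    a = order_of((("a", 1), ("b", 1)))
    b = order_of((("b", -1), ("a", -1)))
    assert adjacency_set(a) == adjacency_set(b)


# breakpoint distance ---------------------------------------------------------


def test_distance_zero_on_identical_and_transformed():
    o = order_of((("a", 1), ("b", -1), ("c", 1), ("d", 1), ("e", -1)))
    assert breakpoint_distance(o, o) == 0
    assert breakpoint_distance(o, o.rotated(2)) == 0
    assert breakpoint_distance(o, o.reflected()) == 0


def test_distance_transposition_example():
    """Swapping two neighbors breaks 2 unsigned adjacencies; the signed
    distance also counts the now strand-inconsistent (2,3) pairing."""
    a = order_of(tuple((str(i), 1) for i in (1, 2, 3, 4, 5)))
    b = order_of(tuple((str(i), 1) for i in (1, 3, 2, 4, 5)))
    assert breakpoint_distance(a, b, strand_aware=False) == 2
    assert breakpoint_distance(a, b) == 3
    assert brute_distance(a, b) == 3


def test_distance_mismatched_labels_lists_difference():
    a = order_of((("a", 1), ("b", 1)))
    b = order_of((("a", 1), ("c", 1)))
    with pytest.raises(go.GeneOrderError, match=r"\['b', 'c'\]"):
        breakpoint_distance(a, b)


def test_strand_blind_ignores_pure_flips():
    a = order_of((("a", 1), ("b", 1), ("c", 1), ("d", 1)))
    flipped = order_of((("a", 1), ("b", -1), ("c", 1), ("d", 1)))
    assert breakpoint_distance(a, flipped) == 2  # strand-aware default
    assert breakpoint_distance(a, flipped, strand_aware=False) == 0


def test_distance_matches_brute_oracle_exhaustively():
    """All signed circular orders of 4 genes versus a fixed reference."""
    labels = ["a", "b", "c", "d"]
    ref = order_of(tuple((x, 1) for x in labels))
    for perm in itertools.permutations(labels[1:]):
        for signs in itertools.product((1, -1), repeat=4):
            genes = tuple(zip([labels[0], *perm], signs))
            o = order_of(genes)
            assert breakpoint_distance(o, ref) == brute_distance(o, ref)
            assert breakpoint_distance(o, ref) == breakpoint_distance(ref, o)


def test_distance_random_13_gene_orders_match_oracle():
    rng = np.random.default_rng(13)
    labels = [f"g{i}" for i in range(13)]
    for _ in range(100):
        perm = rng.permutation(13)
        signs = rng.choice([1, -1], size=13)
        a = order_of(tuple((labels[perm[i]], int(signs[i]))
                           for i in range(13)))
        ref = order_of(tuple((x, 1) for x in labels))
        d = breakpoint_distance(a, ref)
        assert d == brute_distance(a, ref)
        k = int(rng.integers(0, 13))
        assert breakpoint_distance(a.rotated(k), ref) == d
        assert breakpoint_distance(a.reflected(), ref) == d


def test_inversions_break_at_most_two_adjacencies_each():
    template, _ = synth.ancestral_template()
    rng = np.random.default_rng(99)
    for _ in range(300):
        k = int(rng.integers(1, 5))
        invs = synth.random_inversions(rng, len(template.genes), k)
        derived = synth.apply_inversions(template, invs)
        assert breakpoint_distance(derived, template) <= 2 * k


# rearranged segments ---------------------------------------------------------


def test_segments_empty_iff_identical():
    o = order_of(tuple((str(i), 1) for i in range(8)))
    assert rearranged_segments(o, o) == []
    assert rearranged_segments(o.rotated(3), o) == []


def test_single_inversion_yields_exactly_that_block():
    genes = [(f"g{i}", 1) for i in range(10)]
    ref = order_of(tuple(genes))
    inverted = genes[:3] + [(g, -s) for g, s in reversed(genes[3:6])] \
        + genes[6:]
    segs = rearranged_segments(order_of(tuple(inverted)), ref)
    assert segs == [(("g5", -1), ("g4", -1), ("g3", -1))]


def test_fully_shuffled_yields_one_segment_of_non_anchor_genes():
    rng = np.random.default_rng(1)
    labels = [f"g{i}" for i in range(12)]
    ref = order_of(tuple((x, 1) for x in labels))
    perm = ["g0"] + [labels[i] for i in rng.permutation(np.arange(1, 12))]
    shuffled = order_of(tuple((x, 1) for x in perm))
    assert breakpoint_distance(shuffled, ref) > 0
    segs = rearranged_segments(shuffled, ref)
    if len(segs) == 1:  # generic shuffle: everything but the anchor moved
        assert {g for g, _ in segs[0]} == set(perm[1:])


def test_every_segment_is_flanked_by_broken_adjacencies(two_family,
                                                        template_orders):
    _, template_pcg, _ = template_orders
    derived = order_from_genome(
        next(g for g in two_family.genomes if g.id == "A1"))
    ref_adj = adjacency_set(template_pcg)
    segs = rearranged_segments(derived, template_pcg)
    assert segs  # the derived family is rearranged
    genes = list(derived.genes)
    n = len(genes)
    for seg in segs:
        i = genes.index(seg[0])
        j = genes.index(seg[-1])
        left = go._canon(genes[(i - 1) % n], genes[i])
        right = go._canon(genes[j], genes[(j + 1) % n])
        assert left not in ref_adj
        assert right not in ref_adj


# ancestral inference ---------------------------------------------------------


def star_tree(ids, outgroup="OUT"):
    return f"({outgroup},{','.join(ids)});"


def test_identical_orders_recover_themselves(template_orders):
    full, _, _ = template_orders
    orders = {f"S{i}": SignedGeneOrder(f"S{i}", full.genes, "circular")
              for i in range(4)}
    orders["OUT"] = SignedGeneOrder("OUT", full.genes, "circular")
    anc, fallback = infer_ancestral_order(
        orders, star_tree([f"S{i}" for i in range(4)]), "OUT")
    assert anc.genes == anchor_order(full).genes
    assert not fallback


def test_one_shuffled_lineage_does_not_distort_ancestor(template_orders):
    """Outgroup = template; three template ingroup lineages plus one heavily
    rearranged one: the ancestor stays the template."""
    full, _, _ = template_orders
    rng = np.random.default_rng(8)
    shuffled = synth.apply_inversions(
        full, synth.random_inversions(rng, len(full.genes), 6))
    orders = {
        "S0": SignedGeneOrder("S0", full.genes, "circular"),
        "S1": SignedGeneOrder("S1", full.genes, "circular"),
        "S2": SignedGeneOrder("S2", full.genes, "circular"),
        "S3": SignedGeneOrder("S3", shuffled.genes, "circular"),
        "OUT": SignedGeneOrder("OUT", full.genes, "circular"),
    }
    anc, _ = infer_ancestral_order(
        orders, star_tree(["S0", "S1", "S2", "S3"]), "OUT")
    assert anc.genes == anchor_order(full).genes


def test_bifurcating_tree_recovery(template_orders):
    full, _, _ = template_orders
    rng = np.random.default_rng(17)
    moved = synth.apply_inversions(
        full, synth.random_inversions(rng, len(full.genes), 2))
    orders = {
        "A": SignedGeneOrder("A", full.genes, "circular"),
        "B": SignedGeneOrder("B", moved.genes, "circular"),
        "C": SignedGeneOrder("C", full.genes, "circular"),
        "D": SignedGeneOrder("D", full.genes, "circular"),
        "OUT": SignedGeneOrder("OUT", full.genes, "circular"),
    }
    anc, _ = infer_ancestral_order(orders, "(OUT,((A,B),(C,D)));", "OUT")
    assert anc.genes == anchor_order(full).genes


def test_missing_outgroup_rejected(template_orders):
    full, _, _ = template_orders
    orders = {"S0": SignedGeneOrder("S0", full.genes, "circular")}
    with pytest.raises(go.GeneOrderError):
        infer_ancestral_order(orders, "(S0);", "OUT")
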