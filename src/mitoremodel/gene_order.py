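"""Mitochondrial gene order as circular signed permutations.

A gene order is the circular sequence of gene labels with orientation signs.
Orders are compared through their signed adjacencies: the ordered pair
``(a -> b)`` of consecutive genes, identified with its reading on the other
strand ``(-b -> -a)``. The breakpoint distance counts adjacencies of one
order absent from the other; it is invariant to rotation and reflection, the
two symmetries of a circular genome with arbitrary strand choice.

Ancestral gene orders are inferred by adjacency parsimony over a rooted tree
with an outgroup, then greedily assembled into a single circular tour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy

from .genome_io import (AnnotatedMitogenome, CANONICAL, PCG, RRNA, TRNA)

logger = logging.getLogger(__name__)

SignedGene = tuple[str, int]
Adjacency = tuple[SignedGene, SignedGene]

ALL_CLASSES = frozenset({PCG, RRNA, TRNA})


class GeneOrderError(ValueError):
    pass


@dataclass(frozen=True)
class SignedGeneOrder:
    """Circular (or linear) signed permutation of gene labels."""

    genome_id: str
    genes: tuple[SignedGene, ...]
    topology: str = "circular"
    classes_included: frozenset = field(default=ALL_CLASSES)

    def __post_init__(self):
        labels = [g for g, _ in self.genes]
        if len(set(labels)) != len(labels):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise GeneOrderError(f"duplicate gene labels: {dups}")

    @property
    def labels(self) -> frozenset:
        return frozenset(g for g, _ in self.genes)

    def rotated(self, k: int) -> "SignedGeneOrder":
        return replace(self, genes=self.genes[k:] + self.genes[:k])

    def reflected(self) -> "SignedGeneOrder":
        return replace(self, genes=tuple((g, -s)
                                         for g, s in reversed(self.genes)))


def anchor_order(order: SignedGeneOrder,
                 anchor: str = "COX1") -> SignedGeneOrder:
    """Rotate so the anchor gene comes first; reflect first if the anchor is
    on the minus strand, so the anchored order always begins (anchor, +1)."""
    labels = [g for g, _ in order.genes]
    if anchor not in labels:
        raise GeneOrderError(f"{order.genome_id}: anchor {anchor} absent")
    i = labels.index(anchor)
    if order.genes[i][1] == -1:
        order = order.reflected()
        labels = [g for g, _ in order.genes]
        i = labels.index(anchor)
    return order.rotated(i)


def order_from_genome(genome: AnnotatedMitogenome,
                      classes=(PCG,),
                      anchor: str | None = "COX1") -> SignedGeneOrder:
    """Gene order from annotated features, filtered to the given classes.

    Features are taken in start-coordinate order with signs from strand.
    Unknown and ambiguous-isoacceptor labels (trnL?/trnS?) are excluded.
    """
    classes = frozenset(classes)
    feats = sorted((f for f in genome.features if f.cls in classes),
                   key=lambda f: (f.start, f.end))
    genes = []
    for f in feats:
        if f.label not in CANONICAL:
            logger.warning("%s: excluding non-canonical label %r from order",
                           genome.id, f.label)
            continue
        genes.append((f.label, f.strand))
    order = SignedGeneOrder(genome.id, tuple(genes), genome.topology, classes)
    if anchor is not None:
        order = anchor_order(order, anchor)
    return order


# adjacencies and breakpoint distance ----------------------------------------


def _canon(a: SignedGene, b: SignedGene, signed: bool = True):
    """Canonical form of the adjacency a->b, identified with (-b)->(-a)."""
    if not signed:
        pair = (a[0], b[0])
        return min(pair, (b[0], a[0]))
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def adjacency_set(order: SignedGeneOrder, signed: bool = True) -> frozenset:
    """Signed adjacencies of consecutive genes; circular orders include the
    wrap-around pair last->first."""
    if not order.genes:
        raise GeneOrderError("empty gene order")
    genes = order.genes
    pairs = list(zip(genes, genes[1:]))
    if order.topology == "circular" and len(genes) > 1:
        pairs.append((genes[-1], genes[0]))
    return frozenset(_canon(a, b, signed) for a, b in pairs)


def _check_comparable(a: SignedGeneOrder, b: SignedGeneOrder) -> None:
    if a.topology != b.topology:
        raise GeneOrderError(
            f"topology mismatch: {a.topology} vs {b.topology}")
    if a.labels != b.labels:
        diff = sorted(a.labels ^ b.labels)
        raise GeneOrderError(f"label sets differ by: {diff}")


def breakpoint_distance(a: SignedGeneOrder, b: SignedGeneOrder,
                        strand_aware: bool = True) -> int:
    """Number of adjacencies of ``a`` not conserved in ``b``.

    For circular orders of n genes this is n - |shared adjacencies| (n-1 for
    linear); zero iff the orders coincide up to rotation and reflection.
    ``strand_aware=False`` ignores signs, so a pure strand flip of one gene
    does not count as rearrangement.
    """
    _check_comparable(a, b)
    sa = adjacency_set(a, signed=strand_aware)
    sb = adjacency_set(b, signed=strand_aware)
    n = len(a.genes) if a.topology == "circular" else len(a.genes) - 1
    return n - len(sa & sb)


def rearranged_segments(target: SignedGeneOrder,
                        reference: SignedGeneOrder,
                        strand_aware: bool = True) -> list[tuple[SignedGene, ...]]:
    """Maximal runs of genes in ``target`` displaced relative to ``reference``.

    Broken adjacencies (present in target, absent from reference) cut the
    circular target into arcs of conserved adjacency. The arc containing the
    first (anchor) gene is the conserved backbone; the complement, merged
    into maximal runs, is reported as rearranged segments. Empty iff the
    breakpoint distance is zero.
    """
    _check_comparable(target, reference)
    genes = target.genes
    n = len(genes)
    if n < 2:
        return []
    ref_adj = adjacency_set(reference, signed=strand_aware)
    circular = target.topology == "circular"

    def conserved(i: int) -> bool:
        """Adjacency between genes[i] and genes[(i+1) % n]."""
        if not circular and i == n - 1:
            return False  # linear ends are boundaries, not adjacencies
        return _canon(genes[i], genes[(i + 1) % n], strand_aware) in ref_adj

    if all(conserved(i) for i in range(n if circular else n - 1)):
        return []
    # backbone = conserved-adjacency arc containing the anchor (index 0)
    backbone = {0}
    i = 0
    while conserved(i):  # extend rightwards
        i = (i + 1) % n
        if i in backbone:
            break
        backbone.add(i)
    j = 0
    while conserved((j - 1) % n):  # extend leftwards
        j = (j - 1) % n
        if j in backbone:
            break
        backbone.add(j)
    # segments = maximal index runs outside the backbone (index 0 is always
    # in the backbone, so runs never wrap the list boundary)
    segments: list[list[int]] = []
    for i in (k for k in range(n) if k not in backbone):
        if segments and segments[-1][-1] == i - 1:
            segments[-1].append(i)
        else:
            segments.append([i])
    return [tuple(genes[i] for i in seg) for seg in segments]


# ancestral inference ---------------------------------------------------------

_HEAD, _TAIL = "h", "t"


def _ends(adj: Adjacency):
    (a, sa), (b, sb) = adj
    out_end = (a, _HEAD if sa > 0 else _TAIL)
    in_end = (b, _TAIL if sb > 0 else _HEAD)
    return out_end, in_end


class _DSU:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        self.parent[self.find(x)] = self.find(y)


def _load_tree(tree, taxa: set) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" not in text:  # a path
        return dendropy.Tree.get(path=text, schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


def _fitch_sets(node, orders, signed=True):
    """Set-valued parsimony: intersection of child sets when nonempty,
    else union."""
    if node.is_leaf():
        tid = node.taxon.label
        return adjacency_set(orders[tid], signed=signed)
    child_sets = [_fitch_sets(c, orders, signed) for c in node.child_nodes()]
    inter = frozenset.intersection(*child_sets)
    return inter if inter else frozenset.union(*child_sets)


def infer_ancestral_order(orders: dict[str, SignedGeneOrder], tree,
                          outgroup_id: str,
                          anchor: str = "COX1",
                          ) -> tuple[SignedGeneOrder, bool]:
    """Infer the gene order of the ingroup's last common ancestor.

    Adjacency presence is propagated by set-valued (Fitch-style) parsimony
    from the tips to the ingroup root; the root candidate set is then
    greedily assembled into one circular tour, preferring adjacencies shared
    with the outgroup, then higher ingroup support, ties broken
    lexicographically. If the candidate set cannot complete a tour, the
    outgroup's own adjacencies supplement it; the returned flag is True when
    that fallback was needed.
    """
    if outgroup_id not in orders:
        raise GeneOrderError(f"outgroup {outgroup_id!r} has no gene order")
    ingroup = {k: v for k, v in orders.items() if k != outgroup_id}
    if not ingroup:
        raise GeneOrderError("no ingroup orders")
    label_sets = {frozenset(o.labels) for o in orders.values()}
    if len(label_sets) != 1:
        raise GeneOrderError("gene orders carry different label sets")
    labels = sorted(next(iter(label_sets)))
    n = len(labels)

    t = _load_tree(tree, set(orders))
    tip_labels = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = set(orders) - tip_labels
    if missing:
        raise GeneOrderError(f"tree lacks tips for: {sorted(missing)}")
    og_node = t.find_node_with_taxon_label(outgroup_id)
    if og_node is None:
        raise GeneOrderError(f"outgroup {outgroup_id!r} not in tree")
    t.reroot_at_edge(og_node.edge, update_bipartitions=False)

    ingroup_children = [c for c in t.seed_node.child_nodes()
                        if not (c.is_leaf() and c.taxon.label == outgroup_id)]
    child_sets = [_fitch_sets(c, orders) for c in ingroup_children]
    inter = frozenset.intersection(*child_sets)
    candidate = inter if inter else frozenset.union(*child_sets)

    og_adj = adjacency_set(orders[outgroup_id])
    support = {}
    for o in ingroup.values():
        for adj in adjacency_set(o):
            support[adj] = support.get(adj, 0) + 1

    ranked = sorted(candidate,
                    key=lambda adj: (adj not in og_adj,
                                     -support.get(adj, 0), adj))
    fallback = [adj for adj in sorted(og_adj) if adj not in candidate]

    dsu = _DSU()
    used_ends: set = set()
    chosen: list[Adjacency] = []
    used_fallback = False
    for pool, is_fallback in ((ranked, False), (fallback, True)):
        for adj in pool:
            if len(chosen) == n:
                break
            out_end, in_end = _ends(adj)
            if out_end in used_ends or in_end in used_ends:
                continue  # each physical gene end joins one neighbor
            a, b = out_end[0], in_end[0]
            if dsu.find(a) == dsu.find(b) and len(chosen) < n - 1:
                continue  # would close a premature sub-cycle
            used_ends.add(out_end)
            used_ends.add(in_end)
            dsu.union(a, b)
            chosen.append(adj)
            if is_fallback:
                used_fallback = True
    if len(chosen) < n:
        raise GeneOrderError(
            "could not assemble a circular ancestral tour "
            f"({len(chosen)}/{n} adjacencies placed)")

    # walk the tour starting from the anchor (or first label) on +
    nxt = {}
    for adj in chosen:
        (a, sa), (b, sb) = adj
        nxt[(a, sa)] = (b, sb)
        nxt[(b, -sb)] = (a, -sa)  # reverse reading of the same adjacency
    start_label = anchor if anchor in labels else labels[0]
    cur = (start_label, 1)
    genes = [cur]
    for _ in range(n - 1):
        cur = nxt[cur]
        genes.append(cur)
    any_order = next(iter(orders.values()))
    result = SignedGeneOrder("ancestor", tuple(genes), "circular",
                             any_order.classes_included)
    return anchor_order(result, start_label), used_fallback


def pairwise_distance_matrix(orders: dict[str, SignedGeneOrder],
                             strand_aware: bool = True):
    """Symmetric breakpoint-distance matrix as a nested dict."""
    ids = sorted(orders)
    return {
        a: {b: breakpoint_distance(orders[a], orders[b],
                                   strand_aware=strand_aware) for b in ids}
        for a in ids
    }
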