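"""tRNA repertoire scoring and conserved tRNA-cluster detection.

Metazoan mitogenomes canonically carry 22 tRNAs; velvet worms frequently
lose or truncate some of them, and the two families differ both in which
tRNAs remain and in how surviving tRNAs are grouped into contiguous clusters
(runs of consecutive tRNA genes with no intervening protein-coding or rRNA
gene). This module scores presence/absence against the canonical complement
and finds clusters conserved across every genome of a group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome_io import TRNA, TRNAS
from .gene_order import SignedGeneOrder, SignedGene

logger = logging.getLogger(__name__)


def presence_matrix(genomes) -> pd.DataFrame:
    """Genomes x 22 canonical tRNA labels, 0/1.

    Duplicated tRNA annotations count once (and are logged); ambiguous
    isoacceptors (trnL?/trnS?) do not score.
    """
    rows = {}
    for g in genomes:
        seen = set()
        for f in g.features:
            if f.cls != TRNA or f.label not in TRNAS:
                continue
            if f.label in seen:
                logger.warning("%s: duplicate tRNA %s counted once",
                               g.id, f.label)
            seen.add(f.label)
        rows[g.id] = {t: int(t in seen) for t in TRNAS}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TRNAS))
    df.index.name = "genome_id"
    return df


@dataclass(frozen=True)
class TrnaCluster:
    """A run of >= 2 consecutive tRNAs conserved in every genome of a group."""

    members: tuple[SignedGene, ...]
    group: str
    genomes: tuple[str, ...]
    shared_by_groups: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return "-".join(lbl for lbl, _ in self.members)


def _reflect(block: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
    return tuple((lbl, -s) for lbl, s in reversed(block))


def _canon_block(block: tuple[SignedGene, ...],
                 ignore_strand: bool) -> tuple:
    if ignore_strand:
        seq = tuple(lbl for lbl, _ in block)
        return min(seq, tuple(reversed(seq)))
    return min(block, _reflect(block))


def _trna_runs(order: SignedGeneOrder) -> list[tuple[SignedGene, ...]]:
    """Maximal runs of consecutive tRNAs (circular runs may wrap)."""
    genes = list(order.genes)
    n = len(genes)
    is_t = [lbl in TRNAS for lbl, _ in genes]
    if not any(is_t):
        return []
    if all(is_t):
        return [tuple(genes)]
    if order.topology == "circular":
        # rotate so index 0 is a non-tRNA: runs then never wrap
        k = is_t.index(False)
        genes = genes[k:] + genes[:k]
        is_t = is_t[k:] + is_t[:k]
    runs, cur = [], []
    for g, t in zip(genes, is_t):
        if t:
            cur.append(g)
        elif cur:
            runs.append(tuple(cur))
            cur = []
    if cur:
        runs.append(tuple(cur))
    return runs


def _blocks(order: SignedGeneOrder, ignore_strand: bool) -> dict:
    """All contiguous tRNA sub-blocks of length >= 2, canonicalized.

    Maps canonical form -> one representative reading (for display).
    """
    out = {}
    for run in _trna_runs(order):
        m = len(run)
        for i in range(m):
            for j in range(i + 2, m + 1):
                block = run[i:j]
                out.setdefault(_canon_block(block, ignore_strand), block)
    return out


def shared_clusters(orders: dict[str, SignedGeneOrder],
                    groups: dict[str, str],
                    ignore_strand: bool = False) -> list[TrnaCluster]:
    """Maximal tRNA clusters present in every genome of each group.

    ``orders`` must be tRNA-inclusive (all gene classes), COX1-anchored
    gene orders; matching requires identical internal order and, by default,
    identical strands, with reflection-equivalent readings merged. The
    ``shared_by_groups`` field lists every group whose members all carry the
    cluster, enabling group-exclusive cluster identification.
    """
    by_group: dict[str, list[str]] = {}
    for gid, grp in groups.items():
        if gid in orders:
            by_group.setdefault(grp, []).append(gid)
    for grp, members in by_group.items():
        if not members:
            raise ValueError(f"group {grp!r} has no genomes")
    if not by_group:
        raise ValueError("no genomes assigned to any group")

    block_maps = {gid: _blocks(orders[gid], ignore_strand)
                  for grp in by_group for gid in by_group[grp]}

    group_shared: dict[str, dict] = {}
    for grp, members in sorted(by_group.items()):
        common = set(block_maps[members[0]])
        rep = block_maps[members[0]]
        for gid in members[1:]:
            common &= set(block_maps[gid])
        group_shared[grp] = {c: rep[c] for c in common}

    def contained(small: tuple, big_repr: tuple[SignedGene, ...],
                  ignore: bool) -> bool:
        m = len(small[0]) if ignore else len(small)
        # compare canonical forms of all sub-blocks of the big block
        n = len(big_repr)
        for i in range(n):
            for j in range(i + 2, n + 1):
                if _canon_block(big_repr[i:j], ignore) == small:
                    return True
        return False

    clusters: list[TrnaCluster] = []
    for grp, shared in sorted(group_shared.items()):
        maximal = []
        for canon, block in shared.items():
            bigger = any(
                len(other_rep) > len(block)
                and contained(canon, other_rep, ignore_strand)
                for other_canon, other_rep in shared.items()
                if other_canon != canon)
            if not bigger:
                maximal.append((canon, block))
        for canon, block in sorted(maximal, key=lambda x: (-len(x[1]), x[1])):
            sharing = tuple(
                g2 for g2, shared2 in sorted(group_shared.items())
                if canon in shared2)
            clusters.append(TrnaCluster(
                members=block, group=grp,
                genomes=tuple(sorted(by_group[grp])),
                shared_by_groups=sharing))
    return clusters


def clusters_to_records(clusters) -> list[dict]:
    """JSON-serializable view of a cluster list."""
    return [
        {"group": c.group, "name": c.name,
         "members": [[lbl, s] for lbl, s in c.members],
         "genomes": list(c.genomes),
         "shared_by_groups": list(c.shared_by_groups)}
        for c in clusters
    ]
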