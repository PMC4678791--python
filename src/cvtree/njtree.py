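"""Neighbor-joining tree inference, outgroup rooting and Newick output.

Trees are :class:`dendropy.Tree` objects; leaves carry genome ids as taxon
labels.  The agglomeration method is standard Saitou–Nei neighbor joining
with one extra contract: ties in the Q-criterion are broken by the
lexicographically smallest pair of cluster keys (a cluster's key is the
smallest genome id it contains), so the whole pipeline is reproducible.

Branch lengths are estimated and retained internally (negative values are
not clamped — they are diagnostic only) but the method's product is the
branching order: Newick output omits lengths unless explicitly requested.
"""

from __future__ import annotations

from pathlib import Path

import dendropy

from .distance import DistanceMatrix
from .errors import DataError, OutgroupError


def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Infer the unrooted NJ tree from a distance matrix (n >= 3).

    Iteratively joins the pair of clusters minimising
    ``Q(i,j) = (N-2) d(i,j) - r(i) - r(j)``; exact Q ties fall back to the
    lexicographic cluster-key order.  The result is an unrooted binary tree
    whose seed node has degree 3.
    """
    m.validate()
    n = len(m.ids)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 genomes, got {n}")
    taxa = dendropy.TaxonNamespace(m.ids)

    nodes: dict[int, dendropy.Node] = {}
    keys: dict[int, str] = {}
    for i, gid in enumerate(m.ids):
        nodes[i] = dendropy.Node(taxon=taxa.get_taxon(gid))
        keys[i] = gid
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(m.d[i, j])

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    active = list(range(n))
    next_label = n
    while len(active) > 3:
        big_n = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        bi = bj = -1
        for x in range(big_n):
            for y in range(x + 1, big_n):
                i, j = active[x], active[y]
                q = (big_n - 2) * d(i, j) - r[i] - r[j]
                cand = (q, min(keys[i], keys[j]), max(keys[i], keys[j]))
                if best is None or cand < best:
                    best, bi, bj = cand, i, j
        dij = d(bi, bj)
        li = dij / 2.0 + (r[bi] - r[bj]) / (2.0 * (big_n - 2))
        lj = dij - li
        u = dendropy.Node()
        a, b = (bi, bj) if keys[bi] <= keys[bj] else (bj, bi)
        la, lb = (li, lj) if a == bi else (lj, li)
        u.add_child(nodes[a])
        u.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        for k in active:
            if k in (bi, bj):
                continue
            duk = (d(bi, k) + d(bj, k) - dij) / 2.0
            lo, hi = (next_label, k) if next_label < k else (k, next_label)
            dist[(lo, hi)] = duk
        nodes[next_label] = u
        keys[next_label] = min(keys[bi], keys[bj])
        active = [k for k in active if k not in (bi, bj)] + [next_label]
        next_label += 1

    # final three clusters join at one internal node (the unrooted centre)
    i, j, k = sorted(active, key=lambda t: keys[t])
    centre = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        va = (d(a, b) + d(a, c) - d(b, c)) / 2.0
        centre.add_child(nodes[a])
        nodes[a].edge.length = va
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=centre)
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_ids: set[str], hide_outgroup: bool = False
) -> dendropy.Tree:
    """Root the tree at the midpoint of the outgroup/ingroup edge.

    The outgroup must form one side of some edge of the (unrooted) tree;
    otherwise an :class:`OutgroupError` is raised rather than forcing a
    root.  With ``hide_outgroup`` the outgroup leaves are pruned from the
    returned rooted tree (display counts then cover the ingroup only).
    The input tree is not modified.
    """
    outgroup_ids = set(outgroup_ids)
    leaves = leaf_labels(tree)
    if not outgroup_ids:
        raise OutgroupError("empty outgroup")
    if not outgroup_ids <= leaves:
        raise OutgroupError(f"outgroup ids not in tree: {sorted(outgroup_ids - leaves)}")
    if outgroup_ids == leaves:
        raise OutgroupError("outgroup cannot contain every leaf")

    work = tree.clone(depth=1)
    target = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == outgroup_ids or (leaves - below) == outgroup_ids:
            target = node
            break
    if target is None:
        raise OutgroupError(
            f"outgroup {sorted(outgroup_ids)} does not form one side of any edge "
            "(not contiguous in the tree)"
        )
    edge_len = target.edge.length
    half = edge_len / 2.0 if edge_len is not None else None
    work.reroot_at_edge(target.edge, update_bipartitions=False)
    work.is_rooted = True
    root_children = work.seed_node.child_nodes()
    if half is not None and len(root_children) == 2:
        for ch in root_children:
            ch.edge.length = half
    if hide_outgroup:
        keep = leaves - outgroup_ids
        work.retain_taxa_with_labels(sorted(keep))
    return work


def write_newick(tree: dendropy.Tree, with_lengths: bool = False) -> str:
    """Serialise as Newick; topology-only by default (no branch lengths)."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=not with_lengths,
        unquoted_underscores=True,
        preserve_spaces=True,
    )
    return s.strip()


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a string or a file path.

    Unquoted underscores are kept verbatim (genome ids routinely contain
    them), departing from the bare Newick space convention.
    """
    looks_like_data = isinstance(source, str) and ("(" in source or ";" in source)
    if isinstance(source, Path) or (not looks_like_data and Path(source).exists()):
        return dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits, each normalised to the side without the smallest leaf."""
    leaves = frozenset(leaf_labels(tree))
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(leaves) - 1:
            continue
        if ref in below:
            below = leaves - below
        splits.add(below)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds (symmetric-difference) distance on unrooted splits."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, only in second {sorted(l2 - l1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """Unrooted-topology equality (identical leaf sets, RF distance 0)."""
    return leaf_labels(t1) == leaf_labels(t2) and rf_distance(t1, t2) == 0
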