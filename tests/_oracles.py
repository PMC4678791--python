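"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (substring enumeration, exhaustive
clade listing, BFS path lengths) and shares no code with the package paths
it checks.
"""

from __future__ import annotations

import random

from cvtree.cvcore import CANONICAL_ALPHABET

CANON = set(CANONICAL_ALPHABET)


def naive_kmer_counts(proteins: list[str], k: int) -> dict[str, int]:
    """Count length-k windows by direct substring enumeration."""
    counts: dict[str, int] = {}
    for seq in proteins:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if all(ch in CANON for ch in w):
                counts[w] = counts.get(w, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Random trees as nested tuples; leaves are strings.

def random_binary_topology(labels: list[str], rng: random.Random):
    """Random rooted binary tree over ``labels`` by random pair joins."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append((a, b))
    return nodes[0]


def tree_leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return [lf for child in node for lf in tree_leaves(child)]


def to_newick(node, lengths: dict | None = None) -> str:
    """Render a nested-tuple tree; ``lengths`` maps id(subtree) -> length."""

    def render(nd):
        body = nd if isinstance(nd, str) else "(" + ",".join(render(c) for c in nd) + ")"
        if lengths is not None and id(nd) in lengths:
            return f"{body}:{lengths[id(nd)]}"
        return body

    return render(node) + ";"


def all_clades(node) -> list[frozenset[str]]:
    """Leaf sets of every node of a rooted nested-tuple tree."""
    out: list[frozenset[str]] = []

    def walk(nd) -> frozenset[str]:
        if isinstance(nd, str):
            s = frozenset([nd])
        else:
            s = frozenset().union(*(walk(c) for c in nd))
        out.append(s)
        return s

    walk(node)
    return out


def brute_force_clusters(node, members: set[str]) -> list[int]:
    """Sizes (descending) of maximal clades containing only members,
    found by exhaustive clade enumeration."""
    pure = [c for c in all_clades(node) if c <= members]
    maximal = [c for c in pure if not any(c < d for d in pure)]
    covered = frozenset().union(*maximal) if maximal else frozenset()
    assert covered == frozenset(members), "maximal pure clades must partition members"
    return sorted((len(c) for c in maximal), reverse=True)


def additive_distances(node, edge_lengths: dict) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths via BFS over an adjacency map.

    ``edge_lengths`` maps id(subtree) -> length of the edge above it.
    """
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str] = {}

    def walk(nd):
        if isinstance(nd, str):
            labels[id(nd)] = nd
        else:
            for c in nd:
                w = edge_lengths[id(c)]
                adj.setdefault(id(nd), []).append((id(c), w))
                adj.setdefault(id(c), []).append((id(nd), w))
                walk(c)

    walk(node)
    leaves = {i: lab for i, lab in labels.items()}
    dists: dict[tuple[str, str], float] = {}
    for start, lab in leaves.items():
        seen = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, w in adj.get(cur, []):
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        for other, lab2 in leaves.items():
            if lab < lab2:
                dists[(lab, lab2)] = seen[other]
    return dists


def random_additive_matrix(n: int, rng: random.Random):
    """(labels, matrix-as-dict, nested-tuple tree) with random edge lengths."""
    labels = [f"t{i:02d}" for i in range(n)]
    topo = random_binary_topology(labels, rng)
    edge_lengths: dict[int, float] = {}

    def assign(nd):
        if not isinstance(nd, str):
            for c in nd:
                edge_lengths[id(c)] = rng.uniform(0.05, 1.0)
                assign(c)

    assign(topo)
    dists = additive_distances(topo, edge_lengths)
    # rescale into [0, 1] (the dissimilarity range) preserving additivity
    scale = 0.9 / max(dists.values())
    return labels, {k: v * scale for k, v in dists.items()}, topo
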