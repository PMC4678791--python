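"""Tree-vs-taxonomy congruence: monophyly, convergence, collapsing, reports.

A taxon is *monophyletic* (operationally, relative to the input genome set
and the reference classification) when all of its genomes appear
exclusively as the leaves of a single clade of the inferred tree.  A taxon
whose genomes fall into several maximal pure clades is *convergent*; its
clusters are reported as ``Name{k/n}`` (k genomes of the taxon's n in one
cluster).  Collapsed branches are labelled ``<R>Name{n + m}`` where n
genomes carry complete nine-rank lineages and m incomplete ones; ``{n}``
is rendered when m = 0 and ``{0 + m}`` when n = 0.

Taxon buckets are keyed by the full lineage prefix down to the rank under
study, not by the bare name, so homonymous taxa under different parents
never merge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .io_lineage import RANKS, UNCLASSIFIED, LineageTable
from .njtree import leaf_labels, root_with_outgroup

#: Ranks at which taxa are reported: Domain down to Species (strains are
#: leaves, never taxa of their own).
REPORT_RANKS: tuple[str, ...] = RANKS[:-1]


def format_nm(n: int, m: int) -> str:
    """Render the {n + m} complete/incomplete membership annotation."""
    if m == 0:
        return f"{{{n}}}"
    if n == 0:
        return f"{{0 + {m}}}"
    return f"{{{n} + {m}}}"


@dataclass
class TaxonStatus:
    """Monophyly verdict for one taxon at one rank."""

    rank: str
    name: str
    n_complete: int
    n_incomplete: int
    status: str  # "monophyletic" | "convergent" | "singleton"
    clusters: list[int]
    prefix: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if sum(self.clusters) != self.n_complete + self.n_incomplete:
            raise ValueError(
                f"{self.name}: cluster sizes {self.clusters} do not sum to "
                f"{self.n_complete + self.n_incomplete} members"
            )

    @property
    def n_members(self) -> int:
        return self.n_complete + self.n_incomplete

    def render(self) -> str:
        """``Name{n + m}`` when monophyletic, ``Name{k/n}, ...`` when convergent."""
        if self.status == "convergent":
            total = self.n_members
            return ", ".join(f"{self.name}{{{c}/{total}}}" for c in self.clusters)
        return f"{self.name}{format_nm(self.n_complete, self.n_incomplete)}"


@dataclass
class CollapsedNode:
    """One node of a collapsed tree.

    A collapsed branch carries a ``<R>Name{n + m}`` label and the genomes it
    absorbs; an uncollapsed internal node has an empty label and children.
    """

    label: str
    member_ids: frozenset[str]
    children: list["CollapsedNode"] = field(default_factory=list)
    rank: str | None = None
    name: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_nodes(self) -> list["CollapsedNode"]:
        if self.is_leaf:
            return [self]
        out: list[CollapsedNode] = []
        for ch in self.children:
            out.extend(ch.leaf_nodes())
        return out

    def all_member_ids(self) -> set[str]:
        return {g for lf in self.leaf_nodes() for g in lf.member_ids}


def taxon_members(
    lt: LineageTable, rank: str
) -> dict[tuple[str, ...], tuple[set[str], set[str]]]:
    """Group genome ids by taxon at one rank.

    Returns a mapping from the full lineage prefix (Domain..rank, the
    homonym-safe bucket key; the taxon's display name is the last element)
    to ``(complete_ids, incomplete_ids)``.  A genome is *incomplete* when
    any of its nine ranks is Unclassified.  Genomes Unclassified at the
    requested rank form their own bucket(s).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank tag {rank!r}")
    out: dict[tuple[str, ...], tuple[set[str], set[str]]] = {}
    for gid, lin in lt.entries.items():
        key = lin.prefix(rank)
        comp, incomp = out.setdefault(key, (set(), set()))
        (comp if lin.complete else incomp).add(gid)
    return out


def _pure_clades(
    tree: dendropy.Tree, members: set[str]
) -> list[set[str]]:
    """Maximal clades whose leaves are all members; they partition members."""
    pure: dict[dendropy.Node, bool] = {}
    below: dict[dendropy.Node, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            below[node] = {lab}
            pure[node] = lab in members
        else:
            kids = node.child_nodes()
            below[node] = set().union(*(below[c] for c in kids))
            pure[node] = all(pure[c] for c in kids)
    clusters = []
    for node in tree.preorder_node_iter():
        if pure[node] and (node.parent_node is None or not pure[node.parent_node]):
            clusters.append(below[node])
    return clusters


def monophyly_status(
    tree: dendropy.Tree,
    members: set[str],
    rank: str = "",
    name: str = "",
    lineage_table: LineageTable | None = None,
    rooted: bool = True,
    prefix: tuple[str, ...] = (),
) -> TaxonStatus:
    """Classify a taxon's members as monophyletic / convergent / singleton.

    With ``rooted`` (default) clusters are the maximal clades of the rooted
    tree that contain only members.  With ``rooted=False`` the tree is
    treated as unrooted: it is provisionally rooted on the pendant edge of
    the smallest non-member leaf, which makes the verdict a statement about
    bipartitions only (for outgroup-free use).
    """
    members = set(members)
    if not members:
        raise ValueError("members must be nonempty")
    leaves = leaf_labels(tree)
    missing = members - leaves
    if missing:
        raise KeyError(f"member ids not among tree leaves: {sorted(missing)}")
    if not rooted:
        rest = leaves - members
        if rest:
            tree = root_with_outgroup(tree, {min(rest)})
        # members == all leaves: trivially one clade under any rooting
    clusters = sorted((len(c) for c in _pure_clades(tree, members)), reverse=True)
    if len(members) == 1:
        status = "singleton"
    elif len(clusters) == 1:
        status = "monophyletic"
    else:
        status = "convergent"
    if lineage_table is not None:
        n = sum(1 for g in members if lineage_table.get(g).complete)
    else:
        n = len(members)
    return TaxonStatus(
        rank=rank,
        name=name,
        n_complete=n,
        n_incomplete=len(members) - n,
        status=status,
        clusters=clusters,
        prefix=prefix,
    )


def _deepest_shared_rank(lineages, max_idx: int) -> int | None:
    """Deepest rank index <= max_idx at which all lineages share one named taxon."""
    for i in range(max_idx, -1, -1):
        prefixes = {lin.prefix(RANKS[i]) for lin in lineages}
        if len(prefixes) == 1 and next(iter(prefixes))[-1] != UNCLASSIFIED:
            return i
    return None


def collapse(
    tree: dendropy.Tree, lt: LineageTable, max_rank: str = "P"
) -> CollapsedNode:
    """Maximally collapse a rooted tree by shared taxa down to ``max_rank``.

    A node is replaced by a single labelled :class:`CollapsedNode` when all
    of its descendant genomes share one named taxon at some rank i <=
    ``max_rank`` and no member still carries a named rank deeper than i (up
    to ``max_rank``) that could refine the view.  The label uses the
    deepest such shared rank, so e.g. a clade that is all one phylum reads
    ``<P>Name{n + m}`` rather than its domain.  Sharing only
    ``Unclassified`` never licenses a collapse.  Every genome appears in
    exactly one collapsed leaf.
    """
    if max_rank not in RANKS:
        raise ValueError(f"unknown rank tag {max_rank!r}")
    max_idx = RANKS.index(max_rank)

    def build(node: dendropy.Node) -> CollapsedNode:
        gids = sorted(lf.taxon.label for lf in node.leaf_iter())
        lineages = [lt.get(g) for g in gids]
        i_star = _deepest_shared_rank(lineages, max_idx)
        if i_star is not None:
            refinable = any(
                lin.names[RANKS[j]] != UNCLASSIFIED
                for lin in lineages
                for j in range(i_star + 1, max_idx + 1)
            )
            if not refinable:
                name = lineages[0].names[RANKS[i_star]]
                n = sum(1 for lin in lineages if lin.complete)
                m = len(lineages) - n
                return CollapsedNode(
                    label=f"<{RANKS[i_star]}>{name}{format_nm(n, m)}",
                    member_ids=frozenset(gids),
                    rank=RANKS[i_star],
                    name=name,
                )
        if node.is_leaf():
            return CollapsedNode(label=gids[0], member_ids=frozenset(gids))
        return CollapsedNode(
            label="",
            member_ids=frozenset(gids),
            children=[build(c) for c in node.child_nodes()],
        )

    return build(tree.seed_node)


def full_report(
    tree: dendropy.Tree, lt: LineageTable, rooted: bool = True
) -> list[TaxonStatus]:
    """Monophyly verdicts for every named taxon at every rank Domain..Species.

    The lineage table is restricted to the tree's leaves (e.g. a hidden
    outgroup drops out of the accounting).  Entries are sorted by rank,
    then by descending member count, then by name.
    """
    leaves = leaf_labels(tree)
    table = lt.restricted_to(sorted(leaves))
    report: list[TaxonStatus] = []
    for rank in REPORT_RANKS:
        rank_entries: list[TaxonStatus] = []
        for prefix, (comp, incomp) in taxon_members(table, rank).items():
            if prefix[-1] == UNCLASSIFIED:
                continue
            members = comp | incomp
            rank_entries.append(
                monophyly_status(
                    tree,
                    members,
                    rank=rank,
                    name=prefix[-1],
                    lineage_table=table,
                    rooted=rooted,
                    prefix=prefix,
                )
            )
        rank_entries.sort(key=lambda s: (-s.n_members, s.name, s.prefix))
        report.extend(rank_entries)
    return report


def report_summary(report: list[TaxonStatus]) -> pd.DataFrame:
    """Per-rank counts of monophyletic / convergent / singleton taxa."""
    rows = []
    for rank in REPORT_RANKS:
        entries = [s for s in report if s.rank == rank]
        rows.append(
            {
                "rank": rank,
                "taxa": len(entries),
                "monophyletic": sum(1 for s in entries if s.status == "monophyletic"),
                "convergent": sum(1 for s in entries if s.status == "convergent"),
                "singleton": sum(1 for s in entries if s.status == "singleton"),
            }
        )
    return pd.DataFrame(rows)


def report_to_frame(report: list[TaxonStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": s.rank,
                "name": s.name,
                "n": s.n_complete,
                "m": s.n_incomplete,
                "status": s.status,
                "clusters": ",".join(map(str, s.clusters)),
                "rendered": s.render(),
            }
            for s in report
        ]
    )


def write_report_tsv(report: list[TaxonStatus], path: str | Path) -> None:
    report_to_frame(report).to_csv(path, sep="\t", index=False)


def write_report_json(report: list[TaxonStatus], path: str | Path) -> None:
    payload = [
        {
            "rank": s.rank,
            "name": s.name,
            "prefix": list(s.prefix),
            "n_complete": s.n_complete,
            "n_incomplete": s.n_incomplete,
            "status": s.status,
            "clusters": s.clusters,
            "rendered": s.render(),
        }
        for s in report
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Collapsed-tree renderings

def _quote_label(label: str) -> str:
    if any(ch in label for ch in " (){},;:'\"<>[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def collapsed_newick(node: CollapsedNode) -> str:
    """Newick rendering of a collapsed tree (labels quoted as needed)."""

    def render(nd: CollapsedNode) -> str:
        if nd.is_leaf:
            return _quote_label(nd.label)
        inner = ",".join(render(c) for c in nd.children)
        return f"({inner}){_quote_label(nd.label) if nd.label else ''}"

    return render(node) + ";"


def collapsed_text(node: CollapsedNode) -> str:
    """Indented-text rendering of a collapsed tree, one node per line."""
    lines: list[str] = []

    def walk(nd: CollapsedNode, depth: int) -> None:
        label = nd.label if nd.label else "+"
        lines.append("  " * depth + label)
        for c in nd.children:
            walk(c, depth + 1)

    walk(node, 0)
    return "\n".join(lines) + "\n"
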