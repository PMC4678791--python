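"""Synthetic proteome sets with a known true phylogeny and taxonomy.

The simulator evolves a root proteome along a guide tree by independent
per-site amino-acid substitution (no indels — composition vectors are
window-based, and indels would only shift windows).  Each edge carries a
substitution probability; a substituted site takes one of the 19 other
residues uniformly.  Leaf proteomes come with a lineage table whose named
taxa at every rank are exactly clades of the guide tree, so ground-truth
monophyly is known by construction.

The default root proteome (200 proteins of 300 residues) is large enough
for informative K = 5–6 vectors yet keeps a full pipeline run at
seconds scale.  Residues are drawn from an average globular-protein
composition rather than uniformly, so background subtraction has a
realistic non-flat base frequency to work against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .cvcore import CANONICAL_ALPHABET
from .io_lineage import RANKS, Lineage, LineageTable, Proteome, write_lineage_table
from .njtree import write_newick

#: Average amino-acid composition of globular proteins (order of
#: CANONICAL_ALPHABET = ACDEFGHIKLMNPQRSTVWY), normalised at use.
DEFAULT_AA_FREQS: tuple[float, ...] = (
    0.0825, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0596, 0.0580,
    0.0966, 0.0242, 0.0406, 0.0470, 0.0393, 0.0553, 0.0657, 0.0534, 0.0687,
    0.0110, 0.0292,
)


@dataclass
class SimSpec:
    """Specification of one simulated proteome set.

    ``guide_tree`` is a rooted Newick string whose edge lengths are
    per-edge substitution probabilities (each in [0, 0.75]).
    """

    guide_tree: str
    n_proteins: int = 200
    protein_length: int = 300
    aa_freqs: tuple[float, ...] = DEFAULT_AA_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.protein_length < 1:
            raise ValueError("n_proteins and protein_length must be positive")
        if len(self.aa_freqs) != 20 or any(f < 0 for f in self.aa_freqs):
            raise ValueError("aa_freqs must be 20 nonnegative frequencies")


def balanced_guide_tree(n_leaves: int = 8, p: float = 0.05) -> str:
    """Balanced binary guide tree (n_leaves a power of two), all edges at p."""
    if n_leaves < 2 or n_leaves & (n_leaves - 1):
        raise ValueError("n_leaves must be a power of two >= 2")
    labels = [f"g{i + 1:02d}" for i in range(n_leaves)]

    def build(block: list[str]) -> str:
        if len(block) == 1:
            return f"{block[0]}:{p}"
        h = len(block) // 2
        return f"({build(block[:h])},{build(block[h:])}):{p}"

    h = n_leaves // 2
    return f"({build(labels[:h])},{build(labels[h:])});"


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at probability p; new residue uniform over the
    19 alternatives (implemented as a nonzero cyclic offset)."""
    out = seq.copy()
    mask = rng.random(seq.shape) < p
    n_hit = int(mask.sum())
    if n_hit:
        offsets = rng.integers(1, 20, size=n_hit)
        out[mask] = (out[mask] + offsets) % 20
    return out


def _clade_lineages(tree: dendropy.Tree) -> LineageTable:
    """Lineage table whose taxon at rank index i is the leaf's depth-i
    ancestor clade (the leaf itself once i reaches or passes the leaf).

    Each clade is keyed by its smallest leaf label, which is unique among
    clades at one depth, so taxa at each rank are exactly clades of the
    guide tree.
    """
    entries: dict[str, Lineage] = {}
    min_leaf: dict[dendropy.Node, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            min_leaf[node] = node.taxon.label
        else:
            min_leaf[node] = min(min_leaf[c] for c in node.child_nodes())
    for leaf in tree.leaf_node_iter():
        path = [leaf]
        node = leaf
        while node.parent_node is not None:
            node = node.parent_node
            path.append(node)
        path.reverse()  # root .. leaf
        names: dict[str, str] = {}
        for i, rank in enumerate(RANKS):
            anchor = path[min(i, len(path) - 1)]
            names[rank] = f"tax{rank}_{min_leaf[anchor]}"
        names["T"] = leaf.taxon.label
        entries[leaf.taxon.label] = Lineage(names)
    return LineageTable(entries)


def simulate_proteomes(
    spec: SimSpec,
) -> tuple[dict[str, Proteome], dendropy.Tree, LineageTable]:
    """Simulate leaf proteomes along the guide tree.

    Returns ``(proteomes by genome_id, true rooted tree, lineage table)``.
    Fully deterministic under ``spec.seed``.
    """
    tree = dendropy.Tree.get(data=spec.guide_tree, schema="newick")
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and not 0.0 <= edge.length <= 0.75:
            raise ValueError(f"substitution probability {edge.length} outside [0, 0.75]")
    rng = np.random.default_rng(spec.seed)
    freqs = np.asarray(spec.aa_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    shape = (spec.n_proteins, spec.protein_length)
    root_seq = rng.choice(20, size=shape, p=freqs).astype(np.int8)

    alphabet = np.frombuffer(CANONICAL_ALPHABET.encode(), dtype=np.uint8)
    proteomes: dict[str, Proteome] = {}
    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        p = node.edge.length if node.edge.length is not None else 0.0
        seqs[node] = _mutate(seqs[node.parent_node], p, rng)
        if node.is_leaf():
            arr = alphabet[seqs[node]]
            proteins = [row.tobytes().decode() for row in arr]
            proteomes[node.taxon.label] = Proteome(node.taxon.label, proteins)
    lt = _clade_lineages(tree)
    return proteomes, tree, lt


def perturb_lineage(
    lt: LineageTable, n_moves: int, seed: int
) -> tuple[LineageTable, list[tuple[str, str, str, str]]]:
    """Reassign ``n_moves`` genomes to wrong taxa at a random rank.

    Each move copies another genome's lineage prefix down to the chosen
    rank (keeping deeper ranks), and is returned as
    ``(genome_id, rank, old_name, new_name)`` so tests know which taxa must
    become convergent.  Genome count and ids are conserved.
    """
    gids = sorted(lt.entries)
    if n_moves > len(gids):
        raise ValueError(f"n_moves {n_moves} exceeds {len(gids)} genomes")
    rng = np.random.default_rng(seed)
    victims = [gids[i] for i in rng.permutation(len(gids))[:n_moves]]
    entries = {g: lin for g, lin in lt.entries.items()}
    moves: list[tuple[str, str, str, str]] = []
    for gid in victims:
        # ranks where another genome offers a different taxon to move into
        options: list[tuple[str, str]] = []
        for rank in RANKS[:-1]:
            own = entries[gid].prefix(rank)
            donors = [g for g in gids if g != gid and entries[g].prefix(rank) != own]
            if donors:
                options.append((rank, donors[int(rng.integers(len(donors)))]))
        if not options:
            continue
        rank, donor = options[int(rng.integers(len(options)))]
        i = RANKS.index(rank)
        names = dict(entries[gid].names)
        old_name = names[rank]
        for r in RANKS[: i + 1]:
            names[r] = entries[donor].names[r]
        entries[gid] = Lineage(names)
        moves.append((gid, rank, old_name, names[rank]))
    return LineageTable(entries), moves


def write_project(
    out_dir: str | Path,
    proteomes: dict[str, Proteome],
    lt: LineageTable,
    tree: dendropy.Tree | None = None,
) -> Path:
    """Write a runnable project directory: per-genome .faa files,
    Lineage.txt, and (optionally) the true tree."""
    out_dir = Path(out_dir)
    faa_dir = out_dir / "inputs"
    faa_dir.mkdir(parents=True, exist_ok=True)
    for gid in sorted(proteomes):
        p = proteomes[gid]
        lines = []
        for i, prot in enumerate(p.proteins):
            lines.append(f">{gid}_p{i + 1:04d}")
            lines.append(prot)
        (faa_dir / f"{gid}.faa").write_text("\n".join(lines) + "\n")
    write_lineage_table(lt, out_dir / "Lineage.txt")
    if tree is not None:
        (out_dir / "true_tree.nwk").write_text(write_newick(tree) + "\n")
    return out_dir
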