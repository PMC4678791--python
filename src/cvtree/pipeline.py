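"""End-to-end orchestration over a range of K values.

One run takes a set of protein FASTA files plus a lineage file and, for
every K in the configured range (K = 3–8 by default, a single run), builds
composition vectors, the dissimilarity matrix, the NJ tree (outgroup-rooted
if requested) and the taxonomy-congruence report.  Watching how the
branching order changes with K is part of the method — the cross-K summary
records at which K each taxon is monophyletic, and the pairwise
Robinson–Foulds table quantifies topology drift between K values.

Project layout under ``out_dir``::

    cv_cache/                 cached composition vectors (content-hash keyed)
    k{K}/distance.phylip      square PHYLIP dissimilarity matrix
    k{K}/tree.nwk             NJ tree (topology-only unless with_lengths)
    k{K}/tree_collapsed.nwk   collapsed tree, Newick labels
    k{K}/tree_collapsed.txt   collapsed tree, indented text
    k{K}/taxonomy_report.tsv  per-taxon monophyly report (+ .json)
    summary.tsv               per taxon: the K values where it is monophyletic
    rf_table.tsv              pairwise RF distances between the K trees

Everything is deterministic given the configuration: fixed iteration
orders, compensated summation, and lexicographic NJ tie-breaks mean two
runs of the same project produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import cvcore, distance, io_lineage, njtree, taxcompare
from .io_lineage import LineageTable

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = (3, 4, 5, 6, 7, 8)


@dataclass
class ProjectConfig:
    """Configuration of one pipeline run (flag-for-flag with the CLI)."""

    genome_paths: list[Path]
    lineage_path: Path | None = None
    modification_path: Path | None = None
    k_values: list[int] = field(default_factory=lambda: list(DEFAULT_K_VALUES))
    outgroup: set[str] = field(default_factory=set)
    out_dir: Path | None = None
    use_modified_lineage: bool = False
    collapse_rank: str = "P"
    with_lengths: bool = False
    hide_outgroup: bool = False
    cache_cvs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.genome_paths = [Path(p) for p in self.genome_paths]
        self.k_values = sorted(set(int(k) for k in self.k_values))
        if not self.k_values or self.k_values[0] < 3:
            raise ValueError(f"k values must all be >= 3, got {self.k_values}")
        if self.collapse_rank not in io_lineage.RANKS:
            raise ValueError(f"unknown collapse rank {self.collapse_rank!r}")


@dataclass
class KResult:
    """Outputs of one K value."""

    k: int
    matrix: distance.DistanceMatrix
    tree: dendropy.Tree          # unrooted NJ tree
    display_tree: dendropy.Tree  # outgroup-rooted if an outgroup was given
    report: list[taxcompare.TaxonStatus]
    collapsed: taxcompare.CollapsedNode


@dataclass
class ProjectResult:
    config: ProjectConfig
    lineage: LineageTable
    per_k: dict[int, KResult]
    summary: pd.DataFrame
    rf_table: pd.DataFrame | None
    errors: dict[int, str]


def parse_k_spec(spec: str) -> list[int]:
    """Parse a K-range spec like ``3-8`` or ``5,6`` into a sorted list."""
    out: set[int] = set()
    for part in spec.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        elif part:
            out.add(int(part))
    return sorted(out)


def load_config(path: str | Path) -> ProjectConfig:
    """Read a ``key = value`` config file equivalent to the CLI flags.

    Keys: genomes (whitespace-separated paths or globs), lineage, mods, k
    (range spec), outgroup (comma-separated ids), out, collapse_rank,
    with_lengths, use_modified_lineage, hide_outgroup, cache_cvs, seed.
    """
    kv: dict[str, str] = {}
    base = Path(path).parent
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    genome_paths: list[Path] = []
    for token in kv.get("genomes", "").split():
        matches = sorted(base.glob(token)) if any(c in token for c in "*?[") else [base / token]
        genome_paths.extend(matches)
    truthy = {"1", "true", "yes", "on"}
    return ProjectConfig(
        genome_paths=genome_paths,
        lineage_path=base / kv["lineage"] if kv.get("lineage") else None,
        modification_path=base / kv["mods"] if kv.get("mods") else None,
        k_values=parse_k_spec(kv["k"]) if kv.get("k") else list(DEFAULT_K_VALUES),
        outgroup={s.strip() for s in kv.get("outgroup", "").split(",") if s.strip()},
        out_dir=base / kv["out"] if kv.get("out") else None,
        use_modified_lineage=kv.get("use_modified_lineage", "").lower() in truthy,
        collapse_rank=kv.get("collapse_rank", "P"),
        with_lengths=kv.get("with_lengths", "").lower() in truthy,
        hide_outgroup=kv.get("hide_outgroup", "").lower() in truthy,
        cache_cvs=kv.get("cache_cvs", "true").lower() in truthy,
        seed=int(kv.get("seed", "0")),
    )


def _load_inputs(cfg: ProjectConfig) -> tuple[list[io_lineage.Proteome], LineageTable]:
    proteomes = [io_lineage.read_proteome(p) for p in cfg.genome_paths]
    ids = [p.genome_id for p in proteomes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate genome ids among inputs: {ids}")
    if cfg.lineage_path is not None:
        lt = io_lineage.read_lineage_table(cfg.lineage_path)
    else:
        lt = LineageTable()
    lt = lt.restricted_to(ids)
    if cfg.use_modified_lineage and cfg.modification_path is not None:
        mods = io_lineage.read_lineage_table(cfg.modification_path)
        lt = io_lineage.apply_modifications(lt, mods)
        logger.info("applied lineage modifications for %d genome(s)", len(mods))
    return proteomes, lt


def compare_k_topologies(trees: dict[int, dendropy.Tree]) -> pd.DataFrame:
    """Pairwise Robinson–Foulds distances between the per-K trees."""
    if len(trees) < 2:
        raise ValueError("need >= 2 trees to compare")
    ks = sorted(trees)
    leaf_sets = {k: njtree.leaf_labels(trees[k]) for k in ks}
    first = leaf_sets[ks[0]]
    for k in ks[1:]:
        if leaf_sets[k] != first:
            raise ValueError(f"leaf sets differ between k={ks[0]} and k={k}")
    table = pd.DataFrame(0, index=ks, columns=ks)
    for i, ka in enumerate(ks):
        for kb in ks[i + 1 :]:
            rf = njtree.rf_distance(trees[ka], trees[kb])
            table.loc[ka, kb] = table.loc[kb, ka] = rf
    return table


def _run_one_k(
    cfg: ProjectConfig,
    k: int,
    cvs: list[cvcore.CompositionVector],
    lt: LineageTable,
    k_dir: Path | None,
) -> KResult:
    matrix = distance.build_matrix(cvs)
    tree = njtree.neighbor_joining(matrix)
    if cfg.outgroup:
        display_tree = njtree.root_with_outgroup(
            tree, cfg.outgroup, hide_outgroup=cfg.hide_outgroup
        )
        rooted = True
    else:
        display_tree = tree
        rooted = False
    report = taxcompare.full_report(display_tree, lt, rooted=rooted)
    collapsed = taxcompare.collapse(display_tree, lt, max_rank=cfg.collapse_rank)
    if k_dir is not None:
        k_dir.mkdir(parents=True, exist_ok=True)
        distance.write_phylip(matrix, k_dir / "distance.phylip")
        (k_dir / "tree.nwk").write_text(
            njtree.write_newick(display_tree, with_lengths=cfg.with_lengths) + "\n"
        )
        (k_dir / "tree_collapsed.nwk").write_text(taxcompare.collapsed_newick(collapsed) + "\n")
        (k_dir / "tree_collapsed.txt").write_text(taxcompare.collapsed_text(collapsed))
        taxcompare.write_report_tsv(report, k_dir / "taxonomy_report.tsv")
        taxcompare.write_report_json(report, k_dir / "taxonomy_report.json")
    return KResult(k=k, matrix=matrix, tree=tree, display_tree=display_tree,
                   report=report, collapsed=collapsed)


def _cross_k_summary(per_k: dict[int, KResult]) -> pd.DataFrame:
    """Per taxon, the K values at which it is monophyletic (or a trivial
    singleton) — the "monophyletic for at least one K" bookkeeping."""
    taxa: dict[tuple[str, tuple[str, ...]], dict] = {}
    for k in sorted(per_k):
        for s in per_k[k].report:
            key = (s.rank, s.prefix)
            row = taxa.setdefault(
                key,
                {"rank": s.rank, "name": s.name, "n": s.n_complete,
                 "m": s.n_incomplete, "mono_k": []},
            )
            if s.status in ("monophyletic", "singleton"):
                row["mono_k"].append(k)
    rank_order = {r: i for i, r in enumerate(io_lineage.RANKS)}
    rows = sorted(
        taxa.values(), key=lambda r: (rank_order[r["rank"]], -(r["n"] + r["m"]), r["name"])
    )
    for row in rows:
        row["monophyletic_at_k"] = ",".join(map(str, row.pop("mono_k")))
    return pd.DataFrame(rows)


def run_project(cfg: ProjectConfig) -> ProjectResult:
    """Run the full pipeline for every configured K.

    A failure at one K is recorded (with its context) and the remaining K
    values still run; completed outputs are retained on disk.
    """
    proteomes, lt = _load_inputs(cfg)
    if len(proteomes) < 3:
        raise ValueError(f"need >= 3 genomes, got {len(proteomes)}")
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    cache_dir = (out_dir / "cv_cache") if (out_dir is not None and cfg.cache_cvs) else None

    cvs_by_genome = {}
    for p in proteomes:
        logger.info("building CVs for %s (k=%s)", p.genome_id, cfg.k_values)
        cvs_by_genome[p.genome_id] = cvcore.build_cvs_cached(p, cfg.k_values, cache_dir)

    per_k: dict[int, KResult] = {}
    errors: dict[int, str] = {}
    for k in cfg.k_values:
        cvs = [cvs_by_genome[p.genome_id][k] for p in proteomes]
        k_dir = (out_dir / f"k{k}") if out_dir is not None else None
        try:
            per_k[k] = _run_one_k(cfg, k, cvs, lt, k_dir)
            logger.info("k=%d: tree and report done", k)
        except Exception as exc:  # error context, keep other K values going
            errors[k] = f"k={k}: {exc}"
            logger.error("k=%d failed: %s", k, exc)
    if not per_k:
        raise RuntimeError("all K values failed: " + "; ".join(errors.values()))

    summary = _cross_k_summary(per_k)
    rf_table = None
    if len(per_k) >= 2:
        rf_table = compare_k_topologies({k: r.tree for k, r in per_k.items()})
    if out_dir is not None:
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        if rf_table is not None:
            rf_table.to_csv(out_dir / "rf_table.tsv", sep="\t")
    return ProjectResult(config=cfg, lineage=lt, per_k=per_k, summary=summary,
                         rf_table=rf_table, errors=errors)
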