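"""Proteome input and the tagged nine-rank lineage dialect.

A proteome is one multi-FASTA file of annotated protein products per genome.
Lineage annotations use one line per genome::

    genome_id <D>Bacteria<K>Unclassified<P>Firmicutes...<T>strain-name

with the nine rank tags D, K, P, C, O, F, G, S, T standing for Domain,
Kingdom, Phylum, Class, Order, Family, Genus, Species and sTrain.  A missing
rank is written ``Unclassified``; a lineage containing one or more
``Unclassified`` entries is *incomplete*.  Both the ASCII ``<D>`` and the
typographic ``〈D〉`` tag spelling are accepted on input; ASCII is emitted.
Taxon names may contain spaces and punctuation — the tag, not whitespace,
delimits fields.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import EmptyProteomeError, LineageFormatError

logger = logging.getLogger(__name__)

#: Canonical rank tags, shallowest (Domain) to deepest (sTrain).
RANKS: tuple[str, ...] = ("D", "K", "P", "C", "O", "F", "G", "S", "T")

#: Full rank names keyed by tag.
RANK_NAMES: dict[str, str] = {
    "D": "Domain",
    "K": "Kingdom",
    "P": "Phylum",
    "C": "Class",
    "O": "Order",
    "F": "Family",
    "G": "Genus",
    "S": "Species",
    "T": "sTrain",
}

UNCLASSIFIED = "Unclassified"

_TAG_RE = re.compile(r"[<〈]([A-Za-z])[>〉]")


@dataclass
class Proteome:
    """A genome identifier plus its protein sequences.

    ``genome_id`` is the unique project key and becomes the tree leaf label.
    Sequences are upper-case amino-acid strings; non-standard symbols are
    retained here and handled at counting time.
    """

    genome_id: str
    proteins: list[str]

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be nonempty")
        if any(not p for p in self.proteins):
            raise ValueError("proteins must be nonempty strings")

    @property
    def n_residues(self) -> int:
        return sum(len(p) for p in self.proteins)


@dataclass(frozen=True)
class Lineage:
    """Nine-rank taxonomic annotation for one genome.

    ``names`` maps every rank tag in :data:`RANKS` to a taxon name or the
    ``Unclassified`` sentinel.  ``complete`` is true iff no rank is
    Unclassified.
    """

    names: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.names) != set(RANKS):
            missing = set(RANKS) - set(self.names)
            extra = set(self.names) - set(RANKS)
            raise ValueError(f"lineage ranks malformed (missing={missing}, extra={extra})")

    @property
    def complete(self) -> bool:
        return all(v != UNCLASSIFIED for v in self.names.values())

    def name_at(self, rank: str) -> str:
        return self.names[rank]

    def prefix(self, rank: str) -> tuple[str, ...]:
        """Names from Domain down to ``rank`` inclusive (homonym-safe key)."""
        i = RANKS.index(rank)
        return tuple(self.names[r] for r in RANKS[: i + 1])

    @staticmethod
    def unclassified() -> "Lineage":
        return Lineage({r: UNCLASSIFIED for r in RANKS})


@dataclass
class LineageTable:
    """Mapping genome_id -> :class:`Lineage` for one project."""

    entries: dict[str, Lineage] = field(default_factory=dict)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, genome_id: str) -> Lineage:
        """Lineage for a genome; all-Unclassified if the genome is unknown."""
        return self.entries.get(genome_id, Lineage.unclassified())

    def restricted_to(self, genome_ids) -> "LineageTable":
        """Table covering exactly ``genome_ids``; absentees get Unclassified."""
        return LineageTable({g: self.get(g) for g in genome_ids})


def read_proteome(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read one protein multi-FASTA file into a :class:`Proteome`.

    The genome identifier defaults to the file stem.  Sequences are
    upper-cased; records with empty sequences are dropped with a warning.

    Raises
    ------
    EmptyProteomeError
        If no record with a nonempty sequence is found.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    proteins: list[str] = []
    n_empty = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().strip("*")  # trailing stop codons are common
        if not seq:
            n_empty += 1
            continue
        proteins.append(seq)
    if n_empty:
        logger.warning("%s: dropped %d empty record(s)", path, n_empty)
    if not proteins:
        raise EmptyProteomeError(f"{path}: no nonempty protein records")
    return Proteome(genome_id=gid, proteins=proteins)


def parse_lineage_line(line: str) -> tuple[str, Lineage]:
    """Parse one ``genome_id <D>...<T>...`` record.

    Tags may appear in any order; absent ranks become ``Unclassified``.

    Raises
    ------
    LineageFormatError
        On a duplicated rank tag, an unknown tag letter, or a missing
        genome identifier.
    """
    matches = list(_TAG_RE.finditer(line))
    gid = line[: matches[0].start()].strip() if matches else line.strip()
    if not gid:
        raise LineageFormatError(f"missing genome identifier in line: {line!r}")
    names = {r: UNCLASSIFIED for r in RANKS}
    seen: set[str] = set()
    for i, m in enumerate(matches):
        tag = m.group(1).upper()
        if tag not in RANKS:
            raise LineageFormatError(f"unknown rank tag <{m.group(1)}> in line for {gid!r}")
        if tag in seen:
            raise LineageFormatError(f"duplicated rank tag <{tag}> in line for {gid!r}")
        seen.add(tag)
        end = matches[i + 1].start() if i + 1 < len(matches) else len(line)
        name = line[m.end() : end].strip()
        names[tag] = name if name else UNCLASSIFIED
    return gid, Lineage(names)


def serialize_lineage_line(genome_id: str, lineage: Lineage) -> str:
    """Render one record in canonical D→T order with ASCII tags."""
    tags = "".join(f"<{r}>{lineage.names[r]}" for r in RANKS)
    return f"{genome_id} {tags}"


def read_lineage_table(path: str | Path) -> LineageTable:
    """Read a Lineage.txt-dialect file (one record per nonblank line)."""
    entries: dict[str, Lineage] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        gid, lin = parse_lineage_line(line)
        entries[gid] = lin
    return LineageTable(entries)


def write_lineage_table(table: LineageTable, path: str | Path) -> None:
    lines = [serialize_lineage_line(g, lin) for g, lin in table.entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def apply_modifications(base: LineageTable, mods: LineageTable) -> LineageTable:
    """Overlay trial lineage modifications on a base table (pure function).

    For every genome in ``mods``, ranks explicitly named there (i.e. not
    ``Unclassified``) overwrite the base ranks; unmentioned ranks are kept.
    The genome set is conserved: the result has exactly the base's ids.

    Raises
    ------
    KeyError
        If a modification names a genome absent from the base table.
    """
    unknown = sorted(set(mods.entries) - set(base.entries))
    if unknown:
        raise KeyError(f"modifications reference unknown genome(s): {unknown}")
    out: dict[str, Lineage] = {}
    for gid, lin in base.entries.items():
        if gid in mods.entries:
            patch = mods.entries[gid].names
            merged = {
                r: (patch[r] if patch[r] != UNCLASSIFIED else lin.names[r]) for r in RANKS
            }
            out[gid] = Lineage(merged)
        else:
            out[gid] = lin
    return LineageTable(out)
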