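"""Pairwise CV dissimilarities and the distance matrix.

The dissimilarity between two genomes is derived from the cosine
correlation of their composition vectors,

    C(u, v) = sum_w u(w) v(w) / (||u|| ||v||),     D(u, v) = (1 - C) / 2,

so D ranges over [0, 1]: identical vectors give 0, uncorrelated ones 0.5,
anti-parallel ones 1.  Dot products are accumulated with compensated
summation (``math.fsum``); for a fixed input order matrix entries are
reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cvcore import CompositionVector
from .errors import DataError, DegenerateGenomeError


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise dissimilarities over genome ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DataError(f"matrix shape {self.d.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise DataError("duplicate genome ids in distance matrix")
        self.validate()

    def validate(self) -> None:
        if np.isnan(self.d).any():
            raise DataError("distance matrix contains NaN")
        if not np.array_equal(self.d, self.d.T):
            raise DataError("distance matrix is not symmetric")
        if np.diag(self.d).any():
            raise DataError("distance matrix has nonzero diagonal")
        if self.d.min() < -1e-12 or self.d.max() > 1.0 + 1e-12:
            raise DataError("distance entries outside [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def cosine(u: CompositionVector, v: CompositionVector) -> float:
    """Cosine correlation C of two CVs, clamped to [-1, 1].

    Summation runs over the sparse intersection of the two peptide sets.
    """
    if u.k != v.k:
        raise ValueError(f"mismatched k: {u.k} vs {v.k}")
    if u.norm == 0.0 or v.norm == 0.0:
        bad = u.genome_id if u.norm == 0.0 else v.genome_id
        raise DegenerateGenomeError(f"zero-norm composition vector for genome {bad!r}")
    small, large = (u.scores, v.scores) if len(u.scores) <= len(v.scores) else (v.scores, u.scores)
    dot = math.fsum(a * large[w] for w, a in small.items() if w in large)
    c = dot / (u.norm * v.norm)
    return max(-1.0, min(1.0, c))


def dissimilarity(u: CompositionVector, v: CompositionVector) -> float:
    """D = (1 - C) / 2 in [0, 1]; 0 iff the vectors are parallel."""
    return (1.0 - cosine(u, v)) / 2.0


def build_matrix(cvs: list[CompositionVector]) -> DistanceMatrix:
    """Full symmetric dissimilarity matrix over >= 3 composition vectors.

    Each pair is computed once (upper triangle in id order) and mirrored, so
    symmetry holds exactly as stored.
    """
    if len(cvs) < 3:
        raise ValueError(f"need >= 3 composition vectors, got {len(cvs)}")
    ks = {cv.k for cv in cvs}
    if len(ks) != 1:
        raise ValueError(f"mixed k values in one matrix: {sorted(ks)}")
    ids = [cv.genome_id for cv in cvs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids among composition vectors")
    n = len(cvs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = dissimilarity(cvs[i], cvs[j])
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=ids, d=d)


def write_phylip(m: DistanceMatrix, path: str | Path) -> None:
    """Write the square PHYLIP distance-matrix dialect (relaxed names)."""
    lines = [f"{len(m.ids)}"]
    for gid, row in zip(m.ids, m.d):
        vals = " ".join(format(x, ".17g") for x in row)
        lines.append(f"{gid}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read the square PHYLIP dialect written by :func:`write_phylip`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    if len(lines) != n + 1:
        raise DataError(f"expected {n} matrix rows, found {len(lines) - 1}")
    ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        parts = ln.split()
        ids.append(parts[0])
        row = [float(x) for x in parts[1:]]
        if len(row) != n:
            raise DataError(f"row for {parts[0]!r} has {len(row)} entries, expected {n}")
        rows.append(row)
    return DistanceMatrix(ids=ids, d=np.array(rows))
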