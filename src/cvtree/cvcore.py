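"""K-peptide counting and background-subtracted composition vectors.

The composition-vector (CV) method summarises a whole proteome by the
frequencies of its length-K amino-acid windows (K-peptides), with the
neutral-mutation background removed.  For a K-peptide ``w = a1..aK`` the
expected background frequency under a (K-2)-th order Markov model is

    q(w) = f(a1..a(K-1)) * f(a2..aK) / f(a2..a(K-1))

where each ``f`` is a window count divided by its own total window count at
that length.  The CV component for an observed peptide is the relative
deviation

    a(w) = (f(w) - q(w)) / q(w)      (a(w) = 0 when q(w) = 0)

so only selection-shaped departures from the random background contribute.

Conventions fixed here:

* frequencies, not raw counts, enter the Markov ratio — the forms differ by
  a near-unity factor for large proteomes and the frequency form is
  self-normalising;
* windows never cross protein boundaries;
* any window containing a non-canonical residue (``X B Z J U O * -`` and
  friends) is skipped; only those windows are lost, the rest of the protein
  still counts;
* peptides never observed at length K are absent from the sparse vector
  even when q > 0.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DegenerateGenomeError
from .io_lineage import Proteome

#: The 20 standard amino acids; everything else voids its windows.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_NON_CANONICAL_RE = re.compile(f"[^{CANONICAL_ALPHABET}]+")


@dataclass
class KmerCounts:
    """Sparse window counts for one proteome at one peptide length."""

    k: int
    counts: dict[str, int]
    total_windows: int

    def frequency(self, peptide: str) -> float:
        """Observed frequency f(peptide); 0 when unobserved."""
        if self.total_windows == 0:
            return 0.0
        return self.counts.get(peptide, 0) / self.total_windows


@dataclass
class CompositionVector:
    """Background-subtracted sparse composition vector for one genome."""

    genome_id: str
    k: int
    scores: dict[str, float]
    norm: float = field(default=0.0)

    @staticmethod
    def from_scores(genome_id: str, k: int, scores: dict[str, float]) -> "CompositionVector":
        norm = math.sqrt(math.fsum(a * a for a in scores.values()))
        return CompositionVector(genome_id, k, scores, norm)


def _canonical_segments(protein: str) -> list[str]:
    """Maximal runs of canonical residues; windows are confined to a run."""
    return [s for s in _NON_CANONICAL_RE.split(protein) if s]


def count_kmers(proteome: Proteome, k: int) -> KmerCounts:
    """Count every length-k window of every protein.

    Windows never span protein boundaries and windows containing any
    non-canonical symbol are skipped; proteins shorter than k contribute
    nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: dict[str, int] = {}
    total = 0
    for protein in proteome.proteins:
        for seg in _canonical_segments(protein):
            n = len(seg) - k + 1
            if n <= 0:
                continue
            total += n
            for i in range(n):
                w = seg[i : i + k]
                counts[w] = counts.get(w, 0) + 1
    return KmerCounts(k=k, counts=counts, total_windows=total)


def count_kmer_tables(proteome: Proteome, lengths: list[int]) -> dict[int, KmerCounts]:
    """Count several window lengths in one traversal of the proteome."""
    for k in lengths:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
    lengths = sorted(set(lengths))
    tables = {k: ({}, 0) for k in lengths}
    for protein in proteome.proteins:
        for seg in _canonical_segments(protein):
            for k in lengths:
                n = len(seg) - k + 1
                if n <= 0:
                    continue
                counts, total = tables[k]
                for i in range(n):
                    w = seg[i : i + k]
                    counts[w] = counts.get(w, 0) + 1
                tables[k] = (counts, total + n)
    return {k: KmerCounts(k=k, counts=c, total_windows=t) for k, (c, t) in tables.items()}


def markov_expected(c_k1: KmerCounts, c_k2: KmerCounts, peptide: str) -> float:
    """Background frequency q(peptide) from the (K-2)-th order Markov model.

    ``c_k1`` and ``c_k2`` are the (K-1)- and (K-2)-length count tables of the
    same proteome.  Returns 0 when any factor count is zero.
    """
    k = len(peptide)
    if k < 3:
        raise ValueError(f"Markov prediction needs peptide length >= 3, got {k}")
    if c_k1.k != k - 1 or c_k2.k != k - 2:
        raise ValueError(
            f"count-table lengths ({c_k1.k}, {c_k2.k}) do not match peptide length {k}"
        )
    if c_k1.total_windows == 0 or c_k2.total_windows == 0:
        return 0.0
    n_pre = c_k1.counts.get(peptide[:-1], 0)
    n_suf = c_k1.counts.get(peptide[1:], 0)
    n_mid = c_k2.counts.get(peptide[1:-1], 0)
    if n_pre == 0 or n_suf == 0 or n_mid == 0:
        return 0.0
    f_pre = n_pre / c_k1.total_windows
    f_suf = n_suf / c_k1.total_windows
    f_mid = n_mid / c_k2.total_windows
    return f_pre * f_suf / f_mid


def build_cv_from_tables(
    genome_id: str, k: int, tables: dict[int, KmerCounts]
) -> CompositionVector:
    """Assemble the composition vector at length k from precomputed tables."""
    if k < 3:
        raise ValueError(f"composition vectors need k >= 3, got {k}")
    for kk in (k, k - 1, k - 2):
        if kk not in tables:
            raise ValueError(f"missing count table for length {kk}")
        if tables[kk].total_windows == 0:
            raise DegenerateGenomeError(
                f"genome {genome_id!r}: no countable windows at length {kk}"
            )
    ck, ck1, ck2 = tables[k], tables[k - 1], tables[k - 2]
    total = ck.total_windows
    scores: dict[str, float] = {}
    for w, c in ck.counts.items():
        q = markov_expected(ck1, ck2, w)
        scores[w] = (c / total - q) / q if q > 0.0 else 0.0
    return CompositionVector.from_scores(genome_id, k, scores)


def build_cv(proteome: Proteome, k: int) -> CompositionVector:
    """Count windows and build the background-subtracted CV at length k."""
    if k < 3:
        raise ValueError(f"composition vectors need k >= 3, got {k}")
    tables = count_kmer_tables(proteome, [k - 2, k - 1, k])
    return build_cv_from_tables(proteome.genome_id, k, tables)


def build_cvs(proteome: Proteome, k_values: list[int]) -> dict[int, CompositionVector]:
    """CVs for several K in one counting pass (shared sub-length tables)."""
    ks = sorted(set(k_values))
    if any(k < 3 for k in ks):
        raise ValueError(f"composition vectors need k >= 3, got {ks}")
    lengths = sorted({kk for k in ks for kk in (k - 2, k - 1, k)})
    tables = count_kmer_tables(proteome, lengths)
    return {k: build_cv_from_tables(proteome.genome_id, k, tables) for k in ks}


# ---------------------------------------------------------------------------
# On-disk CV cache (plain JSON keyed by proteome content hash and k), so a
# re-run with a different K subset reuses earlier work.

def proteome_content_hash(proteome: Proteome) -> str:
    h = hashlib.sha256()
    for p in proteome.proteins:
        h.update(p.encode())
        h.update(b"\n")
    return h.hexdigest()[:24]


def _cache_path(cache_dir: Path, content_hash: str, k: int) -> Path:
    return Path(cache_dir) / f"cv_{content_hash}_k{k}.json"


def save_cv(cv: CompositionVector, cache_dir: str | Path, content_hash: str) -> Path:
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = _cache_path(cache_dir, content_hash, cv.k)
    payload = {"genome_id": cv.genome_id, "k": cv.k, "scores": cv.scores}
    path.write_text(json.dumps(payload))
    return path

def load_cv(cache_dir: str | Path, content_hash: str, k: int) -> CompositionVector | None:
    path = _cache_path(Path(cache_dir), content_hash, k)
    if not path.exists():
        return None
    payload = json.loads(path.read_text())
    return CompositionVector.from_scores(payload["genome_id"], payload["k"], payload["scores"])


def build_cvs_cached(
    proteome: Proteome, k_values: list[int], cache_dir: str | Path | None
) -> dict[int, CompositionVector]:
    """Like :func:`build_cvs`, consulting/filling an on-disk cache if given."""
    if cache_dir is None:
        return build_cvs(proteome, k_values)
    chash = proteome_content_hash(proteome)
    out: dict[int, CompositionVector] = {}
    missing: list[int] = []
    for k in sorted(set(k_values)):
        cached = load_cv(cache_dir, chash, k)
        if cached is not None:
            # genome_id follows the current project, not the cache writer
            out[k] = CompositionVector(proteome.genome_id, cached.k, cached.scores, cached.norm)
        else:
            missing.append(k)
    if missing:
        for k, cv in build_cvs(proteome, missing).items():
            save_cv(cv, cache_dir, chash)
            out[k] = cv
    return out
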