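import random

import numpy as np
import pytest

from cvtree import (
    DistanceMatrix,
    Proteome,
    SimSpec,
    balanced_guide_tree,
    simulate_proteomes,
)
from cvtree.cvcore import CANONICAL_ALPHABET


@pytest.fixture
def toy_proteome() -> Proteome:
    """The worked micro-example: one protein AAAC."""
    return Proteome("toy", ["AAAC"])


def random_proteome(rng: random.Random, max_proteins: int = 6, max_len: int = 40,
                    with_noncanonical: bool = True) -> Proteome:
    alphabet = CANONICAL_ALPHABET + ("XBZ*U" if with_noncanonical else "")
    n = rng.randint(1, max_proteins)
    proteins = [
        "".join(rng.choice(alphabet) for _ in range(rng.randint(1, max_len)))
        for _ in range(n)
    ]
    return Proteome(f"r{rng.randint(0, 10**6)}", proteins)


def matrix_from_dists(labels: list[str], dists: dict) -> DistanceMatrix:
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            d[i, j] = d[j, i] = dists[(a, b) if a < b else (b, a)]
    return DistanceMatrix(ids=list(labels), d=d)


@pytest.fixture(scope="session")
def small_sim():
    """A small but informative simulated project shared across tests."""
    spec = SimSpec(
        guide_tree=balanced_guide_tree(8, 0.05),
        n_proteins=40,
        protein_length=150,
        seed=7,
    )
    return simulate_proteomes(spec)
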