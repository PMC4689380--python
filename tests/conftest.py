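"""Shared fixtures: tiny hand-built instances and the session-scoped
simulation study reused by the recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from netquant.catalog import Gene, Transcript, TranscriptCatalog
from netquant.compat import CompatibilityMatrix, GeneCompat
from netquant.experiments import recovery_experiment
from netquant.network import TranscriptNetwork


@pytest.fixture
def two_gene_catalog() -> TranscriptCatalog:
    """Gene A (a1, a2) and gene B (b1, b2), all length 1000."""
    return TranscriptCatalog(
        [
            Gene("A", (Transcript("a1", 1000), Transcript("a2", 1000))),
            Gene("B", (Transcript("b1", 1000), Transcript("b2", 1000))),
        ]
    )


@pytest.fixture
def two_gene_toy(two_gene_catalog):
    """Gene A with unique reads 9:1; gene B fully ambiguous (10 reads);
    one edge a1-b1.  The classic instance where the prior breaks B's tie."""
    q = 1.0 / (1000 - 76 + 1)
    compat = CompatibilityMatrix(
        two_gene_catalog,
        [
            GeneCompat(counts=[9, 1], q=[[q, 0.0], [0.0, q]]),
            GeneCompat(counts=[10], q=[[q, q]]),
        ],
    )
    net = TranscriptNetwork(two_gene_catalog, np.array([[0, 2]]))
    return two_gene_catalog, compat, net


def random_gene_compat(
    rng: np.random.Generator,
    n_tx: int | None = None,
    n_classes: int | None = None,
) -> GeneCompat:
    """A random single-gene instance with valid classes."""
    k = n_tx if n_tx is not None else int(rng.integers(2, 7))
    e = n_classes if n_classes is not None else int(rng.integers(5, 201))
    counts = rng.integers(1, 20, size=e).astype(float)
    q = np.zeros((e, k))
    for row in range(e):
        members = rng.choice(k, size=int(rng.integers(1, k + 1)), replace=False)
        q[row, members] = 1.0 / rng.integers(50, 2000, size=members.size)
    return GeneCompat(counts=counts, q=q)


@pytest.fixture(scope="session")
def recovery_study() -> dict:
    """The full parameter-recovery experiment at the study scale:
    10 replicate datasets of 100 genes / 200k reads, three prior weights,
    20 label-permuted null networks, and three edge-removal fractions."""
    return recovery_experiment(
        n_seeds=10,
        lams=(0.01, 0.1, 1.0),
        n_genes=100,
        n_reads=200_000,
        n_permutations=20,
        removal_fractions=(0.1, 0.2, 0.9),
        base_seed=20240001,
    )
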