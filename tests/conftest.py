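import numpy as np
import pytest

import netcbi as nc


@pytest.fixture()
def toy_similarity():
    """3x3 symmetric miRNA similarity with unequal off-diagonal weights."""
    values = np.array(
        [
            [1.0, 0.8, 0.2],
            [0.8, 1.0, 0.4],
            [0.2, 0.4, 1.0],
        ]
    )
    return nc.SimilarityMatrix(ids=("mirA", "mirB", "mirC"), values=values)


@pytest.fixture()
def toy_network():
    """3 miRNAs x 2 phenotypes with three known associations."""
    adjacency = np.array(
        [
            [0.0, 1.0],
            [1.0, 0.0],
            [0.0, 1.0],
        ]
    )
    return nc.AssociationNetwork(
        mirna_ids=("mirA", "mirB", "mirC"),
        phenotype_ids=("100001", "100002"),
        adjacency=adjacency,
    )


@pytest.fixture(scope="session")
def signal_dataset():
    """One seeded synthetic dataset with planted block signal (default spec)."""
    return nc.generate(nc.SyntheticSpec(seed=11))


def random_column_stochastic(rng: np.random.Generator, k: int) -> nc.SimilarityMatrix:
    """Random nonnegative matrix with every column normalized to sum 1."""
    values = rng.random((k, k))
    sim = nc.SimilarityMatrix(ids=tuple(f"e{i}" for i in range(k)), values=values)
    return nc.normalize_columns(sim)


def neumann_relevance(s_norm: np.ndarray, q: np.ndarray, alpha: float, terms: int = 4000):
    """Brute-force truncated series (1-a) * sum_k a^k S^k q — the independent
    oracle for the graph-Laplacian propagation."""
    acc = np.zeros_like(q, dtype=float)
    power = q.astype(float).copy()
    for _ in range(terms):
        acc += power
        power = alpha * (s_norm @ power)
    return (1.0 - alpha) * acc
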