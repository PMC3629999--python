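"""Benchmark-like synthetic fixtures for the full inference/evaluation stack.

Real inputs to the predictor are (i) a miRNA functional similarity matrix,
(ii) a disease-phenotype similarity matrix, and (iii) a sparse bipartite
association network whose edges preferentially connect functionally related
miRNAs to phenotypically similar diseases.  The generator emulates exactly
that statistical structure: miRNAs and phenotypes are partitioned into
paired blocks ("communities"); within-block similarity is drawn around a
high mean and cross-block similarity around a low one; associations are
Bernoulli edges with an elevated probability inside paired blocks.

A degree-preserving edge shuffle provides the matched null: it destroys the
similarity-association coupling while keeping both degree sequences, so any
residual AUC above chance on shuffled data would indicate a leak in the
evaluation protocol rather than signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .net_model import AssociationNetwork, SimilarityMatrix

__all__ = ["SyntheticSpec", "generate", "generate_null_by_shuffle"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a moderately sized network with clear but noisy
    community signal: 60 miRNAs and 30 phenotypes in 3 paired blocks,
    within-block similarity 0.7 vs 0.1 across blocks (sd 0.05), and a 0.3 vs
    0.02 association probability contrast.  Setting ``within_sim ==
    between_sim`` and ``edge_prob_matched == edge_prob_unmatched`` yields a
    null dataset with no planted signal.
    """

    n_mirnas: int = 60
    n_phenotypes: int = 30
    n_blocks: int = 3
    within_sim: float = 0.7
    between_sim: float = 0.1
    sim_noise: float = 0.05
    edge_prob_matched: float = 0.3
    edge_prob_unmatched: float = 0.02
    seed: int = 0
    allow_null: bool = field(default=False)

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_phenotypes", "n_blocks"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.n_blocks > min(self.n_mirnas, self.n_phenotypes):
            raise ParameterError("more blocks than entities on one side")
        for name in ("within_sim", "between_sim", "edge_prob_matched", "edge_prob_unmatched"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {value}")
        if self.sim_noise < 0:
            raise ParameterError("sim_noise must be nonnegative")
        if self.within_sim < self.between_sim:
            raise ParameterError("within_sim must be >= between_sim")
        if (
            not self.allow_null
            and self.within_sim == self.between_sim
            and self.edge_prob_matched == self.edge_prob_unmatched
        ):
            raise ParameterError(
                "spec plants no signal; pass allow_null=True for an explicit null dataset"
            )

    def null_version(self) -> "SyntheticSpec":
        """Signal-free counterpart: similarity and edge probabilities set to
        the averages of their matched/unmatched values."""
        mean_sim = 0.5 * (self.within_sim + self.between_sim)
        mean_edge = 0.5 * (self.edge_prob_matched + self.edge_prob_unmatched)
        return SyntheticSpec(
            n_mirnas=self.n_mirnas,
            n_phenotypes=self.n_phenotypes,
            n_blocks=self.n_blocks,
            within_sim=mean_sim,
            between_sim=mean_sim,
            sim_noise=self.sim_noise,
            edge_prob_matched=mean_edge,
            edge_prob_unmatched=mean_edge,
            seed=self.seed,
            allow_null=True,
        )


def _block_labels(count: int, n_blocks: int) -> np.ndarray:
    sizes = [len(chunk) for chunk in np.array_split(np.arange(count), n_blocks)]
    return np.repeat(np.arange(n_blocks), sizes)


def _block_similarity(
    labels: np.ndarray, within: float, between: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    means = np.where(same, within, between).astype(float)
    jitter = rng.normal(0.0, noise, size=means.shape) if noise > 0 else 0.0
    values = means + jitter
    values = np.triu(values, k=1)
    values = values + values.T  # symmetric off-diagonal
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return values


def generate(
    spec: SyntheticSpec,
) -> tuple[SimilarityMatrix, SimilarityMatrix, AssociationNetwork, dict]:
    """Draw one synthetic dataset; fully reproducible from ``spec.seed``.

    Returns the miRNA similarity matrix, the phenotype similarity matrix,
    the association network, and a ground-truth record with the block label
    of every entity.
    """
    rng = np.random.default_rng(spec.seed)
    mirna_labels = _block_labels(spec.n_mirnas, spec.n_blocks)
    phenotype_labels = _block_labels(spec.n_phenotypes, spec.n_blocks)
    mirna_ids = tuple(f"mir-{i + 1:03d}" for i in range(spec.n_mirnas))
    phenotype_ids = tuple(f"{100000 + j + 1}" for j in range(spec.n_phenotypes))

    sim_m = SimilarityMatrix(
        ids=mirna_ids,
        values=_block_similarity(
            mirna_labels, spec.within_sim, spec.between_sim, spec.sim_noise, rng
        ),
    )
    sim_p = SimilarityMatrix(
        ids=phenotype_ids,
        values=_block_similarity(
            phenotype_labels, spec.within_sim, spec.between_sim, spec.sim_noise, rng
        ),
    )
    matched = mirna_labels[:, None] == phenotype_labels[None, :]
    edge_prob = np.where(matched, spec.edge_prob_matched, spec.edge_prob_unmatched)
    adjacency = (rng.random(edge_prob.shape) < edge_prob).astype(float)
    net = AssociationNetwork(
        mirna_ids=mirna_ids, phenotype_ids=phenotype_ids, adjacency=adjacency
    )
    truth = {
        "mirna_blocks": {mid: int(b) for mid, b in zip(mirna_ids, mirna_labels)},
        "phenotype_blocks": {pid: int(b) for pid, b in zip(phenotype_ids, phenotype_labels)},
        "spec": {
            "n_mirnas": spec.n_mirnas,
            "n_phenotypes": spec.n_phenotypes,
            "n_blocks": spec.n_blocks,
            "within_sim": spec.within_sim,
            "between_sim": spec.between_sim,
            "sim_noise": spec.sim_noise,
            "edge_prob_matched": spec.edge_prob_matched,
            "edge_prob_unmatched": spec.edge_prob_unmatched,
            "seed": spec.seed,
        },
    }
    return sim_m, sim_p, net, truth


def generate_null_by_shuffle(
    net: AssociationNetwork, seed: int, n_swaps: int | None = None
) -> AssociationNetwork:
    """Degree-preserving randomization of the bipartite network.

    Repeated random 2x2 checkerboard swaps — pick two edges (i1, j1) and
    (i2, j2) with the cross pairs absent, replace them by (i1, j2) and
    (i2, j1) — leave both degree sequences exactly invariant while erasing
    any similarity-association coupling.  The default attempt budget of
    10x the edge count is a standard mixing heuristic for bipartite nulls.
    """
    adjacency = net.adjacency.copy()
    edges = list(zip(*np.nonzero(adjacency)))
    if len(edges) < 2:
        warnings.warn("too few edges to shuffle; returning the network unchanged", stacklevel=2)
        return net.with_adjacency(adjacency)
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    rng = np.random.default_rng(seed)
    for _ in range(n_swaps):
        k1, k2 = rng.integers(0, len(edges), size=2)
        (i1, j1), (i2, j2) = edges[k1], edges[k2]
        if i1 == i2 or j1 == j2:
            continue
        if adjacency[i1, j2] or adjacency[i2, j1]:
            continue
        adjacency[i1, j1] = adjacency[i2, j2] = 0.0
        adjacency[i1, j2] = adjacency[i2, j1] = 1.0
        edges[k1] = (i1, j2)
        edges[k2] = (i2, j1)
    return net.with_adjacency(adjacency)
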