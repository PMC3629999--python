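"""The three association scoring methods: MBSI, PBSI and NetCBI.

All three score miRNA-phenotype pairs on the bipartite association network
under the assumption that functionally related miRNAs target phenotypically
similar diseases; they differ in which similarity channel they exploit.

* **MBSI** (miRNA-based similarity inference): the score of pair (i, j) is
  the similarity-weighted average, over all other miRNAs l, of whether l is
  associated with phenotype j —

      v_ij = sum_{l != i} S(m_i, m_l) a_lj / sum_{l != i} S(m_i, m_l)

* **PBSI** (phenotype-based similarity inference): symmetric construction on
  the phenotype side —

      v_ij = sum_{l != j} S(p_j, p_l) a_il / sum_{l != j} S(p_j, p_l)

* **NetCBI** (network-consistency-based inference) combines both channels.
  Relevance of every miRNA to a query miRNA is measured by a graph-Laplacian
  label propagation on the column-normalized similarity network,

      m_tilde = (1 - alpha) (I - alpha * M_bar)^{-1} m,

  and likewise p_tilde on the phenotype network with parameter beta.  The
  score of candidate phenotype j for the query is the Pearson correlation
  between ``a @ p_tilde_j`` and ``m_tilde``: high when the known associations
  connect miRNAs relevant to the query with phenotypes relevant to j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import NumericalError, ParameterError, ValidationError
from .net_model import AssociationNetwork, QueryIndicator, SimilarityMatrix

__all__ = [
    "SmoothingParams",
    "RelevanceVector",
    "ScoreTable",
    "mbsi_scores",
    "pbsi_scores",
    "laplacian_relevance",
    "relevance_matrix",
    "netcbi_scores",
    "netcbi_score_table",
    "rank_predictions",
]

#: residual contract of the linear solve behind the Laplacian scores
SOLVE_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class SmoothingParams:
    """Propagation parameters: ``alpha`` on the miRNA side, ``beta`` on the
    phenotype side, both in the open interval (0, 1).  Larger values weight
    network smoothness over fidelity to the query indicator."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, value in (("alpha", self.alpha), ("beta", self.beta)):
            if not (0.0 < value < 1.0):
                raise ParameterError(f"{name} must lie in (0, 1), got {value}")


@dataclass(frozen=True)
class RelevanceVector:
    """Graph-Laplacian relevance scores aligned to one axis of the network."""

    axis: str
    scores: np.ndarray
    smoothing: float

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if not np.all(np.isfinite(scores)):
            raise NumericalError("relevance vector contains non-finite entries")


@dataclass(frozen=True)
class ScoreTable:
    """Dense n x m table of association scores for one method.

    MBSI/PBSI scores are weighted averages of binary values, hence in [0, 1];
    NetCBI scores are Pearson correlations in [-1, 1] with degenerate
    (zero-variance) cases mapped to 0.
    """

    mirna_ids: tuple[str, ...]
    phenotype_ids: tuple[str, ...]
    scores: np.ndarray
    method: str
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.mirna_ids), len(self.phenotype_ids)):
            raise ValidationError("score matrix shape does not match identifier axes")


def _check_alignment(sim_ids: tuple[str, ...], net_ids: tuple[str, ...], axis: str) -> None:
    if sim_ids != net_ids:
        raise ValidationError(
            f"similarity matrix {axis} identifiers do not match the association network"
        )


def mbsi_scores(sim_m: SimilarityMatrix, net: AssociationNetwork) -> ScoreTable:
    """Score every pair by miRNA-based similarity inference.

    The self term l == i is excluded from both sums, so a pair's score is a
    convex combination of the *other* miRNAs' association indicators.  A
    miRNA with zero similarity to every other miRNA has an empty evidence
    base; all its scores are defined as 0.
    """
    _check_alignment(sim_m.ids, net.mirna_ids, "miRNA")
    weights = sim_m.values.copy()
    np.fill_diagonal(weights, 0.0)
    numerator = weights @ net.adjacency
    denominator = weights.sum(axis=1)
    safe = np.where(denominator > 0, denominator, 1.0)
    scores = np.where(denominator[:, None] > 0, numerator / safe[:, None], 0.0)
    return ScoreTable(
        mirna_ids=net.mirna_ids,
        phenotype_ids=net.phenotype_ids,
        scores=scores,
        method="mbsi",
    )


def pbsi_scores(sim_p: SimilarityMatrix, net: AssociationNetwork) -> ScoreTable:
    """Score every pair by phenotype-based similarity inference (self term
    l == j excluded; zero-support phenotypes score 0)."""
    _check_alignment(sim_p.ids, net.phenotype_ids, "phenotype")
    weights = sim_p.values.copy()
    np.fill_diagonal(weights, 0.0)
    # score(i, j) = sum_l a_il * w_jl / sum_l w_jl
    numerator = net.adjacency @ weights.T
    denominator = weights.sum(axis=1)
    safe = np.where(denominator > 0, denominator, 1.0)
    scores = np.where(denominator[None, :] > 0, numerator / safe[None, :], 0.0)
    return ScoreTable(
        mirna_ids=net.mirna_ids,
        phenotype_ids=net.phenotype_ids,
        scores=scores,
        method="pbsi",
    )


def laplacian_relevance(
    sim_norm: SimilarityMatrix, query: QueryIndicator, alpha: float
) -> RelevanceVector:
    """Solve the graph-Laplacian propagation ``(I - alpha S) x = (1 - alpha) q``.

    This is the closed-form minimiser of a smoothness penalty over the
    similarity graph plus an alpha-weighted fidelity term to the query
    indicator.  The solution is obtained by a direct linear solve, never an
    explicit inverse, and checked against a residual contract of
    ``1e-8 * ||q||``.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if not sim_norm.normalized:
        raise ValidationError("laplacian_relevance requires a column-normalized matrix")
    q = query.vector
    if q.shape[0] != sim_norm.size:
        raise ValidationError("query indicator length does not match the similarity axis")
    system = np.eye(sim_norm.size) - alpha * sim_norm.values
    rhs = (1.0 - alpha) * q
    try:
        x = scipy.linalg.solve(system, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"propagation solve failed: {exc}") from exc
    residual = np.linalg.norm(system @ x - rhs)
    if residual > SOLVE_RESIDUAL_TOL * max(np.linalg.norm(q), 1e-300):
        raise NumericalError(
            f"propagation residual {residual:.3g} exceeds contract "
            f"{SOLVE_RESIDUAL_TOL:.0e} * ||q||"
        )
    return RelevanceVector(axis=query.axis, scores=x, smoothing=alpha)


def relevance_matrix(sim_norm: SimilarityMatrix, alpha: float) -> np.ndarray:
    """All single-entity relevance vectors at once: column i of the result is
    the propagation of the indicator of entity i.

    Equals ``(1 - alpha)(I - alpha S)^{-1}``, computed by one factorization
    shared across all right-hand sides; numerically equivalent to per-query
    solves within the solver tolerance.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if not sim_norm.normalized:
        raise ValidationError("relevance_matrix requires a column-normalized matrix")
    k = sim_norm.size
    system = np.eye(k) - alpha * sim_norm.values
    try:
        out = scipy.linalg.solve(system, (1.0 - alpha) * np.eye(k))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"propagation solve failed: {exc}") from exc
    return out


def _pearson_columns(matrix: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``vector`` against each column of ``matrix``;
    zero-variance cases give 0 rather than NaN."""
    xc = vector - vector.mean()
    xnorm = np.linalg.norm(xc)
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    col_norms = np.linalg.norm(centered, axis=0)
    denom = xnorm * col_norms
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered.T @ xc) / denom
    corr = np.where(denom > 0, corr, 0.0)
    return np.clip(corr, -1.0, 1.0)


def netcbi_scores(
    sim_m_norm: SimilarityMatrix,
    sim_p_norm: SimilarityMatrix,
    net: AssociationNetwork,
    query: QueryIndicator,
    params: SmoothingParams,
    *,
    phenotype_relevance: np.ndarray | None = None,
) -> np.ndarray:
    """NetCBI scores of every phenotype for one query miRNA.

    ``phenotype_relevance`` may carry a precomputed ``relevance_matrix`` of
    the phenotype network at ``params.beta`` so that repeated queries share
    the factorization; when omitted it is computed here.

    An all-zero association matrix carries no consistency signal: every
    correlation is degenerate and all scores are 0.
    """
    _check_alignment(sim_m_norm.ids, net.mirna_ids, "miRNA")
    _check_alignment(sim_p_norm.ids, net.phenotype_ids, "phenotype")
    if query.axis != "mirna":
        raise ValidationError("NetCBI queries are miRNAs")
    m_tilde = laplacian_relevance(sim_m_norm, query, params.alpha).scores
    if phenotype_relevance is None:
        phenotype_relevance = relevance_matrix(sim_p_norm, params.beta)
    # column j of (a @ P_tilde) is a @ p_tilde_j
    projected = net.adjacency @ phenotype_relevance
    if not net.adjacency.any():
        warnings.warn("association matrix is all-zero; every NetCBI score is 0", stacklevel=2)
    return _pearson_columns(projected, m_tilde)


def netcbi_score_table(
    sim_m_norm: SimilarityMatrix,
    sim_p_norm: SimilarityMatrix,
    net: AssociationNetwork,
    params: SmoothingParams,
) -> ScoreTable:
    """NetCBI scores for every (miRNA, phenotype) pair.

    Both relevance matrices are computed once; row i of the result is the
    score vector of query miRNA i against all phenotypes.
    """
    _check_alignment(sim_m_norm.ids, net.mirna_ids, "miRNA")
    _check_alignment(sim_p_norm.ids, net.phenotype_ids, "phenotype")
    m_relevance = relevance_matrix(sim_m_norm, params.alpha)
    p_relevance = relevance_matrix(sim_p_norm, params.beta)
    projected = net.adjacency @ p_relevance
    scores = np.empty((net.n, net.m))
    for i in range(net.n):
        scores[i] = _pearson_columns(projected, m_relevance[:, i])
    return ScoreTable(
        mirna_ids=net.mirna_ids,
        phenotype_ids=net.phenotype_ids,
        scores=scores,
        method="netcbi",
        alpha=params.alpha,
        beta=params.beta,
    )


def rank_predictions(table: ScoreTable, net: AssociationNetwork, top_k: int):
    """Rank the unknown pairs of a score table, highest score first.

    Pairs already present in the network (``a_ij == 1``) are excluded.  Ties
    are broken lexicographically on (miRNA id, phenotype id) so that output
    ordering is reproducible across runs and platforms.  Returns a pandas
    DataFrame with columns rank, mirna_id, phenotype_id, score; if ``top_k``
    exceeds the number of unknown pairs, all of them are returned.
    """
    if table.mirna_ids != net.mirna_ids or table.phenotype_ids != net.phenotype_ids:
        raise ValidationError("score table axes do not match the association network")
    if top_k < 0:
        raise ParameterError("top_k must be nonnegative")
    unknown_i, unknown_j = np.nonzero(net.adjacency == 0)
    records = sorted(
        (
            (-table.scores[i, j], table.mirna_ids[i], table.phenotype_ids[j])
            for i, j in zip(unknown_i, unknown_j)
        ),
    )
    records = records[: min(top_k, len(records))]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(records) + 1),
            "mirna_id": [r[1] for r in records],
            "phenotype_id": [r[2] for r in records],
            "score": [-r[0] for r in records],
            "method": table.method,
            "alpha": table.alpha,
            "beta": table.beta,
        }
    )
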