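"""Leave-one-out cross-validation, ROC/AUC computation and parameter tuning.

The evaluation protocol mirrors how the three methods are meant to be used.
For the miRNA-query methods (MBSI, NetCBI) every miRNA with at least one
association is held out in turn: its *entire* adjacency row is removed, the
reduced network scores all phenotypes for that miRNA, and the removed
phenotypes are the positives of a per-query ROC curve.  For PBSI the roles
swap: each phenotype's adjacency column is removed and its miRNAs ranked.
The reported figure of merit is the unweighted mean of per-query AUCs.

AUC is computed by a threshold sweep over the distinct candidate scores
(trapezoidal rule), which is provably identical to the pairwise-concordance
statistic P(score_pos > score_neg) + 0.5 P(score_pos = score_neg); both
routes are implemented and tested against each other.

Everything in this module is deterministic given its inputs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import ParameterError, UndefinedAUCError
from .inference import (
    SmoothingParams,
    mbsi_scores,
    pbsi_scores,
    relevance_matrix,
)
from .net_model import AssociationNetwork, SimilarityMatrix

__all__ = [
    "QueryResult",
    "CVReport",
    "TuningResult",
    "roc_auc",
    "concordance_auc",
    "loocv_mirna_query",
    "loocv_phenotype_query",
    "grid_search",
    "nested_loocv",
    "DEFAULT_GRID",
]

logger = logging.getLogger(__name__)

#: default tuning grid on both smoothing parameters
DEFAULT_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass(frozen=True)
class QueryResult:
    """ROC curve and AUC of one held-out query."""

    query_id: str
    roc_points: tuple[tuple[float, float], ...]  # (FPF, TPF) pairs
    auc: float


@dataclass(frozen=True)
class CVReport:
    """Outcome of one leave-one-out cross-validation run."""

    method: str
    per_query: tuple[QueryResult, ...]
    average_auc: float
    params: SmoothingParams | None = None
    skipped: tuple[tuple[str, str], ...] = ()

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "params": None
            if self.params is None
            else {"alpha": self.params.alpha, "beta": self.params.beta},
            "average_auc": self.average_auc,
            "per_query_auc": {q.query_id: q.auc for q in self.per_query},
            "skipped": [list(s) for s in self.skipped],
        }


@dataclass(frozen=True)
class TuningResult:
    """Outcome of a (possibly nested) parameter search."""

    grid: tuple[tuple[float, float], ...]
    grid_aucs: tuple[float, ...]
    selected: tuple[float, float]
    outer_auc: float | None = None
    selected_per_fold: tuple[tuple[float, float], ...] = ()

    @property
    def fold_mean_sd(self) -> tuple[tuple[float, float], tuple[float, float]] | None:
        """Per-fold selection summary: ((mean alpha, mean beta), (sd alpha, sd beta))."""
        if not self.selected_per_fold:
            return None
        arr = np.asarray(self.selected_per_fold)
        return tuple(arr.mean(axis=0)), tuple(arr.std(axis=0))

    def as_dict(self) -> dict:
        out = {
            "grid": [list(g) for g in self.grid],
            "grid_aucs": list(self.grid_aucs),
            "selected": list(self.selected),
            "outer_auc": self.outer_auc,
            "selected_per_fold": [list(s) for s in self.selected_per_fold],
        }
        summary = self.fold_mean_sd
        if summary is not None:
            out["selected_mean"] = list(summary[0])
            out["selected_sd"] = list(summary[1])
        return out


def roc_auc(scores, positives) -> tuple[tuple[tuple[float, float], ...], float]:
    """ROC curve and AUC from one score vector and a positive index set.

    Thresholds are the distinct score values in descending order; at each
    threshold TPF is the fraction of positives scoring at or above it and FPF
    the fraction of negatives doing so.  The curve is anchored at (0, 0) and
    (1, 1) and integrated by the trapezoidal rule, which half-credits ties.
    """
    scores = np.asarray(scores, dtype=float)
    pos_mask = np.zeros(scores.shape[0], dtype=bool)
    pos_mask[list(positives)] = True
    n_pos = int(pos_mask.sum())
    n_neg = scores.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("ROC needs at least one positive and one negative")
    thresholds = np.unique(scores)[::-1]
    at_or_above = scores[None, :] >= thresholds[:, None]
    tpf = at_or_above[:, pos_mask].sum(axis=1) / n_pos
    fpf = at_or_above[:, ~pos_mask].sum(axis=1) / n_neg
    fpf = np.concatenate(([0.0], fpf))
    tpf = np.concatenate(([0.0], tpf))
    # the final threshold (minimum score) always yields (1, 1)
    auc = float(np.trapezoid(tpf, fpf))
    return tuple(zip(fpf.tolist(), tpf.tolist())), auc


def concordance_auc(scores, positives) -> float:
    """AUC as the pairwise-concordance probability (Mann-Whitney form):
    P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg).

    Kept as an independent route to the same quantity as :func:`roc_auc`.
    """
    scores = np.asarray(scores, dtype=float)
    pos_mask = np.zeros(scores.shape[0], dtype=bool)
    pos_mask[list(positives)] = True
    pos = scores[pos_mask]
    neg = scores[~pos_mask]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedAUCError("AUC needs at least one positive and one negative")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))


def _fast_auc(scores: np.ndarray, pos_mask: np.ndarray) -> float:
    """Rank-based AUC (identical to roc_auc); used in tuning inner loops
    where the ROC points themselves are not needed."""
    n_pos = int(pos_mask.sum())
    n_neg = scores.shape[0] - n_pos
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _mirna_query_scorer(method, sim_m, sim_p, params):
    """Return f(adjacency_without_query_row, query_index) -> phenotype scores.

    Heavy per-parameter work (the two propagation matrices and the projected
    association matrix) is factored out so that the LOOCV loop touches only
    cheap rank-1 updates: removing the query row of ``a`` changes exactly one
    row of ``a @ P_tilde``.
    """
    if method == "mbsi":
        def score(net_loo: AssociationNetwork, i: int) -> np.ndarray:
            return mbsi_scores(sim_m, net_loo).scores[i]

        return score
    if method == "netcbi":
        if params is None:
            raise ParameterError("NetCBI evaluation requires SmoothingParams")
        from .inference import _pearson_columns

        m_rel = relevance_matrix(sim_m, params.alpha)
        p_rel = relevance_matrix(sim_p, params.beta)

        def score(net_loo: AssociationNetwork, i: int) -> np.ndarray:
            projected = net_loo.adjacency @ p_rel
            return _pearson_columns(projected, m_rel[:, i])

        return score
    raise ParameterError(f"unknown miRNA-query method {method!r}")


def loocv_mirna_query(
    method: str,
    sim_m: SimilarityMatrix,
    sim_p: SimilarityMatrix | None,
    net: AssociationNetwork,
    params: SmoothingParams | None = None,
) -> CVReport:
    """Leave-one-out cross-validation over miRNA queries (MBSI or NetCBI).

    For each miRNA with at least one association, its whole adjacency row is
    zeroed, all phenotypes are scored for it on the reduced network, and the
    removed phenotypes act as positives.  Queries with no associations are
    skipped (nothing to hold out); queries with no negatives have an
    undefined ROC and are excluded from the average with a logged note.

    ``sim_m`` must be un-normalized for MBSI and column-normalized for
    NetCBI (which also needs normalized ``sim_p``).
    """
    scorer = _mirna_query_scorer(method, sim_m, sim_p, params)
    adjacency = net.adjacency
    results: list[QueryResult] = []
    skipped: list[tuple[str, str]] = []
    for i in range(net.n):
        positives = np.flatnonzero(adjacency[i])
        if positives.size == 0:
            skipped.append((net.mirna_ids[i], "no associations to hold out"))
            continue
        if positives.size == net.m:
            skipped.append((net.mirna_ids[i], "no negatives; AUC undefined"))
            logger.warning(
                "query %s associates with every phenotype; excluded from the average",
                net.mirna_ids[i],
            )
            continue
        reduced = adjacency.copy()
        reduced[i] = 0.0
        scores = scorer(net.with_adjacency(reduced), i)
        roc, auc = roc_auc(scores, positives)
        results.append(QueryResult(query_id=net.mirna_ids[i], roc_points=roc, auc=auc))
    if not results:
        raise UndefinedAUCError("no evaluable miRNA queries in the network")
    return CVReport(
        method=method,
        per_query=tuple(results),
        average_auc=float(np.mean([r.auc for r in results])),
        params=params,
        skipped=tuple(skipped),
    )


def loocv_phenotype_query(
    sim_p: SimilarityMatrix, net: AssociationNetwork
) -> CVReport:
    """Leave-one-out cross-validation over phenotype queries with PBSI.

    Each phenotype's adjacency column is removed in turn and its miRNAs
    ranked by PBSI on the reduced network.  (PBSI's sum over l != j never
    reads column j, so the reduced-network scores coincide with the
    full-network ones; the removal is still performed for protocol
    uniformity.)
    """
    adjacency = net.adjacency
    results: list[QueryResult] = []
    skipped: list[tuple[str, str]] = []
    for j in range(net.m):
        positives = np.flatnonzero(adjacency[:, j])
        if positives.size == 0:
            skipped.append((net.phenotype_ids[j], "no associations to hold out"))
            continue
        if positives.size == net.n:
            skipped.append((net.phenotype_ids[j], "no negatives; AUC undefined"))
            logger.warning(
                "query %s associates with every miRNA; excluded from the average",
                net.phenotype_ids[j],
            )
            continue
        reduced = adjacency.copy()
        reduced[:, j] = 0.0
        scores = pbsi_scores(sim_p, net.with_adjacency(reduced)).scores[:, j]
        roc, auc = roc_auc(scores, positives)
        results.append(QueryResult(query_id=net.phenotype_ids[j], roc_points=roc, auc=auc))
    if not results:
        raise UndefinedAUCError("no evaluable phenotype queries in the network")
    return CVReport(
        method="pbsi",
        per_query=tuple(results),
        average_auc=float(np.mean([r.auc for r in results])),
        skipped=tuple(skipped),
    )


def _validate_grid(alpha_grid, beta_grid) -> tuple[tuple[float, ...], tuple[float, ...]]:
    alpha_grid = tuple(float(a) for a in alpha_grid)
    beta_grid = tuple(float(b) for b in beta_grid)
    if not alpha_grid or not beta_grid:
        raise ParameterError("parameter grids must be non-empty")
    for v in itertools.chain(alpha_grid, beta_grid):
        if not (0.0 < v < 1.0):
            raise ParameterError(f"grid value {v} outside (0, 1)")
    return alpha_grid, beta_grid


def _netcbi_loocv_mean_auc(
    m_rel: np.ndarray,
    projected: np.ndarray,
    adjacency: np.ndarray,
    query_indices,
) -> float:
    """Mean NetCBI LOOCV AUC given precomputed propagation products.

    ``projected`` is ``a @ P_tilde`` for the *training* adjacency (which must
    already have any outer-fold row removed along with ``adjacency``);
    zeroing a query's row of ``a`` zeroes exactly that row of the product.
    """
    from .inference import _pearson_columns

    aucs = []
    for i in query_indices:
        pos_mask = adjacency[i] > 0
        if not pos_mask.any() or pos_mask.all():
            continue
        reduced = projected.copy()
        reduced[i] = 0.0
        scores = _pearson_columns(reduced, m_rel[:, i])
        aucs.append(_fast_auc(scores, pos_mask))
    if not aucs:
        raise UndefinedAUCError("no evaluable queries")
    return float(np.mean(aucs))


def grid_search(
    sim_m_norm: SimilarityMatrix,
    sim_p_norm: SimilarityMatrix,
    net: AssociationNetwork,
    alpha_grid=DEFAULT_GRID,
    beta_grid=DEFAULT_GRID,
) -> TuningResult:
    """Exhaustive (alpha, beta) search maximising the NetCBI LOOCV average AUC.

    Ties are resolved toward the lexicographically smallest (alpha, beta).
    """
    alpha_grid, beta_grid = _validate_grid(alpha_grid, beta_grid)
    queries = range(net.n)
    grid: list[tuple[float, float]] = []
    aucs: list[float] = []
    m_rels = {a: relevance_matrix(sim_m_norm, a) for a in alpha_grid}
    p_rels = {b: relevance_matrix(sim_p_norm, b) for b in beta_grid}
    for alpha in alpha_grid:
        for beta in beta_grid:
            projected = net.adjacency @ p_rels[beta]
            auc = _netcbi_loocv_mean_auc(m_rels[alpha], projected, net.adjacency, queries)
            grid.append((alpha, beta))
            aucs.append(auc)
    best = max(range(len(grid)), key=lambda k: (aucs[k], (-grid[k][0], -grid[k][1])))
    return TuningResult(grid=tuple(grid), grid_aucs=tuple(aucs), selected=grid[best])


def nested_loocv(
    sim_m_norm: SimilarityMatrix,
    sim_p_norm: SimilarityMatrix,
    net: AssociationNetwork,
    alpha_grid=DEFAULT_GRID,
    beta_grid=DEFAULT_GRID,
) -> TuningResult:
    """Nested leave-one-out cross-validation for an unbiased NetCBI AUC.

    Outer loop: each miRNA in turn becomes the validation case and its
    adjacency row is removed.  Inner loop: a full LOOCV over the remaining
    miRNAs, run at every grid point, selects (alpha, beta) for that fold
    (ties toward the smallest pair).  The validation miRNA is then scored
    with the selected parameters on the row-removed network and its AUC
    recorded.  ``outer_auc`` is the mean of validation AUCs;
    ``selected_per_fold`` keeps each fold's choice so the spread of selected
    parameters can be summarised as mean +/- sd.
    """
    from .inference import _pearson_columns

    alpha_grid, beta_grid = _validate_grid(alpha_grid, beta_grid)
    m_rels = {a: relevance_matrix(sim_m_norm, a) for a in alpha_grid}
    p_rels = {b: relevance_matrix(sim_p_norm, b) for b in beta_grid}
    pairs = [(a, b) for a in alpha_grid for b in beta_grid]

    adjacency = net.adjacency
    outer_aucs: list[float] = []
    fold_choices: list[tuple[float, float]] = []
    # accumulate mean inner AUC per grid point across folds for reporting
    grid_auc_sums = np.zeros(len(pairs))
    n_folds = 0

    for v in range(net.n):
        positives = np.flatnonzero(adjacency[v])
        if positives.size == 0 or positives.size == net.m:
            continue
        train_adj = adjacency.copy()
        train_adj[v] = 0.0
        inner_queries = [t for t in range(net.n) if t != v]
        inner_aucs = []
        for k, (alpha, beta) in enumerate(pairs):
            projected = train_adj @ p_rels[beta]
            try:
                auc = _netcbi_loocv_mean_auc(
                    m_rels[alpha], projected, train_adj, inner_queries
                )
            except UndefinedAUCError:
                auc = np.nan
            inner_aucs.append(auc)
        inner_aucs = np.asarray(inner_aucs)
        if np.all(np.isnan(inner_aucs)):
            continue
        best = max(
            range(len(pairs)),
            key=lambda k: (
                -np.inf if np.isnan(inner_aucs[k]) else inner_aucs[k],
                (-pairs[k][0], -pairs[k][1]),
            ),
        )
        alpha, beta = pairs[best]
        fold_choices.append((alpha, beta))
        grid_auc_sums += np.where(np.isnan(inner_aucs), 0.0, inner_aucs)
        n_folds += 1
        # validate the held-out miRNA with the fold's selected parameters
        projected = train_adj @ p_rels[beta]
        scores = _pearson_columns(projected, m_rels[alpha][:, v])
        pos_mask = np.zeros(net.m, dtype=bool)
        pos_mask[positives] = True
        outer_aucs.append(_fast_auc(scores, pos_mask))

    if not outer_aucs:
        raise UndefinedAUCError("no evaluable outer folds")
    grid_aucs = tuple((grid_auc_sums / n_folds).tolist())
    # overall selection: argmax of the fold-averaged inner AUCs, ties toward
    # the smallest (alpha, beta) pair
    best_overall = max(
        range(len(pairs)),
        key=lambda k: (grid_aucs[k], (-pairs[k][0], -pairs[k][1])),
    )
    selected = pairs[best_overall]
    return TuningResult(
        grid=tuple(pairs),
        grid_aucs=grid_aucs,
        selected=selected,
        outer_auc=float(np.mean(outer_aucs)),
        selected_per_fold=tuple(fold_choices),
    )
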