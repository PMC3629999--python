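"""Core data types for similarity networks and the bipartite association network.

A prediction run consumes three inputs:

* a square miRNA-miRNA functional similarity matrix ``M`` (rows/columns are
  miRNA identifiers, entries in ``[0, 1]``, MISIM-style),
* a square disease-phenotype similarity matrix ``P`` (rows/columns are OMIM
  phenotype identifiers, MimMiner-style),
* a two-column edge list of experimentally verified miRNA-phenotype
  associations, encoded as the binary ``n x m`` adjacency ``a``.

This module holds the containers for those objects, the TSV loaders, the
column normalization used by the graph-Laplacian propagation, and basic
degree statistics of the bipartite network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "SimilarityMatrix",
    "AssociationNetwork",
    "QueryIndicator",
    "DegreeStats",
    "load_similarity",
    "load_associations",
    "normalize_columns",
    "degree_stats",
]

#: symmetry deviations larger than this trigger a warning in the loader
SYMMETRY_TOL = 1e-8
#: column sums after normalization must match 1 within this tolerance
NORMALIZATION_TOL = 1e-10


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square nonnegative similarity matrix with an ordered identifier axis.

    Parameters
    ----------
    ids
        Entity identifiers (miRNA names or OMIM phenotype IDs), one per
        row/column, in matrix order.
    values
        Square ``(k, k)`` array of nonnegative similarity scores.
    normalized
        True when every column with a nonzero original sum has been scaled
        to sum to 1 (the column-stochastic form used for propagation).
    """

    ids: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise FormatError(f"similarity matrix must be square, got shape {values.shape}")
        if len(self.ids) != values.shape[0]:
            raise ValidationError(
                f"{len(self.ids)} ids for a {values.shape[0]}x{values.shape[1]} matrix"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate identifiers in similarity matrix")
        if not np.all(np.isfinite(values)):
            raise ValidationError("similarity matrix contains non-finite entries")
        if np.any(values < 0):
            raise ValidationError("similarity matrix contains negative entries")
        if self.normalized:
            sums = values.sum(axis=0)
            bad = np.abs(sums[sums > 0] - 1.0) > NORMALIZATION_TOL
            if np.any(bad):
                raise ValidationError(
                    "normalized flag set but some nonzero columns do not sum to 1"
                )

    @property
    def size(self) -> int:
        return len(self.ids)

    def index_of(self, entity_id: str) -> int:
        try:
            return self.ids.index(entity_id)
        except ValueError:
            raise KeyError(f"unknown identifier {entity_id!r}") from None

    def restrict(self, keep_ids: list[str]) -> "SimilarityMatrix":
        """Sub-matrix over ``keep_ids``, in the given order."""
        idx = [self.index_of(i) for i in keep_ids]
        return SimilarityMatrix(
            ids=tuple(keep_ids),
            values=self.values[np.ix_(idx, idx)].copy(),
            normalized=False,
        )


@dataclass(frozen=True)
class AssociationNetwork:
    """Bipartite miRNA-phenotype association network, the binary adjacency ``a``.

    Rows index miRNAs (length ``n``), columns index disease phenotypes
    (length ``m``); ``adjacency[i, j] == 1`` records a verified association.
    ``kept_edges``/``dropped_edges`` carry the loader's bookkeeping when the
    source edge list referenced entities outside the similarity universes.
    """

    mirna_ids: tuple[str, ...]
    phenotype_ids: tuple[str, ...]
    adjacency: np.ndarray
    kept_edges: int = field(default=-1)
    dropped_edges: int = 0

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "mirna_ids", tuple(str(i) for i in self.mirna_ids))
        object.__setattr__(self, "phenotype_ids", tuple(str(i) for i in self.phenotype_ids))
        if adj.ndim != 2 or adj.shape != (len(self.mirna_ids), len(self.phenotype_ids)):
            raise ValidationError(
                f"adjacency shape {adj.shape} does not match "
                f"({len(self.mirna_ids)}, {len(self.phenotype_ids)}) identifiers"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValidationError("duplicate miRNA identifiers")
        if len(set(self.phenotype_ids)) != len(self.phenotype_ids):
            raise ValidationError("duplicate phenotype identifiers")
        if not np.isin(adj, (0.0, 1.0)).all():
            raise ValidationError("adjacency entries must be exactly 0 or 1")
        if self.kept_edges < 0:
            object.__setattr__(self, "kept_edges", int(adj.sum()))

    @property
    def n(self) -> int:
        """Number of miRNAs (rows)."""
        return len(self.mirna_ids)

    @property
    def m(self) -> int:
        """Number of disease phenotypes (columns)."""
        return len(self.phenotype_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def with_adjacency(self, adjacency: np.ndarray) -> "AssociationNetwork":
        """Same axes, different adjacency (used by LOOCV removal and shuffles)."""
        return replace(self, adjacency=adjacency, kept_edges=int(np.asarray(adjacency).sum()))


@dataclass(frozen=True)
class QueryIndicator:
    """Binary indicator of query entities on one axis of the bipartite network.

    The single-query form is the field's query vector: all zeros except a one
    at the query entity.  Multi-entity indicators are accepted by the
    Laplacian propagation but NetCBI scoring is defined per single miRNA.
    """

    axis: str  # "mirna" | "phenotype"
    vector: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in ("mirna", "phenotype"):
            raise ValidationError(f"axis must be 'mirna' or 'phenotype', got {self.axis!r}")
        vec = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", vec)
        if vec.ndim != 1:
            raise ValidationError("query indicator must be a 1-D vector")
        if not np.isin(vec, (0.0, 1.0)).all():
            raise ValidationError("query indicator entries must be 0 or 1")
        if vec.sum() < 1:
            raise ValidationError("query indicator must mark at least one entity")

    @classmethod
    def single(cls, axis: str, index: int, length: int) -> "QueryIndicator":
        vec = np.zeros(length)
        vec[index] = 1.0
        return cls(axis=axis, vector=vec)

    @property
    def index(self) -> int:
        """Position of the query entity; errors on multi-entity indicators."""
        hits = np.flatnonzero(self.vector)
        if hits.size != 1:
            raise ValidationError("indicator marks more than one entity")
        return int(hits[0])


@dataclass(frozen=True)
class DegreeStats:
    """Summary statistics of the bipartite association network."""

    n_mirnas: int
    n_phenotypes: int
    n_edges: int
    avg_mirna_degree: float
    avg_phenotype_degree: float
    mirna_degrees: tuple[int, ...]
    phenotype_degrees: tuple[int, ...]

    def as_dict(self) -> dict:
        return {
            "n_mirnas": self.n_mirnas,
            "n_phenotypes": self.n_phenotypes,
            "n_edges": self.n_edges,
            "avg_mirna_degree": self.avg_mirna_degree,
            "avg_phenotype_degree": self.avg_phenotype_degree,
            "mirna_degrees": list(self.mirna_degrees),
            "phenotype_degrees": list(self.phenotype_degrees),
        }


def load_similarity(path) -> SimilarityMatrix:
    """Read a similarity matrix from TSV (first row/column carry identifiers).

    Gzip-compressed files are handled transparently via their extension.
    Row and column identifier sets must match exactly; asymmetry beyond
    ``SYMMETRY_TOL`` is reported as a warning but does not abort, since the
    downstream column normalization breaks symmetry anyway.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse similarity table {path}: {exc}") from exc
    row_ids = [str(i) for i in frame.index]
    col_ids = [str(c) for c in frame.columns]
    if len(row_ids) != len(col_ids):
        raise FormatError(
            f"{path}: table is {len(row_ids)}x{len(col_ids)}, expected square"
        )
    if row_ids != col_ids:
        raise FormatError(f"{path}: row identifiers differ from column identifiers")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell value: {exc}") from exc
    sim = SimilarityMatrix(ids=tuple(row_ids), values=values)
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > SYMMETRY_TOL:
        warnings.warn(
            f"{path}: similarity matrix asymmetric (max |S - S^T| = {asym:.3g}); "
            "values used as given",
            stacklevel=2,
        )
    return sim


def load_associations(
    path,
    mirna_universe,
    phenotype_universe,
    on_unknown_phenotype: str = "drop",
) -> AssociationNetwork:
    """Read a two-column (miRNA, phenotype) edge list into a binary adjacency.

    Edges whose miRNA is not in ``mirna_universe`` are dropped and counted:
    with the published benchmark this is exactly the filter that reduces the
    270 curated associations to the 242 whose miRNAs carry functional
    similarity scores.  Unknown phenotypes are dropped with a warning by
    default, or rejected when ``on_unknown_phenotype="fail"``.

    An optional single header line is recognised when neither of its two
    fields belongs to either universe.
    """
    if on_unknown_phenotype not in ("drop", "fail"):
        raise ValidationError("on_unknown_phenotype must be 'drop' or 'fail'")
    mirna_ids = [str(i) for i in mirna_universe]
    phenotype_ids = [str(i) for i in phenotype_universe]
    mirna_index = {mid: k for k, mid in enumerate(mirna_ids)}
    phenotype_index = {pid: k for k, pid in enumerate(phenotype_ids)}
    if len(mirna_index) != len(mirna_ids) or len(phenotype_index) != len(phenotype_ids):
        raise ValidationError("duplicate identifiers in a universe list")

    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs two tab-separated columns")
    edges = [(str(a).strip(), str(b).strip()) for a, b in frame.iloc[:, :2].itertuples(index=False)]
    if edges:
        first_m, first_p = edges[0]
        known = set(mirna_index) | set(phenotype_index)
        if first_m not in known and first_p not in known:
            edges = edges[1:]  # header line

    adjacency = np.zeros((len(mirna_ids), len(phenotype_ids)))
    kept = dropped = 0
    for mid, pid in edges:
        if mid not in mirna_index:
            dropped += 1
            continue
        if pid not in phenotype_index:
            if on_unknown_phenotype == "fail":
                raise ValidationError(f"{path}: unknown phenotype {pid!r} in edge list")
            warnings.warn(f"{path}: dropping edge with unknown phenotype {pid!r}", stacklevel=2)
            dropped += 1
            continue
        adjacency[mirna_index[mid], phenotype_index[pid]] = 1.0
        kept += 1
    return AssociationNetwork(
        mirna_ids=tuple(mirna_ids),
        phenotype_ids=tuple(phenotype_ids),
        adjacency=adjacency,
        kept_edges=kept,
        dropped_edges=dropped,
    )


def normalize_columns(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Column-stochastic normalization: each column divided by its own sum.

    Columns whose sum is zero (an entity with no similarity to anything) are
    left as zero vectors, preserving their "no information" semantics and
    keeping ``I - alpha * S`` well conditioned.  Applying the operation to an
    already-normalized matrix warns and is a numerical no-op.
    """
    if sim.normalized:
        warnings.warn("normalize_columns applied to an already-normalized matrix", stacklevel=2)
    sums = sim.values.sum(axis=0)
    safe = np.where(sums > 0, sums, 1.0)
    return SimilarityMatrix(ids=sim.ids, values=sim.values / safe, normalized=True)


def degree_stats(net: AssociationNetwork) -> DegreeStats:
    """Degree summary of the bipartite network.

    Average miRNA degree is edges / n and average phenotype degree edges / m,
    the two headline statistics of the association network; the full degree
    multisets are returned for distribution work.
    """
    mirna_degrees = net.adjacency.sum(axis=1).astype(int)
    phenotype_degrees = net.adjacency.sum(axis=0).astype(int)
    edges = int(mirna_degrees.sum())
    return DegreeStats(
        n_mirnas=net.n,
        n_phenotypes=net.m,
        n_edges=edges,
        avg_mirna_degree=edges / net.n if net.n else 0.0,
        avg_phenotype_degree=edges / net.m if net.m else 0.0,
        mirna_degrees=tuple(int(d) for d in mirna_degrees),
        phenotype_degrees=tuple(int(d) for d in phenotype_degrees),
    )
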