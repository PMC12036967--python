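"""Core containers and the black-box classifier contract.

Every attack in this package perturbs a genes-by-cells :class:`ExpressionMatrix`
and interrogates a classifier through a single narrow interface,
:class:`ClassifierAdapter`: matrix + per-cell cluster labeling + target cluster
label in, a :class:`ClassifierOutput` (cluster prediction, cluster score,
per-cell score matrix over a fixed cell-type vocabulary, per-cell predictions)
out.  Nothing downstream sees anything else of the model, so any classifier —
marker scoring, SVM, random forest, neural network — can be probed as long as
it is wrapped to honour this contract.

Conventions fixed here and relied on everywhere else:

* matrices are stored genes x cells (the on-disk 10x convention); public
  operations take gene/cell identifiers, never raw indices;
* per-cell predictions are the row-wise argmax of the per-cell score matrix,
  ties broken by the first cell-type column;
* the cluster-level score vector counts, for the target cluster, how many
  cells have each cell type as their argmax; its top two entries (``ctype1``,
  ``ctype2``) define the gradient-descent attack target, with count ties
  broken by the column-wise sum of cell scores over the cluster and then by
  column order, so the target is well defined even for a unanimous cluster.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse as sp


def _is_sparse(values) -> bool:
    return sp.issparse(values)


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with unique string identifiers.

    ``values`` may be a dense :class:`numpy.ndarray` or any scipy sparse
    matrix; sparse inputs are kept sparse until an operation needs dense rows.
    Expression units are whatever the caller provides (raw counts or
    log-normalized values) — the attacks are unit-agnostic.
    """

    values: "np.ndarray | sp.spmatrix"
    gene_ids: list[str]
    cell_ids: list[str]
    _gene_index: dict = field(init=False, repr=False, compare=False)
    _cell_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if not _is_sparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def is_sparse(self) -> bool:
        return _is_sparse(self.values)

    # -- lookups --------------------------------------------------------
    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def cell_index(self, cell_id: str) -> int:
        try:
            return self._cell_index[cell_id]
        except KeyError:
            raise KeyError(f"unknown cell id: {cell_id!r}") from None

    def gene_values(self, gene_id: str) -> np.ndarray:
        """Dense 1-D expression vector of one gene across all cells."""
        j = self.gene_index(gene_id)
        if self.is_sparse:
            return np.asarray(self.values[[j], :].todense()).ravel()
        return np.asarray(self.values[j, :]).ravel()

    def dense(self) -> np.ndarray:
        """Dense genes x cells array (a view for dense storage)."""
        if self.is_sparse:
            return np.asarray(self.values.todense())
        return self.values

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids), list(self.cell_ids))

    def equals(self, other: "ExpressionMatrix") -> bool:
        """Exact (bit-identical) equality of ids and values."""
        if self.gene_ids != other.gene_ids or self.cell_ids != other.cell_ids:
            return False
        if self.is_sparse or other.is_sparse:
            return np.array_equal(self.dense(), other.dense())
        return np.array_equal(self.values, other.values)


def validate_matrix(matrix: ExpressionMatrix) -> list[str]:
    """Check :class:`ExpressionMatrix` invariants; return violations, never raise.

    An empty list means the matrix is well formed.  Each violation names the
    broken rule and the offending identifier or coordinate.
    """
    violations: list[str] = []
    if matrix.values.shape != (len(matrix.gene_ids), len(matrix.cell_ids)):
        violations.append(
            "dimension mismatch: values %s vs %d gene ids x %d cell ids"
            % (matrix.values.shape, len(matrix.gene_ids), len(matrix.cell_ids))
        )
    for kind, ids in (("gene", matrix.gene_ids), ("cell", matrix.cell_ids)):
        seen: set[str] = set()
        for name in ids:
            if name in seen:
                violations.append(f"duplicate {kind} id: {name!r}")
            seen.add(name)
    dense = matrix.dense()
    if dense.size and not np.all(np.isfinite(dense)):
        bad = np.argwhere(~np.isfinite(dense))
        for j, i in bad[:20]:  # cap the report, not the check
            g = matrix.gene_ids[j] if j < len(matrix.gene_ids) else f"row{j}"
            c = matrix.cell_ids[i] if i < len(matrix.cell_ids) else f"col{i}"
            violations.append(f"non-finite entry at ({g}, {c})")
        if len(bad) > 20:
            violations.append(f"... and {len(bad) - 20} further non-finite entries")
    return violations


@dataclass
class ClusterLabeling:
    """Assignment of each cell to exactly one cluster label."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        self.assignment = {str(c): str(l) for c, l in self.assignment.items()}

    @classmethod
    def from_series(cls, series: pd.Series) -> "ClusterLabeling":
        return cls(dict(zip(series.index.astype(str), series.astype(str))))

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def cells_of(self, label: str) -> list[str]:
        cells = [c for c, l in self.assignment.items() if l == label]
        if not cells:
            raise KeyError(f"unknown or empty cluster label: {label!r}")
        return cells

    def validate_against(self, matrix: ExpressionMatrix) -> list[str]:
        violations = []
        missing = [c for c in matrix.cell_ids if c not in self.assignment]
        if missing:
            violations.append(f"cells without a cluster label: {missing[:10]}")
        return violations


@dataclass
class ClassifierOutput:
    """What a wrapped classifier returns for one (matrix, labeling, target) query.

    ``cell_scores`` is a cells x cell-types DataFrame covering at least every
    cell of the target cluster; ``cell_predictions`` must equal its row-wise
    argmax with first-column tie-break.  ``cluster_score`` is adapter-defined
    (a likelihood, vote fraction, margin, ...).
    """

    cluster_prediction: str
    cluster_score: float
    cell_scores: pd.DataFrame
    cell_predictions: pd.Series


def argmax_predictions(cell_scores: pd.DataFrame) -> pd.Series:
    """Row-wise argmax with deterministic first-column tie-break."""
    idx = cell_scores.to_numpy().argmax(axis=1)
    return pd.Series(
        [cell_scores.columns[k] for k in idx], index=cell_scores.index, dtype=object
    )


@dataclass
class ClusterScoreVector:
    """Per-cell-type counts of argmax predictions inside the target cluster.

    ``ranking`` orders the cell-type vocabulary by (count desc, summed cell
    score over the cluster desc, column order); ``ctype1``/``ctype2`` are its
    first two entries.
    """

    counts: dict[str, int]
    ranking: list[str]

    @property
    def ctype1(self) -> str:
        return self.ranking[0]

    @property
    def ctype2(self) -> str | None:
        return self.ranking[1] if len(self.ranking) > 1 else None

    def gap(self) -> int:
        """Count margin between the top and runner-up cell types."""
        if self.ctype2 is None:
            return self.counts[self.ctype1]
        return self.counts[self.ctype1] - self.counts[self.ctype2]


def cluster_score_vector(
    output: ClassifierOutput, labeling: ClusterLabeling, target: str
) -> ClusterScoreVector:
    """Summarize per-cell predictions of the target cluster into type counts."""
    cells = labeling.cells_of(target)  # raises on unknown label
    missing = [c for c in cells if c not in output.cell_scores.index]
    if missing:
        raise KeyError(f"classifier output misses target cells: {missing[:10]}")
    preds = output.cell_predictions.loc[cells]
    vocab = list(output.cell_scores.columns)
    counts = {k: int((preds == k).sum()) for k in vocab}
    sums = output.cell_scores.loc[cells].sum(axis=0)
    order = sorted(
        range(len(vocab)), key=lambda i: (-counts[vocab[i]], -float(sums.iloc[i]), i)
    )
    return ClusterScoreVector(counts=counts, ranking=[vocab[i] for i in order])


class ClassifierAdapter(abc.ABC):
    """The black-box contract every attack talks to.

    Subclasses declare their fixed cell-type vocabulary in ``cell_types`` and
    implement :meth:`classify`.  Adapters must never mutate the input matrix
    and must be deterministic unless they set ``stochastic = True``.
    """

    cell_types: tuple[str, ...] = ()
    stochastic: bool = False

    @abc.abstractmethod
    def classify(
        self, matrix: ExpressionMatrix, labeling: ClusterLabeling, target: str
    ) -> ClassifierOutput:
        ...

    def __call__(
        self, matrix: ExpressionMatrix, labeling: ClusterLabeling, target: str
    ) -> ClassifierOutput:
        return self.classify(matrix, labeling, target)


class CallCountingAdapter(ClassifierAdapter):
    """Transparent proxy counting classifier evaluations.

    Attacks wrap the user's adapter with this proxy so that reported
    ``classifier_calls`` are exact.  The single baseline classification of the
    pristine cluster is performed on the unwrapped adapter and therefore not
    counted — call counts refer to evaluations of modified matrices.
    """

    def __init__(self, inner: ClassifierAdapter):
        self.inner = inner
        self.cell_types = tuple(inner.cell_types)
        self.stochastic = inner.stochastic
        self.calls = 0

    def classify(self, matrix, labeling, target) -> ClassifierOutput:
        self.calls += 1
        return self.inner.classify(matrix, labeling, target)

    def reset(self) -> None:
        self.calls = 0


class FunctionAdapter(ClassifierAdapter):
    """Wrap a plain callable ``f(matrix, labeling, target) -> ClassifierOutput``."""

    def __init__(
        self,
        fn: Callable[[ExpressionMatrix, ClusterLabeling, str], ClassifierOutput],
        cell_types: Sequence[str],
        stochastic: bool = False,
    ):
        self._fn = fn
        self.cell_types = tuple(cell_types)
        self.stochastic = stochastic

    def classify(self, matrix, labeling, target) -> ClassifierOutput:
        return self._fn(matrix, labeling, target)
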