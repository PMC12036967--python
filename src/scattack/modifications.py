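"""Gene-expression modification operators applied by every attack.

A modification rewrites the expression of a chosen gene set inside the target
cluster only, emulating events from plausible biology to outright data
corruption:

* ``perc1`` / ``perc99`` — replace values by the gene's 1st / 99th percentile
  (simulated inactivation / activation);
* ``decile-N`` / ``decile+N`` — shift each value down/up the gene's empirical
  distribution by N tenths of quantile rank (gradual, synchronized
  de/up-regulation; N = 10 saturates at the gene minimum/maximum);
* ``random`` — i.i.d. uniform noise between the gene's min and max;
* ``aberrant+`` / ``aberrant-`` — extreme outliers at plus/minus 1e5 times the
  dataset maximum (technical or processing errors);
* ``custom`` — any caller-supplied transform of the targeted submatrix, e.g.
  the :func:`dropout_custom` helper.

All percentile/decile statistics are computed per gene over *all* cells of the
pristine matrix, once per attack run (the dataset maximum is global, and
cluster-local statistics would make perc99 a no-op for genes silent in the
target cluster).  Percentiles use linear interpolation between closest ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy import sparse as sp

from .data_model import ClusterLabeling, ExpressionMatrix

MOD_NAMES = (
    "perc1",
    "perc99",
    "decile_plus",
    "decile_minus",
    "random",
    "positive_aberrant",
    "negative_aberrant",
    "custom",
)

#: Stable CLI spellings of the modification operators.
CLI_NAMES = {
    "perc1": "perc1",
    "perc99": "perc99",
    "decile_plus": "decile+{n}",
    "decile_minus": "decile-{n}",
    "random": "random",
    "positive_aberrant": "aberrant+",
    "negative_aberrant": "aberrant-",
    "custom": "custom",
}

ABERRANT_FACTOR = 1e5


@dataclass(frozen=True)
class ModificationSpec:
    """A named, parameterized expression-perturbation operator."""

    name: str
    n: int | None = None
    seed: int | None = None
    custom_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.name not in MOD_NAMES:
            raise ValueError(f"unknown modification {self.name!r}; known: {MOD_NAMES}")
        decile = self.name in ("decile_plus", "decile_minus")
        if decile:
            if self.n is None or not (1 <= int(self.n) <= 10):
                raise ValueError("decile modifications need N in 1..10")
        elif self.n is not None:
            raise ValueError("N is only valid for decile modifications")
        if self.name == "random" and self.seed is None:
            raise ValueError("random modification needs a seed")
        if self.name != "random" and self.seed is not None:
            raise ValueError("seed is only valid for the random modification")
        if (self.custom_fn is None) == (self.name == "custom"):
            raise ValueError("custom_fn must be given exactly for custom modifications")

    def label(self) -> str:
        """Stable string used in CLI arguments and reports."""
        if self.name in ("decile_plus", "decile_minus"):
            return CLI_NAMES[self.name].format(n=self.n)
        return CLI_NAMES[self.name]

    @classmethod
    def from_string(cls, text: str, seed: int | None = None) -> "ModificationSpec":
        text = text.strip()
        if text in ("perc1", "perc99"):
            return cls(text)
        if text == "aberrant+":
            return cls("positive_aberrant")
        if text == "aberrant-":
            return cls("negative_aberrant")
        if text.startswith("decile+"):
            return cls("decile_plus", n=int(text[len("decile+"):]))
        if text.startswith("decile-"):
            return cls("decile_minus", n=int(text[len("decile-"):]))
        if text == "random":
            if seed is None:
                raise ValueError("random modification needs a seed")
            return cls("random", seed=seed)
        raise ValueError(f"cannot parse modification {text!r}")


@dataclass
class GeneStats:
    """Per-gene summary statistics of the pristine matrix.

    ``deciles`` holds the 11 quantile values q0..q10 per gene (q0 = min,
    q10 = max); ``dataset_max`` is the global maximum over all entries.
    """

    gene_ids: list[str]
    p01: np.ndarray
    p99: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    deciles: np.ndarray  # (n_genes, 11)
    dataset_max: float
    _index: dict | None = None

    def row(self, gene_id: str) -> int:
        if self._index is None:
            self._index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not present in GeneStats") from None


def compute_gene_stats(matrix: ExpressionMatrix) -> GeneStats:
    """Percentiles, extrema and decile grids per gene over all cells."""
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValueError("cannot compute gene statistics of an empty matrix")
    dense = matrix.dense()
    p01, p99 = np.percentile(dense, [1, 99], axis=1)
    deciles = np.percentile(dense, np.arange(0, 101, 10), axis=1).T
    return GeneStats(
        gene_ids=list(matrix.gene_ids),
        p01=p01,
        p99=p99,
        minimum=dense.min(axis=1),
        maximum=dense.max(axis=1),
        deciles=deciles,
        dataset_max=float(dense.max()),
    )


def dropout_custom(p: float, seed: int) -> ModificationSpec:
    """Custom modification zeroing each targeted entry with probability ``p``.

    Mimics the dropout artefact of single-cell protocols; deterministic given
    the seed (a fresh generator is created on every application, so applying
    the same spec twice yields identical matrices).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"dropout probability must be in [0, 1], got {p}")

    def _dropout(sub: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(seed)
        out = sub.copy()
        out[rng.random(sub.shape) < p] = 0.0
        return out

    return ModificationSpec("custom", custom_fn=_dropout)


def _modified_submatrix(
    matrix: ExpressionMatrix,
    gene_rows: np.ndarray,
    sub: np.ndarray,
    spec: ModificationSpec,
    stats: GeneStats,
    stat_rows: np.ndarray,
) -> np.ndarray:
    if spec.name == "perc1":
        return np.broadcast_to(stats.p01[stat_rows][:, None], sub.shape).copy()
    if spec.name == "perc99":
        return np.broadcast_to(stats.p99[stat_rows][:, None], sub.shape).copy()
    if spec.name in ("positive_aberrant", "negative_aberrant"):
        if stats.dataset_max == 0:
            warnings.warn(
                "dataset maximum is 0: aberrant modification sets entries to 0",
                stacklevel=3,
            )
        sign = 1.0 if spec.name == "positive_aberrant" else -1.0
        return np.full(sub.shape, sign * ABERRANT_FACTOR * stats.dataset_max)
    if spec.name == "random":
        rng = np.random.default_rng(spec.seed)
        lo = stats.minimum[stat_rows][:, None]
        hi = stats.maximum[stat_rows][:, None]
        return lo + (hi - lo) * rng.random(sub.shape)
    if spec.name in ("decile_plus", "decile_minus"):
        shift = (spec.n / 10.0) * (1.0 if spec.name == "decile_plus" else -1.0)
        out = np.empty_like(sub, dtype=float)
        for k, j in enumerate(gene_rows):
            vals = np.sort(matrix.gene_values(matrix.gene_ids[j]))
            ncells = vals.size
            rank = np.searchsorted(vals, sub[k], side="right") / ncells
            out[k] = np.quantile(vals, np.clip(rank + shift, 0.0, 1.0))
        return out
    if spec.name == "custom":
        out = np.asarray(spec.custom_fn(sub.copy()), dtype=float)
        if out.shape != sub.shape:
            raise ValueError(
                f"custom modification changed submatrix shape {sub.shape} -> {out.shape}"
            )
        return out
    raise AssertionError(f"unhandled modification {spec.name}")


def apply_modification(
    matrix: ExpressionMatrix,
    labeling: ClusterLabeling,
    target: str,
    genes: Iterable[str],
    spec: ModificationSpec,
    stats: GeneStats | None = None,
) -> ExpressionMatrix:
    """Return a new matrix with ``spec`` applied to ``genes`` x target cells.

    Entries outside the (genes, target-cluster cells) block are bit-identical
    to the input; the input object is never mutated.  ``stats`` must come from
    the same *unmodified* matrix; it is computed on the fly when omitted.
    """
    genes = list(genes)
    gene_rows = np.array([matrix.gene_index(g) for g in genes], dtype=int)
    cells = labeling.cells_of(target)
    cell_cols = np.array([matrix.cell_index(c) for c in cells], dtype=int)
    if stats is None:
        stats = compute_gene_stats(matrix)
    stat_rows = np.array([stats.row(g) for g in genes], dtype=int)

    if gene_rows.size == 0:
        return matrix.copy()

    if matrix.is_sparse:
        sub = np.asarray(matrix.values[gene_rows][:, cell_cols].todense(), dtype=float)
    else:
        sub = matrix.values[np.ix_(gene_rows, cell_cols)].astype(float)
    new_sub = _modified_submatrix(matrix, gene_rows, sub, spec, stats, stat_rows)

    if matrix.is_sparse:
        out = sp.lil_matrix(matrix.values)
        out[np.ix_(gene_rows, cell_cols)] = new_sub
        values = out.tocsr()
    else:
        values = matrix.values.copy()
        values[np.ix_(gene_rows, cell_cols)] = new_sub
    return ExpressionMatrix(values, list(matrix.gene_ids), list(matrix.cell_ids))
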