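"""Synthetic datasets and contract-conformant reference classifiers.

Real attack surveys run against published classifiers on public atlases; this
module provides self-contained stand-ins so every attack is exercisable with
no download.  :func:`make_synthetic_dataset` emulates a log-normalized,
cluster-structured expression matrix: a low baseline with Gaussian noise,
per-cluster exclusive marker genes shifted upward, values floored at zero and
thinned by dropout.  The classifiers cover the behaviours the attacks need to
be tested against:

* :func:`make_marker_classifier` — marker-score voting (scType-like);
* :func:`make_linear_classifier` — linear per-cell scorer with known weights,
  giving a closed-form gradient oracle for CGD tests;
* :func:`make_threshold_classifier` — flips on a single gene's cluster mean,
  the minimal single-gene-attackable model.

All generators and adapters are deterministic given their seed/parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    ClassifierAdapter,
    ClassifierOutput,
    ClusterLabeling,
    ExpressionMatrix,
    argmax_predictions,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic expression matrix.

    Defaults sketch a small but realistic log-normalized single-cell dataset:
    a baseline expression of 1.0 with noise_sd 0.5, clear markers
    (marker_effect 2.0 per cluster-exclusive gene) and a 30% dropout rate.
    """

    n_genes: int = 2000
    n_clusters: int = 3
    cells_per_cluster: int = 50
    markers_per_cluster: int = 5
    marker_effect: float = 2.0
    base_expression: float = 1.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_clusters", "cells_per_cluster", "markers_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_genes < self.n_clusters * self.markers_per_cluster:
            raise ValueError("n_genes must fit n_clusters * markers_per_cluster markers")


def make_synthetic_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ClusterLabeling, dict[str, list[str]]]:
    """Cluster-structured matrix, labeling, and the planted marker truth."""
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_clusters * spec.cells_per_cluster
    gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    cell_ids = [f"c{i + 1:05d}" for i in range(n_cells)]
    cluster_names = [f"clust{k + 1}" for k in range(spec.n_clusters)]

    marker_rows = rng.choice(
        spec.n_genes, spec.n_clusters * spec.markers_per_cluster, replace=False
    )
    marker_map = {
        cluster_names[k]: sorted(
            gene_ids[j]
            for j in marker_rows[
                k * spec.markers_per_cluster : (k + 1) * spec.markers_per_cluster
            ]
        )
        for k in range(spec.n_clusters)
    }

    values = rng.normal(spec.base_expression, spec.noise_sd, (spec.n_genes, n_cells))
    assignment: dict[str, str] = {}
    for k, name in enumerate(cluster_names):
        cols = slice(k * spec.cells_per_cluster, (k + 1) * spec.cells_per_cluster)
        rows = marker_rows[k * spec.markers_per_cluster : (k + 1) * spec.markers_per_cluster]
        values[np.ix_(rows, np.arange(n_cells)[cols])] += spec.marker_effect
        for c in cell_ids[cols]:
            assignment[c] = name
    np.maximum(values, 0.0, out=values)
    if spec.dropout_rate > 0:
        values[rng.random(values.shape) < spec.dropout_rate] = 0.0

    matrix = ExpressionMatrix(values, gene_ids, cell_ids)
    return matrix, ClusterLabeling(assignment), marker_map


class _ScoreAdapter(ClassifierAdapter):
    """Shared plumbing: per-cell scores -> argmax predictions -> majority vote."""

    def _score_matrix(self, matrix: ExpressionMatrix) -> np.ndarray:
        raise NotImplementedError

    def classify(self, matrix, labeling, target) -> ClassifierOutput:
        scores = pd.DataFrame(
            self._score_matrix(matrix), index=matrix.cell_ids, columns=list(self.cell_types)
        )
        preds = argmax_predictions(scores)
        cluster_cells = labeling.cells_of(target)
        votes = preds.loc[cluster_cells]
        counts = {k: int((votes == k).sum()) for k in self.cell_types}
        winner = max(self.cell_types, key=lambda k: (counts[k], -self.cell_types.index(k)))
        return ClassifierOutput(
            cluster_prediction=winner,
            cluster_score=counts[winner] / len(cluster_cells),
            cell_scores=scores,
            cell_predictions=preds,
        )


class MarkerClassifier(_ScoreAdapter):
    """Score each cell type by the mean expression of its marker genes."""

    def __init__(self, marker_map: dict[str, list[str]]):
        if not marker_map or any(not v for v in marker_map.values()):
            raise ValueError("marker_map needs a non-empty gene list per cell type")
        self.marker_map = {k: list(v) for k, v in marker_map.items()}
        self.cell_types = tuple(marker_map)

    def _score_matrix(self, matrix):
        dense = matrix.dense()
        cols = []
        for ctype in self.cell_types:
            rows = [matrix.gene_index(g) for g in self.marker_map[ctype]]
            cols.append(dense[rows, :].mean(axis=0))
        return np.column_stack(cols)


class LinearClassifier(_ScoreAdapter):
    """Raw linear per-cell scores ``w_k . x_i`` with a known weight matrix.

    The exposed ``weights`` (cell types x genes) make the finite-difference
    gradient analytically checkable: probing gene j changes the score of type
    k by exactly ``w_kj * (alpha*|x_j| + eps)``.
    """

    def __init__(self, weights: pd.DataFrame):
        if not np.all(np.isfinite(weights.to_numpy())):
            raise ValueError("weights must be finite")
        self.weights = weights.astype(float)
        self.cell_types = tuple(weights.index.astype(str))

    def _score_matrix(self, matrix):
        rows = [matrix.gene_index(g) for g in self.weights.columns]
        sub = matrix.dense()[rows, :]  # genes x cells
        return (self.weights.to_numpy() @ sub).T  # cells x types


class ThresholdClassifier(ClassifierAdapter):
    """Predict ``flip_label`` iff the cluster mean of one gene exceeds a threshold.

    The minimal single-gene-attackable model: exactly one gene matters, and a
    modification flips the cluster iff it pushes that gene's within-cluster
    mean over the threshold.
    """

    def __init__(self, gene: str, threshold: float, base_label: str, flip_label: str):
        self.gene = gene
        self.threshold = float(threshold)
        self.cell_types = (base_label, flip_label)

    def classify(self, matrix, labeling, target) -> ClassifierOutput:
        expr = matrix.gene_values(self.gene)
        base_label, flip_label = self.cell_types
        scores = pd.DataFrame(
            {base_label: np.full(matrix.n_cells, self.threshold), flip_label: expr},
            index=matrix.cell_ids,
        )
        preds = argmax_predictions(scores)
        cells = labeling.cells_of(target)
        cols = [matrix.cell_index(c) for c in cells]
        mean = float(expr[cols].mean())
        prediction = flip_label if mean > self.threshold else base_label
        return ClassifierOutput(
            cluster_prediction=prediction,
            cluster_score=mean,
            cell_scores=scores,
            cell_predictions=preds,
        )


class ConstantClassifier(ClassifierAdapter):
    """Ignores the matrix entirely — the zero-sensitivity reference."""

    def __init__(self, label: str, cell_types: tuple[str, ...] | None = None):
        self.label = label
        self.cell_types = cell_types if cell_types is not None else (label, "other")
        if label not in self.cell_types:
            raise ValueError("label must be part of cell_types")

    def classify(self, matrix, labeling, target) -> ClassifierOutput:
        scores = np.zeros((matrix.n_cells, len(self.cell_types)))
        scores[:, self.cell_types.index(self.label)] = 1.0
        df = pd.DataFrame(scores, index=matrix.cell_ids, columns=list(self.cell_types))
        return ClassifierOutput(
            cluster_prediction=self.label,
            cluster_score=1.0,
            cell_scores=df,
            cell_predictions=argmax_predictions(df),
        )


def make_marker_classifier(marker_map: dict[str, list[str]]) -> MarkerClassifier:
    return MarkerClassifier(marker_map)


def make_linear_classifier(weights: pd.DataFrame) -> LinearClassifier:
    return LinearClassifier(weights)


def make_threshold_classifier(
    gene: str, threshold: float, base_label: str, flip_label: str
) -> ThresholdClassifier:
    return ThresholdClassifier(gene, threshold, base_label, flip_label)


def make_constant_classifier(
    label: str, cell_types: tuple[str, ...] | None = None
) -> ConstantClassifier:
    return ConstantClassifier(label, cell_types)


def make_balanced_subset(
    matrix: ExpressionMatrix,
    labeling: ClusterLabeling,
    n_per_cluster: int = 100,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ClusterLabeling]:
    """Exactly ``n_per_cluster`` cells per cluster, bootstrapping small clusters.

    Clusters larger than the quota are subsampled without replacement;
    smaller clusters keep all originals and are topped up with bootstrap
    cells whose gene values are resampled independently per gene within the
    cluster (marginal bootstrap).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    dense = matrix.dense()
    col_of = {c: i for i, c in enumerate(matrix.cell_ids)}

    blocks: list[np.ndarray] = []
    new_cells: list[str] = []
    assignment: dict[str, str] = {}
    for label in labeling.labels:
        cells = labeling.cells_of(label)
        cols = np.array([col_of[c] for c in cells])
        if len(cells) >= n_per_cluster:
            pick = rng.choice(len(cells), n_per_cluster, replace=False)
            chosen = [cells[i] for i in pick]
            blocks.append(dense[:, cols[pick]])
            names = list(chosen)
        else:
            block = dense[:, cols]
            extra = n_per_cluster - len(cells)
            # marginal bootstrap: each gene resampled within the cluster
            boot = np.empty((matrix.n_genes, extra))
            for j in range(matrix.n_genes):
                boot[j] = rng.choice(block[j], size=extra, replace=True)
            blocks.append(np.concatenate([block, boot], axis=1))
            names = list(cells) + [f"{label}_bs{i + 1}" for i in range(extra)]
        for name in names:
            assignment[name] = label
        new_cells.extend(names)
    out = ExpressionMatrix(np.concatenate(blocks, axis=1), list(matrix.gene_ids), new_cells)
    return out, ClusterLabeling(assignment)
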