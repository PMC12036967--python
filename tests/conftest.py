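"""Shared fixtures: tiny handmade matrices and contract-conformant adapters."""

import numpy as np
import pandas as pd
import pytest

from scattack.data_model import (
    ClassifierAdapter,
    ClassifierOutput,
    ClusterLabeling,
    ExpressionMatrix,
    argmax_predictions,
)
from scattack.fixtures import SyntheticSpec, make_synthetic_dataset
from scattack.modifications import compute_gene_stats


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 cells with distinct, easy-to-track values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.0, 0.0, 5.0, 5.0],
            [2.0, 2.0, 2.0, 2.0],
        ]
    )
    return ExpressionMatrix(values, ["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def tiny_labeling():
    return ClusterLabeling({"c1": "L", "c2": "L", "c3": "R", "c4": "R"})


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 2-cluster synthetic dataset with clear planted markers."""
    spec = SyntheticSpec(
        n_genes=120,
        n_clusters=2,
        cells_per_cluster=15,
        markers_per_cluster=2,
        marker_effect=3.0,
        noise_sd=0.3,
        dropout_rate=0.1,
        seed=11,
    )
    matrix, labeling, markers = make_synthetic_dataset(spec)
    return matrix, labeling, markers


class SetLogicAdapter(ClassifierAdapter):
    """Flip iff predicate(set of genes modified in the target cluster) is true.

    A deterministic oracle-friendly classifier: it compares the presented
    matrix with the pristine one, collects genes whose target-cluster entries
    changed, and applies an arbitrary boolean predicate.  Monotone predicates
    give monotone classifiers.
    """

    def __init__(self, pristine, predicate, base_label="base", flip_label="flip"):
        self.pristine = pristine.dense().copy()
        self.gene_ids = list(pristine.gene_ids)
        self.predicate = predicate
        self.cell_types = (base_label, flip_label)

    def modified_genes(self, matrix, labeling, target):
        cols = [matrix.cell_index(c) for c in labeling.cells_of(target)]
        dense = matrix.dense()
        changed = (dense[:, cols] != self.pristine[:, cols]).any(axis=1)
        return {self.gene_ids[j] for j in np.flatnonzero(changed)}

    def classify(self, matrix, labeling, target):
        base_label, flip_label = self.cell_types
        flipped = bool(self.predicate(self.modified_genes(matrix, labeling, target)))
        scores = pd.DataFrame(
            {base_label: np.ones(matrix.n_cells), flip_label: np.zeros(matrix.n_cells)},
            index=matrix.cell_ids,
        )
        if flipped:
            scores[:] = scores.to_numpy()[:, ::-1]
        return ClassifierOutput(
            cluster_prediction=flip_label if flipped else base_label,
            cluster_score=1.0,
            cell_scores=scores,
            cell_predictions=argmax_predictions(scores),
        )


@pytest.fixture(scope="session")
def set_logic_factory(small_dataset):
    matrix, labeling, _ = small_dataset

    def factory(predicate):
        # base label matches the attacked cluster so the baseline is consistent
        return SetLogicAdapter(matrix, predicate, base_label="clust1")

    return factory


@pytest.fixture(scope="session")
def small_stats(small_dataset):
    matrix, _, _ = small_dataset
    return compute_gene_stats(matrix)
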