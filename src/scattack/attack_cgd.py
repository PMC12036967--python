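"""Cluster-based gradient descent (CGD): black-box finite-difference attack.

CGD perturbs a whole cluster one gene per step until the classifier's
second-most-likely cell type for the cluster (``ctype2``) overtakes the
current prediction (``ctype1``).  The model is a black box: the directional
information comes from finite differences.  For a gene j' and cell i with
expression x, the probe value is

    f(x) = (1 + alpha * sign(x)) * x + eps

and the per-cell-type gradient estimate is the difference of the classifier's
per-cell score vectors between probe and current state.  The accepted update
moves each cell along the estimated ascent direction of
score(ctype2) - score(ctype1):

    x  <-  (1 + alpha * sign(x) * sign(slope)) * x + eps * sign(slope)

with ``slope`` the per-cell difference of the two gradient components.  Cells
whose own top prediction already equals the cluster ctype2, or whose slope is
zero, are skipped.  ``alpha`` (multiplicative) and ``eps`` (additive) set both
probe magnitude and step size, i.e. the aggressiveness/perceptibility of the
attack; a pure-alpha attack cannot move zero-valued entries.

Probing uses one classification call per gene on a cluster-wide probe matrix
(all cluster cells probed simultaneously; each cell's row is read from the
per-cell score matrix), since the adapter contract returns per-cell scores in
a single call.  ctype1/ctype2 are refreshed after every accepted step; pass
``freeze_target=True`` to pin them to their step-0 values.  The *augmented*
mode keeps iterating through all provided genes after the prediction has
flipped, recording the prediction trajectory for accuracy/dynamics analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CallCountingAdapter,
    ClassifierAdapter,
    ClusterLabeling,
    ExpressionMatrix,
    cluster_score_vector,
)
from .gene_ranking import RankedGeneList, get_sign_genes


@dataclass(frozen=True)
class PerturbationParams:
    """Multiplicative (alpha) and additive (eps) step sizes, both >= 0."""

    alpha: float = 1.0
    eps: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.eps < 0:
            raise ValueError("alpha and eps must be non-negative")


@dataclass
class CGDStep:
    gene: str
    n_cells_updated: int
    ctype1: str
    ctype2: str
    gap_before: int
    gap_after: int
    cluster_label: str
    fraction_baseline: float


@dataclass
class CGDResult:
    baseline_label: str
    success: bool
    final_label: str
    adversarial_matrix: ExpressionMatrix
    steps: list[CGDStep]
    tested_genes: int
    modified_genes: int
    classifier_calls: int
    augmented: bool
    params: PerturbationParams


def _probe_values(x: np.ndarray, params: PerturbationParams) -> np.ndarray:
    return (1.0 + params.alpha * np.sign(x)) * x + params.eps


def finite_diff_gradient(
    matrix: ExpressionMatrix,
    cell_id: str,
    gene: str,
    adapter: ClassifierAdapter,
    labeling: ClusterLabeling,
    target: str,
    params: PerturbationParams,
) -> pd.Series:
    """Finite-difference score gradient of one cell w.r.t. one gene.

    Returns the per-cell-type score difference between the probed and the
    original matrix; the probe is discarded (the input is never mutated).
    """
    j = matrix.gene_index(gene)
    i = matrix.cell_index(cell_id)
    base = adapter.classify(matrix, labeling, target)
    probe = matrix.copy()
    if probe.is_sparse:
        probe.values = probe.values.tolil()
        probe.values[j, i] = _probe_values(np.array([probe.values[j, i]]), params)[0]
        probe.values = probe.values.tocsr()
    else:
        probe.values[j, i] = _probe_values(np.array([probe.values[j, i]]), params)[0]
    out = adapter.classify(probe, labeling, target)
    return out.cell_scores.loc[cell_id] - base.cell_scores.loc[cell_id]


def _resolve_gene_order(
    gene_order, matrix: ExpressionMatrix, labeling: ClusterLabeling
) -> list[str]:
    if gene_order is None:
        if len(labeling.labels) >= 2:
            return list(get_sign_genes(matrix, labeling, n_top=matrix.n_genes))
        return list(matrix.gene_ids)
    if isinstance(gene_order, RankedGeneList):
        return list(gene_order)
    return [str(g) for g in gene_order]


def adv_cgd(
    matrix: ExpressionMatrix,
    labeling: ClusterLabeling,
    target: str,
    adapter: ClassifierAdapter,
    params: PerturbationParams,
    gene_order: "RankedGeneList | Sequence[str] | None" = None,
    max_genes: int | None = None,
    augmented: bool = False,
    freeze_target: bool = False,
    clip_at_zero: bool = False,
) -> CGDResult:
    """Run the CGD attack on ``target``; never raises on failure to flip.

    ``gene_order`` defaults to the pairwise t-statistic ranking (or matrix
    order for single-cluster data); explicit lists cover alternative
    prioritizations (random, variance, ...).  ``max_genes`` caps the number of
    genes tested; exhausting it returns ``success=False`` with the full step
    log.  ``classifier_calls`` counts probe and re-classification calls, not
    the baseline classification.
    """
    if params.alpha == 0 and params.eps == 0:
        raise ValueError("alpha and eps cannot both be zero for an attack run")
    cells = labeling.cells_of(target)
    order = _resolve_gene_order(gene_order, matrix, labeling)
    for g in order:
        matrix.gene_index(g)
    if max_genes is None:
        max_genes = len(order)

    work = matrix.copy()
    if work.is_sparse:  # updates are dense by nature; work on a dense copy
        work = ExpressionMatrix(work.dense().copy(), list(work.gene_ids), list(work.cell_ids))
    cell_cols = np.array([work.cell_index(c) for c in cells], dtype=int)

    counter = CallCountingAdapter(adapter)
    current = adapter.classify(work, labeling, target)
    base_label = current.cluster_prediction
    if base_label != target:
        warnings.warn(
            f"baseline prediction {base_label!r} differs from cluster label "
            f"{target!r}; attacking the predicted label",
            stacklevel=2,
        )
    def _targets(output, score_vector):
        """ctype1/ctype2 of the cluster; ctype1 follows the adapter's own
        cluster prediction when it appears in the vocabulary (the prediction
        is authoritative; the count ranking resolves the runner-up)."""
        top = output.cluster_prediction
        if top not in score_vector.ranking:
            top = score_vector.ctype1
        runner = next((k for k in score_vector.ranking if k != top), None)
        return top, runner

    csv = cluster_score_vector(current, labeling, target)
    c1, c2 = _targets(current, csv)
    if c2 is None:
        raise ValueError("CGD needs a classifier with at least two cell types")

    steps: list[CGDStep] = []
    success = False
    tested = modified = 0

    if current.cluster_prediction == csv.ctype2:
        # degenerate: the cluster is already predicted as its runner-up type
        return CGDResult(
            baseline_label=base_label,
            success=True,
            final_label=current.cluster_prediction,
            adversarial_matrix=work,
            steps=steps,
            tested_genes=0,
            modified_genes=0,
            classifier_calls=counter.calls,
            augmented=augmented,
            params=params,
        )

    for gene in order[:max_genes]:
        tested += 1
        j = work.gene_index(gene)
        col = work.values[j, cell_cols].copy()

        # cluster-wide probe: one classification for all cells' finite differences
        work.values[j, cell_cols] = _probe_values(col, params)
        probe_out = counter.classify(work, labeling, target)
        work.values[j, cell_cols] = col  # restore

        est = (
            probe_out.cell_scores.loc[cells, [c1, c2]].to_numpy()
            - current.cell_scores.loc[cells, [c1, c2]].to_numpy()
        )
        slope = est[:, 1] - est[:, 0]
        own_top = current.cell_predictions.loc[cells].to_numpy()
        update = (slope != 0) & (own_top != c2)

        gap_before = csv.gap()
        n_updated = int(update.sum())
        if n_updated:
            s = np.sign(slope[update])
            x = col[update]
            new_x = (1.0 + params.alpha * np.sign(x) * s) * x + params.eps * s
            if clip_at_zero:
                new_x = np.maximum(new_x, 0.0)
            work.values[j, cell_cols[update]] = new_x
            modified += 1
            current = counter.classify(work, labeling, target)
            csv = cluster_score_vector(current, labeling, target)

        frac_base = float((current.cell_predictions.loc[cells] == base_label).mean())
        steps.append(
            CGDStep(
                gene=gene,
                n_cells_updated=n_updated,
                ctype1=c1,
                ctype2=c2,
                gap_before=gap_before,
                gap_after=csv.gap(),
                cluster_label=current.cluster_prediction,
                fraction_baseline=frac_base,
            )
        )
        if current.cluster_prediction != base_label:
            success = True
            if not augmented:
                break
        if not freeze_target:
            new_c1, new_c2 = _targets(current, csv)
            if new_c2 is not None:
                c1, c2 = new_c1, new_c2  # else keep the previous target

    return CGDResult(
        baseline_label=base_label,
        success=success,
        final_label=current.cluster_prediction,
        adversarial_matrix=work,
        steps=steps,
        tested_genes=tested,
        modified_genes=modified,
        classifier_calls=counter.calls,
        augmented=augmented,
        params=params,
    )


def prediction_dynamics(result: CGDResult) -> pd.DataFrame:
    """Per-tested-gene trajectory of an augmented CGD run.

    One row per tested gene: the fraction of cluster cells still predicted as
    the baseline type, and the cluster-level label at that point.
    """
    if not result.augmented:
        raise ValueError("prediction dynamics require an augmented CGD run")
    return pd.DataFrame(
        {
            "tested_genes": np.arange(1, len(result.steps) + 1),
            "gene": [s.gene for s in result.steps],
            "fraction_baseline": [s.fraction_baseline for s in result.steps],
            "cluster_label": [s.cluster_label for s in result.steps],
        }
    )
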