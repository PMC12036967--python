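"""Random-walk minimal-change attack and exhaustive grid attack.

The random walk mines a classifier for fortuitous vulnerabilities: draw a
random gene -> modification assignment over a user-chosen gene subset, and if
it flips the cluster's classification, greedily strip entries one by one (in a
re-shuffled order each sweep) as long as the reduced assignment still flips.
The fixpoint is 1-minimal: removing any single remaining entry no longer
flips.  The grid attack instead enumerates *every* assignment (each gene gets
one of the modifications or is left untouched) for fewer than ten genes, and
tabulates which combinations flip — its own exhaustive oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CallCountingAdapter, ClassifierAdapter, ClusterLabeling, ExpressionMatrix
from .modifications import GeneStats, ModificationSpec, apply_modification, compute_gene_stats

#: gene -> ModificationSpec; genes absent from the map stay untouched
GeneModAssignment = dict[str, ModificationSpec]

GRID_MAX_GENES = 9


@dataclass
class WalkResult:
    baseline_label: str
    success: bool
    assignment: GeneModAssignment
    induced_label: str | None
    trajectory: list[tuple[int, bool]]  # (assignment size, still flipping)
    classifier_calls: int


@dataclass
class GridResult:
    baseline_label: str
    table: pd.DataFrame  # assignment, n_genes, flips, induced_label
    classifier_calls: int


def apply_assignment(
    matrix: ExpressionMatrix,
    labeling: ClusterLabeling,
    target: str,
    assignment: GeneModAssignment,
    stats: GeneStats,
) -> ExpressionMatrix:
    """Apply a per-gene modification assignment (genes are disjoint per spec)."""
    groups: dict[ModificationSpec, list[str]] = {}
    for gene, spec in assignment.items():
        groups.setdefault(spec, []).append(gene)
    out = matrix
    for spec, genes in groups.items():
        out = apply_modification(out, labeling, target, genes, spec, stats)
    return out


def _baseline(matrix, labeling, target, adapter):
    out = adapter.classify(matrix, labeling, target)
    return out.cluster_prediction


def adv_random_walk_min_change(
    matrix: ExpressionMatrix,
    labeling: ClusterLabeling,
    target: str,
    adapter: ClassifierAdapter,
    genes: Sequence[str],
    mods: Sequence[ModificationSpec],
    seed: int,
    max_walk: int = 100,
) -> WalkResult:
    """Seeded random-walk search for a 1-minimal flipping assignment.

    ``max_walk`` is the total classifier-call budget: initial resampling and
    the reduction sweeps both draw from it.  If no initial assignment flips
    within the budget the result has ``success=False`` and
    ``classifier_calls == max_walk``.
    """
    genes = list(genes)
    mods = list(mods)
    if not genes or not mods:
        raise ValueError("random walk needs non-empty genes and mods")
    for g in genes:
        matrix.gene_index(g)
    base_label = _baseline(matrix, labeling, target, adapter)
    stats = compute_gene_stats(matrix)
    counter = CallCountingAdapter(adapter)
    rng = np.random.default_rng(seed)

    def flips(assignment: GeneModAssignment) -> tuple[bool, str]:
        modified = apply_assignment(matrix, labeling, target, assignment, stats)
        out = counter.classify(modified, labeling, target)
        return out.cluster_prediction != base_label, out.cluster_prediction

    # -- find a flipping starting assignment ---------------------------
    assignment: GeneModAssignment | None = None
    induced = None
    while counter.calls < max_walk:
        candidate = {g: mods[int(rng.integers(len(mods)))] for g in genes}
        hit, label = flips(candidate)
        if hit:
            assignment, induced = candidate, label
            break
    if assignment is None:
        return WalkResult(base_label, False, {}, None, [], counter.calls)

    # -- greedy reduction to a 1-minimal fixpoint -----------------------
    trajectory = [(len(assignment), True)]
    changed = True
    while changed and counter.calls < max_walk:
        changed = False
        for g in rng.permutation(sorted(assignment)):
            if counter.calls >= max_walk:
                break
            reduced = {k: v for k, v in assignment.items() if k != g}
            if not reduced:
                continue  # an empty assignment modifies nothing, cannot flip
            hit, label = flips(reduced)
            trajectory.append((len(reduced), hit))
            if hit:
                assignment, induced = reduced, label
                changed = True
    return WalkResult(base_label, True, assignment, induced, trajectory, counter.calls)


def adv_grid_min_change(
    matrix: ExpressionMatrix,
    labeling: ClusterLabeling,
    target: str,
    adapter: ClassifierAdapter,
    genes: Sequence[str],
    mods: Sequence[ModificationSpec],
) -> GridResult:
    """Exhaustively classify all (|mods|+1)^n - 1 non-empty assignments."""
    genes = list(genes)
    mods = list(mods)
    if len(genes) > GRID_MAX_GENES:
        raise ValueError(
            f"grid attack is combinatorial: at most {GRID_MAX_GENES} genes "
            f"(got {len(genes)}; (|mods|+1)^n would be "
            f"{(len(mods) + 1) ** len(genes)} classifications)"
        )
    if not genes or not mods:
        raise ValueError("grid attack needs non-empty genes and mods")
    for g in genes:
        matrix.gene_index(g)
    base_label = _baseline(matrix, labeling, target, adapter)
    stats = compute_gene_stats(matrix)
    counter = CallCountingAdapter(adapter)

    rows = []
    for choice in product([None] + mods, repeat=len(genes)):
        assignment = {g: m for g, m in zip(genes, choice) if m is not None}
        if not assignment:
            continue
        modified = apply_assignment(matrix, labeling, target, assignment, stats)
        out = counter.classify(modified, labeling, target)
        flip = out.cluster_prediction != base_label
        rows.append(
            {
                "assignment": "|".join(
                    f"{g}:{assignment[g].label()}" for g in genes if g in assignment
                ),
                "n_genes": len(assignment),
                "flips": flip,
                "induced_label": out.cluster_prediction if flip else None,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["n_genes", "assignment"], kind="stable")
        .reset_index(drop=True)
    )
    return GridResult(base_label, table, counter.calls)
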