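"""Rank genes by pairwise inter-cluster t-statistics (``get_sign_genes``).

For every unordered pair of clusters, genes are scored with the absolute
Welch (unequal-variance) two-sample t-statistic on their expression in the two
clusters.  The final ranking interleaves the per-pair rankings round-robin —
best unused gene of pair 1, pair 2, ..., then the second-best of each pair —
so that every cluster pair contributes discriminating genes near the top.
This list feeds SVM-style classifiers (e.g. the top 20 genes) and is the
default gene prioritization of the gradient-descent attack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import ClusterLabeling, ExpressionMatrix


@dataclass
class RankedGeneList:
    """Ordered genes plus, per emitted gene, the cluster pair that ranked it."""

    genes: list[str]
    provenance: pd.DataFrame  # columns: gene, cluster_a, cluster_b, t, pair_rank

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def get_sign_genes(
    matrix: ExpressionMatrix, labeling: ClusterLabeling, n_top: int
) -> RankedGeneList:
    """Top ``n_top`` genes interleaved across all cluster-pair rankings.

    Pairs where either side has fewer than two cells are skipped with a
    warning (the t-statistic is undefined there).  Zero-variance-in-both-
    groups genes get t = 0; ties in |t| break lexicographically on gene id,
    so the output is fully deterministic and invariant to cell order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    labels = labeling.labels
    if len(labels) < 2:
        raise ValueError("gene ranking needs at least two clusters")

    dense = matrix.dense()
    col_of = {c: i for i, c in enumerate(matrix.cell_ids)}
    cols = {
        lab: np.array([col_of[c] for c in labeling.cells_of(lab) if c in col_of])
        for lab in labels
    }

    gene_arr = np.array(matrix.gene_ids)
    pair_order: list[tuple[str, str]] = []
    pair_rankings: dict[tuple[str, str], np.ndarray] = {}
    pair_t: dict[tuple[str, str], np.ndarray] = {}
    for a, b in combinations(labels, 2):
        if len(cols[a]) < 2 or len(cols[b]) < 2:
            warnings.warn(
                f"cluster pair ({a!r}, {b!r}) skipped: fewer than 2 cells on one side",
                stacklevel=2,
            )
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t = sps.ttest_ind(
                dense[:, cols[a]], dense[:, cols[b]], axis=1, equal_var=False
            ).statistic
        t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
        # primary key: |t| descending; tie-break: gene id ascending
        order = np.lexsort((gene_arr, -np.abs(t)))
        pair_order.append((a, b))
        pair_rankings[(a, b)] = order
        pair_t[(a, b)] = t
    if not pair_order:
        raise ValueError("no cluster pair has >= 2 cells on both sides")

    emitted: list[str] = []
    seen: set[str] = set()
    rows = []
    pointers = {p: 0 for p in pair_order}
    while len(emitted) < min(n_top, matrix.n_genes):
        progressed = False
        for pair in pair_order:
            order = pair_rankings[pair]
            ptr = pointers[pair]
            while ptr < len(order) and gene_arr[order[ptr]] in seen:
                ptr += 1
            pointers[pair] = ptr
            if ptr >= len(order):
                continue
            j = order[ptr]
            gene = str(gene_arr[j])
            seen.add(gene)
            emitted.append(gene)
            rows.append(
                {
                    "gene": gene,
                    "cluster_a": pair[0],
                    "cluster_b": pair[1],
                    "t": float(pair_t[pair][j]),
                    "pair_rank": ptr + 1,
                }
            )
            pointers[pair] = ptr + 1
            progressed = True
            if len(emitted) >= n_top:
                break
        if not progressed:
            break
    return RankedGeneList(genes=emitted, provenance=pd.DataFrame(rows))
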