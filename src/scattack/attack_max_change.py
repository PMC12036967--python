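"""Max-change attack: modify as many genes as possible without flipping a cluster.

The attack greedily grows a *keep-set* of modifiable genes: the full gene list
is modified at once and, whenever the classification changes, the offending
candidate set is split in two and each half is retried in combination with the
keep-set accumulated so far.  Candidate sets at or below ``max_split_size``
that still flip are surrendered to the *signature* — the complement set of
untouchable genes that defines the cluster for this classifier.  A larger
``max_split_size`` stops recursion earlier, trading signature precision for
fewer classifier calls.  The final keep-set is re-verified with one wholesale
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .data_model import CallCountingAdapter, ClassifierAdapter, ClusterLabeling, ExpressionMatrix
from .modifications import GeneStats, ModificationSpec, apply_modification, compute_gene_stats


@dataclass
class MaxChangeResult:
    """Partition of the gene list into modifiable genes and the cluster signature."""

    baseline_label: str
    modifiable: list[str]
    signature: list[str]
    classifier_calls: int
    max_split_size: int
    verified: bool


def adv_max_change(
    matrix: ExpressionMatrix,
    labeling: ClusterLabeling,
    target: str,
    adapter: ClassifierAdapter,
    spec: ModificationSpec,
    max_split_size: int = 1,
    stats: GeneStats | None = None,
) -> MaxChangeResult:
    if max_split_size < 1:
        raise ValueError("max_split_size must be >= 1")
    labeling.cells_of(target)  # raises on unknown/empty cluster

    baseline = adapter.classify(matrix, labeling, target)
    base_label = baseline.cluster_prediction
    if base_label != target:
        warnings.warn(
            f"baseline prediction {base_label!r} differs from cluster label "
            f"{target!r}; preserving the predicted label",
            stacklevel=2,
        )
    if stats is None:
        stats = compute_gene_stats(matrix)
    counter = CallCountingAdapter(adapter)

    def unchanged(gene_subset: list[str]) -> bool:
        modified = apply_modification(matrix, labeling, target, gene_subset, spec, stats)
        out = counter.classify(modified, labeling, target)
        return out.cluster_prediction == base_label

    keep: list[str] = []
    signature: list[str] = []

    def process(candidate: list[str]) -> None:
        # candidate is always tested in combination with the accumulated keep-set
        if unchanged(keep + candidate):
            keep.extend(candidate)
            return
        if len(candidate) <= max_split_size:
            signature.extend(candidate)
            return
        mid = len(candidate) // 2
        process(candidate[:mid])
        process(candidate[mid:])

    process(list(matrix.gene_ids))

    verified = True
    if keep:
        verified = unchanged(keep)
        if not verified:
            warnings.warn(
                "final keep-set verification flipped the classification "
                "(non-monotone classifier); result is heuristic",
                stacklevel=2,
            )
    return MaxChangeResult(
        baseline_label=base_label,
        modifiable=keep,
        signature=signature,
        classifier_calls=counter.calls,
        max_split_size=max_split_size,
        verified=verified,
    )
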