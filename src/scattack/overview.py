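"""Whole-dataset vulnerability survey (quick, reduced-precision attack sweeps).

Testing every cluster against every modification at full precision is slow,
so the survey reruns the single-gene and max-change attacks in a coarse
configuration: the single-gene mode starts from 20 initial bins and halts its
dichotomy once flipping subsets reach 100 genes (reporting vulnerable
100-gene blocks instead of isolated genes), and the max-change recursion
stops at subsets of 100 genes.  The resulting cluster x modification grid
points out hazardous modification types and fragile clusters; flagged blocks
can then be refined with precise runs (``refine=True`` reruns the exact
single-gene search on flagged blocks only).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .attack_max_change import adv_max_change
from .attack_single_gene import adv_single_gene
from .data_model import ClassifierAdapter, ClusterLabeling, ExpressionMatrix
from .modifications import ModificationSpec, compute_gene_stats

QUICK_N_BINS = 20
QUICK_BLOCK_SIZE = 100
QUICK_MAX_SPLIT_SIZE = 100

MODES = ("single-gene", "max-change")


@dataclass
class SurveyReport:
    table: pd.DataFrame  # cluster, modification, mode, summary, detail, calls, error
    settings: dict
    total_classifier_calls: int

    def to_wide(self, mode: str) -> pd.DataFrame:
        """Cluster x modification grid of summaries for one attack mode."""
        sub = self.table[self.table["mode"] == mode]
        return sub.pivot(index="cluster", columns="modification", values="summary")


def survey(
    matrix: ExpressionMatrix,
    labeling: ClusterLabeling,
    adapter: ClassifierAdapter,
    mods: list[ModificationSpec],
    modes: tuple[str, ...] = MODES,
    n_bins: int = QUICK_N_BINS,
    block_size: int = QUICK_BLOCK_SIZE,
    max_split_size: int = QUICK_MAX_SPLIT_SIZE,
    refine: bool = False,
) -> SurveyReport:
    """Sweep clusters x modifications x attack modes in quick mode.

    Summaries: single-gene -> number of vulnerable units (isolated genes plus
    flagged blocks; with ``refine`` blocks are re-searched precisely and the
    count is in genes); max-change -> signature length.  Attack errors are
    recorded per grid cell and the sweep continues.
    """
    unknown = set(modes) - set(MODES)
    if unknown:
        raise ValueError(f"unknown attack modes: {sorted(unknown)}")
    stats = compute_gene_stats(matrix)
    rows = []
    total_calls = 0
    for cluster in labeling.labels:
        for spec in mods:
            for mode in modes:
                row = {
                    "cluster": cluster,
                    "modification": spec.label(),
                    "mode": mode,
                    "summary": None,
                    "detail": None,
                    "classifier_calls": 0,
                    "error": None,
                }
                try:
                    if mode == "single-gene":
                        res = adv_single_gene(
                            matrix, labeling, cluster, adapter, spec,
                            n_bins=n_bins, stats=stats, block_size=block_size,
                        )
                        calls = res.classifier_calls
                        hits = list(res.hits)
                        blocks = list(res.vulnerable_blocks)
                        if refine and blocks:
                            refined_blocks = []
                            for block_genes, _label in blocks:
                                fine = adv_single_gene(
                                    matrix, labeling, cluster, adapter, spec,
                                    n_bins=1, genes=list(block_genes),
                                    stats=stats, block_size=1,
                                )
                                calls += fine.classifier_calls
                                hits.extend(fine.hits)
                                refined_blocks.extend(fine.vulnerable_blocks)
                            blocks = refined_blocks
                        row["summary"] = len(hits) + len(blocks)
                        row["detail"] = {
                            "hits": hits,
                            "vulnerable_blocks": [list(b) for b, _ in blocks],
                        }
                        row["classifier_calls"] = calls
                    else:
                        res = adv_max_change(
                            matrix, labeling, cluster, adapter, spec,
                            max_split_size=max_split_size, stats=stats,
                        )
                        row["summary"] = len(res.signature)
                        row["detail"] = {"signature": list(res.signature)}
                        row["classifier_calls"] = res.classifier_calls
                except Exception as exc:  # keep sweeping on per-cell failures
                    row["error"] = f"{type(exc).__name__}: {exc}"
                total_calls += row["classifier_calls"]
                rows.append(row)
    settings = {
        "n_bins": n_bins,
        "block_size": block_size,
        "max_split_size": max_split_size,
        "refine": refine,
        "modes": list(modes),
    }
    return SurveyReport(pd.DataFrame(rows), settings, total_calls)
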