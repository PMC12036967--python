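"""CGD: finite-difference estimates vs closed form, attack behaviour, dynamics."""

import numpy as np
import pandas as pd
import pytest

from scattack.attack_cgd import (
    PerturbationParams,
    adv_cgd,
    finite_diff_gradient,
    prediction_dynamics,
)
from scattack.data_model import (
    ClassifierOutput,
    ClusterLabeling,
    ExpressionMatrix,
    FunctionAdapter,
    argmax_predictions,
)
from scattack.fixtures import make_constant_classifier, make_linear_classifier


def _linear_fixture(sparse_weights=True, seed=0, n_extra=12):
    """Two clusters A/B with a known-weight linear scorer.

    ``sparse_weights``: only a few genes carry weight (selective model);
    otherwise every gene separates the two types (unselective model).
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = 6, 6
    a_markers = [f"a{i}" for i in range(3)]
    b_markers = [f"b{i}" for i in range(6)]
    extra = [f"x{i}" for i in range(n_extra)]
    genes = a_markers + b_markers + extra
    cells = [f"c{i}" for i in range(n_a + n_b)]
    values = rng.uniform(0.9, 1.1, (len(genes), n_a + n_b))
    for j, g in enumerate(genes):
        if g in a_markers:
            values[j, :n_a] += 2.0
        if g in b_markers:
            values[j, n_a:] += 2.0
    matrix = ExpressionMatrix(values, genes, cells)
    labeling = ClusterLabeling({c: ("A" if i < n_a else "B") for i, c in enumerate(cells)})
    weights = pd.DataFrame(0.0, index=["A", "B"], columns=genes)
    weights.loc["A", a_markers] = 1.0
    weights.loc["B", b_markers] = 1.0
    if not sparse_weights:
        weights.loc["A", extra] = 0.05
        weights.loc["B", extra] = 0.20  # every gene separates the types
    return matrix, labeling, weights


class TestFiniteDifference:
    def test_constant_classifier_gives_zero_vector(self, small_dataset):
        matrix, labeling, _ = small_dataset
        adapter = make_constant_classifier("clust1")
        est = finite_diff_gradient(
            matrix, matrix.cell_ids[0], matrix.gene_ids[0], adapter, labeling,
            "clust1", PerturbationParams(alpha=1.0, eps=1.0),
        )
        assert (est == 0).all()

    def test_identity_perturbation_gives_zero_vector(self):
        matrix, labeling, weights = _linear_fixture()
        adapter = make_linear_classifier(weights)
        est = finite_diff_gradient(
            matrix, "c0", "a0", adapter, labeling, "A",
            PerturbationParams(alpha=0.0, eps=0.0),
        )
        assert (est == 0).all()

    @pytest.mark.parametrize("alpha,eps", [(0.0, 1.0), (0.5, 0.0), (0.7, 0.3)])
    def test_linear_scorer_matches_closed_form(self, alpha, eps):
        # oracle: probing gene j moves score_k by exactly w_kj * (alpha*|x| + eps)
        matrix, labeling, weights = _linear_fixture()
        adapter = make_linear_classifier(weights)
        params = PerturbationParams(alpha=alpha, eps=eps)
        for cell, gene in [("c0", "a1"), ("c7", "b2"), ("c3", "x5")]:
            x = matrix.gene_values(gene)[matrix.cell_index(cell)]
            est = finite_diff_gradient(matrix, cell, gene, adapter, labeling, "A", params)
            expected = weights[gene] * (alpha * abs(x) + eps)
            assert np.allclose(est.to_numpy(), expected.to_numpy(), atol=1e-9)

    def test_probe_does_not_mutate_matrix(self):
        matrix, labeling, weights = _linear_fixture()
        before = matrix.dense().copy()
        adapter = make_linear_classifier(weights)
        finite_diff_gradient(matrix, "c0", "a0", adapter, labeling, "A",
                             PerturbationParams(1.0, 1.0))
        assert np.array_equal(matrix.dense(), before)


def _greedy_oracle(matrix, labeling, target, weights, params, order):
    """Closed-form replay of the attack on a linear scorer (no classifier calls)."""
    w = weights.to_numpy()
    types = list(weights.index)
    cols = [matrix.cell_index(c) for c in labeling.cells_of(target)]
    x = matrix.dense()[:, cols].copy()
    scores = w @ x  # types x cells
    preds = scores.argmax(axis=0)
    counts = np.bincount(preds, minlength=len(types))
    c1, c2 = np.argsort(-counts, kind="stable")[:2]
    base = c1
    modified = []
    for gene in order:
        j = list(matrix.gene_ids).index(gene)
        slope = (w[c2, j] - w[c1, j]) * (params.alpha * np.abs(x[j]) + params.eps)
        own_top = (w @ x).argmax(axis=0)
        upd = (slope != 0) & (own_top != c2)
        if upd.any():
            s = np.sign(slope[upd])
            x[j, upd] = (1 + params.alpha * np.sign(x[j, upd]) * s) * x[j, upd] \
                + params.eps * s
            modified.append(gene)
            scores = w @ x
            preds = scores.argmax(axis=0)
            counts = np.bincount(preds, minlength=len(types))
            winner = counts.argmax()
            if winner != base:
                return modified, True
            c1, c2 = np.argsort(-counts, kind="stable")[:2]
    return modified, False


class TestAttack:
    def test_success_matches_greedy_closed_form_oracle(self):
        matrix, labeling, weights = _linear_fixture()
        adapter = make_linear_classifier(weights)
        params = PerturbationParams(alpha=0.0, eps=1.0)
        order = list(matrix.gene_ids)
        res = adv_cgd(matrix, labeling, "A", adapter, params, gene_order=order)
        assert res.success
        assert res.final_label == "B"
        oracle_modified, oracle_success = _greedy_oracle(
            matrix, labeling, "A", weights, params, order
        )
        assert oracle_success
        assert res.modified_genes == len(oracle_modified)
        # every modified gene carries a nonzero weight difference
        diff = (weights.loc["B"] - weights.loc["A"]).abs()
        for step in res.steps:
            if step.n_cells_updated:
                assert diff[step.gene] > 0

    def test_insensitive_classifier_skips_everything(self, small_dataset):
        matrix, labeling, _ = small_dataset
        adapter = make_constant_classifier("clust1")
        res = adv_cgd(
            matrix, labeling, "clust1", adapter, PerturbationParams(1.0, 1.0),
            gene_order=matrix.gene_ids[:30], max_genes=20,
        )
        assert not res.success
        assert res.modified_genes == 0
        assert res.tested_genes == 20
        assert res.classifier_calls == 20  # one probe per gene, no re-classifications

    def test_already_predicted_as_runner_up_succeeds_immediately(self):
        matrix, labeling, weights = _linear_fixture()

        def classify(m, lab, target):
            scores = pd.DataFrame(
                {"A": np.ones(m.n_cells), "B": np.zeros(m.n_cells)}, index=m.cell_ids
            )
            # per-cell argmax says A, but the adapter's cluster call says B
            return ClassifierOutput("B", 1.0, scores, argmax_predictions(scores))

        adapter = FunctionAdapter(classify, ("A", "B"))
        with pytest.warns(UserWarning, match="differs from cluster label"):
            res = adv_cgd(matrix, labeling, "A", adapter, PerturbationParams(1.0, 1.0))
        assert res.success and res.modified_genes == 0 and res.steps == []

    def test_pure_multiplicative_attack_cannot_move_zeros(self):
        matrix, labeling, weights = _linear_fixture()
        zero_gene = "b0"
        j = matrix.gene_index(zero_gene)
        matrix.values[j, :] = 0.0
        adapter = make_linear_classifier(weights)
        res = adv_cgd(
            matrix, labeling, "A", adapter, PerturbationParams(alpha=1.0, eps=0.0),
            gene_order=[zero_gene], max_genes=1,
        )
        assert not res.success
        assert np.all(res.adversarial_matrix.values[j, :] == 0.0)

    def test_update_direction_matches_analytic_ascent(self):
        matrix, labeling, weights = _linear_fixture()
        adapter = make_linear_classifier(weights)
        params = PerturbationParams(alpha=0.3, eps=0.5)
        res = adv_cgd(matrix, labeling, "A", adapter, params,
                      gene_order=list(matrix.gene_ids))
        cols = [matrix.cell_index(c) for c in labeling.cells_of("A")]
        before = matrix.dense()[:, cols]
        after = res.adversarial_matrix.dense()[:, cols]
        diff = weights.loc["B"] - weights.loc["A"]  # analytic d(score_B - score_A)/dx
        for j, gene in enumerate(matrix.gene_ids):
            moved = after[j] - before[j]
            if diff[gene] > 0:
                assert np.all(moved >= 0)
            elif diff[gene] < 0:
                assert np.all(moved <= 0)
            else:
                assert np.all(moved == 0)

    def test_stronger_steps_never_need_more_genes(self):
        matrix, labeling, weights = _linear_fixture()
        adapter = make_linear_classifier(weights)
        needed = []
        for eps in (0.5, 1.0, 2.0, 4.0):
            res = adv_cgd(matrix, labeling, "A", adapter,
                          PerturbationParams(alpha=0.0, eps=eps),
                          gene_order=list(matrix.gene_ids))
            assert res.success
            needed.append(res.modified_genes)
        assert needed == sorted(needed, reverse=True)

    def test_selective_vs_unselective_modified_tested_ratio(self):
        """Selective (sparse-weight) models skip genes; unselective ones do not."""
        params = PerturbationParams(alpha=0.0, eps=0.25)
        m1, lab1, w_sparse = _linear_fixture(sparse_weights=True)
        res_sparse = adv_cgd(m1, lab1, "A", make_linear_classifier(w_sparse), params,
                             gene_order=list(m1.gene_ids), augmented=True)
        m2, lab2, w_dense = _linear_fixture(sparse_weights=False)
        res_dense = adv_cgd(m2, lab2, "A", make_linear_classifier(w_dense), params,
                            gene_order=list(m2.gene_ids))
        ratio_sparse = res_sparse.modified_genes / res_sparse.tested_genes
        ratio_dense = res_dense.modified_genes / res_dense.tested_genes
        assert ratio_sparse < 1.0
        assert ratio_dense == 1.0
        assert ratio_sparse < ratio_dense

    def test_both_zero_parameters_rejected_for_attack(self):
        matrix, labeling, weights = _linear_fixture()
        with pytest.raises(ValueError):
            adv_cgd(matrix, labeling, "A", make_linear_classifier(weights),
                    PerturbationParams(0.0, 0.0))


class TestDynamics:
    def test_requires_augmented_run(self):
        matrix, labeling, weights = _linear_fixture()
        res = adv_cgd(matrix, labeling, "A", make_linear_classifier(weights),
                      PerturbationParams(0.0, 1.0), gene_order=list(matrix.gene_ids))
        with pytest.raises(ValueError):
            prediction_dynamics(res)

    def test_zero_sensitivity_fraction_constant_one(self, small_dataset):
        matrix, labeling, _ = small_dataset
        adapter = make_constant_classifier("clust1")
        res = adv_cgd(matrix, labeling, "clust1", adapter, PerturbationParams(1.0, 1.0),
                      gene_order=matrix.gene_ids[:10], augmented=True)
        table = prediction_dynamics(res)
        assert len(table) == 10
        assert (table["fraction_baseline"] == 1.0).all()

    def test_monotone_fixture_fraction_non_increasing_until_flip(self):
        matrix, labeling, weights = _linear_fixture()
        res = adv_cgd(matrix, labeling, "A", make_linear_classifier(weights),
                      PerturbationParams(alpha=0.0, eps=0.5),
                      gene_order=list(matrix.gene_ids), augmented=True)
        assert res.success
        table = prediction_dynamics(res)
        flip_rows = table.index[table["cluster_label"] != "A"]
        first_flip = flip_rows[0]
        upto = table.loc[:first_flip, "fraction_baseline"].to_numpy()
        assert np.all(np.diff(upto) <= 1e-12)
        assert table.loc[first_flip, "cluster_label"] == "B"
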