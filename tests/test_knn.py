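import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spenhance as sp
from spenhance.knn import (
    assign_folds,
    baseline_population_mean,
    cosine_distance_matrix,
    select_neighbors,
)
from spenhance.matrix import NORMALIZED_LOG, ExpressionMatrix


class TestCosineDistance:
    def test_identical_orthogonal_opposite(self):
        a = np.array([1.0, 2.0, 3.0])
        assert sp.cosine_distance(a, a) == pytest.approx(0.0)
        assert sp.cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert sp.cosine_distance(a, -a) == pytest.approx(2.0)

    def test_zero_norm_convention(self):
        assert sp.cosine_distance([0, 0], [1, 2]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sp.cosine_distance([1, 2], [1, 2, 3])

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((4, 6)), rng.standard_normal((5, 6))
        dm = cosine_distance_matrix(a, b)
        for i in range(4):
            for j in range(5):
                assert dm[i, j] == pytest.approx(sp.cosine_distance(a[i], b[j]))


class TestWeights:
    def test_hand_example(self):
        np.testing.assert_allclose(
            sp.compute_weights(np.array([0.2, 0.6])), [0.75, 0.25]
        )

    def test_equal_distances_exactly_uniform(self):
        for k in (2, 3, 7):
            w = sp.compute_weights(np.full(k, 0.37))
            assert np.all(w == 1.0 / k)

    def test_all_zero_distances_uniform(self):
        np.testing.assert_array_equal(sp.compute_weights(np.zeros(4)), np.full(4, 0.25))

    def test_single_neighbor(self):
        np.testing.assert_array_equal(sp.compute_weights(np.array([0.4])), [1.0])

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_weights(np.array([0.1, -0.2]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 50))
    def test_weights_sum_to_one(self, seed, k):
        d = np.random.default_rng(seed).random(k)
        w = sp.compute_weights(d)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0)


class TestSelectNeighbors:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            et = rng.standard_normal((20, 8))
            er = rng.standard_normal((40, 8))
            k = 7
            got = select_neighbors(et, er, k)
            for i in range(20):
                d = np.array([sp.cosine_distance(et[i], er[j]) for j in range(40)])
                order = sorted(range(40), key=lambda j: (d[j], j))[:k]
                expected = [j for j in order if d[j] < 1.0] or order
                assert got[i].neighbor_indices.tolist() == expected

    def test_identical_embedding_is_first_neighbor(self):
        rng = np.random.default_rng(2)
        er = rng.random((10, 5)) + 0.1
        et = er[4:5].copy()
        ns = select_neighbors(et, er, 3)[0]
        assert ns.neighbor_indices[0] == 4
        assert ns.distances[0] == pytest.approx(0.0, abs=1e-12)

    def test_distance_ties_prefer_lower_index(self):
        er = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])  # all colinear
        ns = select_neighbors(np.array([[5.0, 0.0]]), er, 2)[0]
        assert ns.neighbor_indices.tolist() == [0, 1]

    def test_k_exceeding_reference_rejected(self):
        with pytest.raises(ValueError):
            select_neighbors(np.ones((1, 2)), np.ones((3, 2)), 4)

    def test_fallback_when_all_similarities_nonpositive(self):
        et = np.array([[1.0, 0.0]])
        er = np.array([[-1.0, 0.0], [-2.0, 1.0], [0.0, -1.0]])
        ns = select_neighbors(et, er, 3)[0]
        assert ns.fallback
        np.testing.assert_allclose(ns.weights, np.full(3, 1 / 3))

    def test_weights_sum_to_one_after_filtering(self):
        rng = np.random.default_rng(3)
        et, er = rng.standard_normal((15, 6)), rng.standard_normal((60, 6))
        for ns in select_neighbors(et, er, 20):
            assert ns.weights.sum() == pytest.approx(1.0, abs=1e-12)


def ref_matrix(values, genes):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values, genes, [f"r{j}" for j in range(values.shape[1])], NORMALIZED_LOG
    )


class TestPredictCell:
    def test_weighted_dot_product(self):
        ref = ref_matrix([[4.0, 0.0]], ["gA"])
        ns = sp.NeighborSet("s0", np.array([0, 1]), np.array([0.2, 0.6]),
                            np.array([0.75, 0.25]))
        assert sp.predict_cell(ns, ref, ["gA"])[0] == pytest.approx(3.0)

    def test_identical_neighbors_reproduce_value(self):
        ref = ref_matrix([[2.5, 2.5, 2.5]], ["gA"])
        ns = sp.NeighborSet("s0", np.array([0, 1, 2]), np.zeros(3), np.full(3, 1 / 3))
        assert sp.predict_cell(ns, ref, ["gA"])[0] == pytest.approx(2.5)

    def test_unknown_gene_named_in_error(self):
        ref = ref_matrix([[1.0]], ["gA"])
        ns = sp.NeighborSet("s0", np.array([0]), np.zeros(1), np.ones(1))
        with pytest.raises(KeyError, match="gB"):
            sp.predict_cell(ns, ref, ["gB"])

    def test_prediction_within_neighbor_range(self):
        rng = np.random.default_rng(4)
        ref = ref_matrix(rng.random((5, 10)) * 8, [f"g{i}" for i in range(5)])
        idx = np.array([1, 4, 7])
        w = sp.compute_weights(rng.random(3))
        ns = sp.NeighborSet("s0", idx, rng.random(3), w)
        pred = sp.predict_cell(ns, ref, [f"g{i}" for i in range(5)])
        sub = ref.values[:, idx]
        assert np.all(pred >= sub.min(axis=1) - 1e-12)
        assert np.all(pred <= sub.max(axis=1) + 1e-12)


class TestEnsembleAndCv:
    def test_ensemble_of_identical_snapshots_equals_single(self, tiny_pair):
        pair, merged = tiny_pair
        cfg = sp.ModelConfig(latent_dim=16, epochs=5, batch_size=32, seed=0,
                             n_snapshots=5)
        pred5, model = sp.enhance(pair, pair.unique_genes[:4], cfg, k=10, seed=0)
        # replicate one snapshot five times
        model.snapshots = [model.snapshots[0]] * 5
        from spenhance.knn import _model_inputs, predict_ensemble
        spx, rfx = _model_inputs(pair, model.gene_order, pair.n_shared)
        single = predict_ensemble(model, spx, rfx, pair.reference,
                                  pair.unique_genes[:4],
                                  list(pair.spatial.cell_ids), k=10)
        model1 = sp.TrainedModel([model.snapshots[0]], model.loss_trace,
                                 model.gene_order, model.config)
        base = predict_ensemble(model1, spx, rfx, pair.reference,
                                pair.unique_genes[:4],
                                list(pair.spatial.cell_ids), k=10)
        np.testing.assert_allclose(single.values, base.values)
        assert single.n_snapshots_averaged == 5
        assert pred5.values.shape == (4, pair.n_spatial_cells)

    def test_fold_sizes_balanced_33_into_5(self):
        folds = assign_folds([f"g{i}" for i in range(33)], 5, seed=0)
        assert sorted((len(f) for f in folds), reverse=True) == [7, 7, 7, 6, 6]
        assert [len(f) for f in folds] == [7, 7, 7, 6, 6]  # larger folds first

    def test_folds_partition_genes(self):
        genes = [f"g{i}" for i in range(17)]
        folds = assign_folds(genes, 4, seed=3)
        flat = [g for f in folds for g in f]
        assert sorted(flat) == sorted(genes)
        assert len(flat) == len(set(flat))

    def test_fold_assignment_deterministic(self):
        genes = [f"g{i}" for i in range(20)]
        assert assign_folds(genes, 5, seed=11) == assign_folds(genes, 5, seed=11)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(["a", "b", "c"], 1, seed=0)

    def test_cv_predicts_every_shared_gene_once(self, tiny_pair):
        pair, _ = tiny_pair
        cfg = sp.ModelConfig(latent_dim=16, epochs=5, batch_size=32, seed=0)
        pred = sp.run_cv(pair, folds=4, seed=0, cfg=cfg, k=10)
        assert pred.gene_names == pair.shared_genes
        assert pred.values.shape == (pair.n_shared, pair.n_spatial_cells)
        assert np.all(np.isfinite(pred.values))
        assert np.all(pred.values >= 0)


def test_baseline_is_constant_per_gene():
    rng = np.random.default_rng(5)
    ref = ref_matrix(rng.random((3, 6)), ["a", "b", "c"])
    base = baseline_population_mean(ref, ["b", "c"], ["s0", "s1"])
    assert base.values.shape == (2, 2)
    np.testing.assert_allclose(base.values[:, 0], base.values[:, 1])
    np.testing.assert_allclose(base.values[0], ref.values[1].mean())
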