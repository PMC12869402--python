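"""NTF, similarity graph, diffusion embedding and topology statistics."""

import warnings

import numpy as np
import pytest

from popgeom.core import EncodingManifold, ResponseTensor
from popgeom.encoding import (
    EncodingModel,
    diffusion_embedding,
    encoding_tensor,
    neuron_similarity_graph,
    ntf_decompose,
    topology_stats,
)
from popgeom.errors import ValidationError
from popgeom.synthetic import (
    EnsembleConfig,
    PopulationConfig,
    make_stimulus_ensemble,
    simulate_population,
)


class TestEncodingTensor:
    def test_per_neuron_max_scales_to_one(self, default_tensor):
        tensor, _ = default_tensor
        arr, flags = encoding_tensor(tensor)
        assert not flags.any()
        np.testing.assert_allclose(arr.max(axis=(1, 2)), 1.0)

    def test_none_is_identity(self, default_tensor):
        tensor, _ = default_tensor
        arr, _ = encoding_tensor(tensor, normalization="none")
        np.testing.assert_array_equal(arr, tensor.activity)

    def test_all_zero_neuron_flagged_and_excluded(self, default_ensemble):
        cfg = PopulationConfig(neurons_per_class={"grating": 6}, noise_scale=0.0)
        tensor, _ = simulate_population(default_ensemble, cfg, seed=0)
        act = tensor.activity.copy()
        act[2] = 0.0
        tensor = ResponseTensor(act, tensor.bin_width, tensor.ensemble, tensor.neuron_ids)
        arr, flags = encoding_tensor(tensor)
        assert flags[2] and flags.sum() == 1
        assert np.all(arr[2] == 0)
        res = EncodingModel(tensor, rank=2, k_neighbors=2).fit()
        assert tensor.neuron_ids[2] not in res.manifold.neuron_ids
        assert res.excluded_neurons == [2]


class TestNTF:
    def test_exact_rank_one_recovery(self):
        """An exact nonnegative rank-1 tensor is recovered to machine error
        with factor cosine > 0.999 against the planted vectors."""
        rng = np.random.default_rng(0)
        a, b, c = (rng.uniform(0.1, 1, n) for n in (20, 15, 10))
        X = np.einsum("i,j,k->ijk", a, b, c)
        d = ntf_decompose(X, rank=1, n_restarts=3, seed=0)
        assert d.rel_error < 1e-6
        for rec, planted in [(d.neuron_factors, a), (d.condition_factors, b),
                             (d.time_factors, c)]:
            cos = abs(rec[:, 0] @ planted) / (
                np.linalg.norm(rec[:, 0]) * np.linalg.norm(planted)
            )
            assert cos > 0.999

    def test_objective_monotone_non_increasing(self, default_tensor):
        tensor, _ = default_tensor
        arr, _ = encoding_tensor(tensor)
        d = ntf_decompose(arr[:30], rank=3, n_restarts=2, seed=1)
        assert np.all(np.diff(d.trace) <= 1e-10)

    def test_rank3_factor_matching(self):
        """Well-separated planted rank-3 factors are recovered: greedy
        (Hungarian) matching achieves mean |cosine| > 0.95."""
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(5)
        # near-orthogonal sparse nonnegative factors
        A = np.zeros((30, 3))
        B = np.zeros((24, 3))
        C = np.zeros((18, 3))
        for r in range(3):
            A[10 * r:10 * (r + 1), r] = rng.uniform(0.5, 1, 10)
            B[8 * r:8 * (r + 1), r] = rng.uniform(0.5, 1, 8)
            C[6 * r:6 * (r + 1), r] = rng.uniform(0.5, 1, 6)
        X = np.einsum("ir,jr,kr->ijk", A, B, C)
        d = ntf_decompose(X, rank=3, n_restarts=5, seed=0)
        for rec, planted in [(d.neuron_factors, A), (d.condition_factors, B),
                             (d.time_factors, C)]:
            rn = rec / np.maximum(np.linalg.norm(rec, axis=0), 1e-12)
            pn = planted / np.linalg.norm(planted, axis=0)
            cos = np.abs(rn.T @ pn)  # recovered x planted
            rows, cols = linear_sum_assignment(-cos)
            assert cos[rows, cols].mean() > 0.95

    def test_rel_error_decreases_with_rank(self, default_tensor):
        tensor, _ = default_tensor
        arr, _ = encoding_tensor(tensor)
        errs = [
            ntf_decompose(arr[:40], rank=r, n_restarts=3, seed=2).rel_error
            for r in (1, 2, 3, 4)
        ]
        assert np.all(np.diff(errs) <= 1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            ntf_decompose(np.full((2, 2, 2), np.nan), 1)
        with pytest.raises(ValidationError):
            ntf_decompose(-np.ones((2, 2, 2)), 1)
        with pytest.warns(UserWarning, match="feasible rank"):
            ntf_decompose(np.ones((2, 2, 2)), rank=10, n_restarts=1, max_iter=5)


class TestSimilarityGraph:
    def test_identical_rows_have_unit_affinity(self):
        F = np.vstack([np.ones((2, 3)), np.eye(3)])
        with pytest.warns(UserWarning, match="duplicate"):
            W = neuron_similarity_graph(F, k=1)
        assert W[0, 1] == pytest.approx(1.0)
        # with a larger local scale the duplicates still have unit affinity
        assert neuron_similarity_graph(F, k=3)[0, 1] == pytest.approx(1.0)

    def test_far_groups_have_negligible_affinity(self):
        """Two groups separated by 10x the within-group scale: the kernel
        evaluated on the construction drops below 1e-4 across groups."""
        rng = np.random.default_rng(0)
        g1 = np.abs(rng.normal(0, 0.02, size=(10, 2))) + [1.0, 0.0]
        g2 = np.abs(rng.normal(0, 0.02, size=(10, 2))) + [0.0, 1.0]
        W = neuron_similarity_graph(np.vstack([g1, g2]), k=3)
        assert W[:10, 10:].max() < 1e-4

    def test_symmetric_unit_diagonal(self, default_tensor):
        tensor, _ = default_tensor
        rng = np.random.default_rng(1)
        F = rng.uniform(0, 1, size=(15, 4))
        W = neuron_similarity_graph(F, k=3)
        np.testing.assert_allclose(W, W.T)
        np.testing.assert_allclose(np.diag(W), 1.0)
        assert np.all(W >= 0)


class TestDiffusionEmbedding:
    def test_two_block_sign_separation(self):
        """Two disconnected cliques: the first coordinate is the centered
        block indicator (the exact lambda = 1 eigenvector orthogonal to the
        constant), separating the blocks by sign."""
        W = np.zeros((12, 12))
        W[:5, :5] = 1.0
        W[5:, 5:] = 1.0
        m = diffusion_embedding(W, n_dims=3)
        first = m.embedding[:, 0]
        assert len({np.sign(v) for v in first[:5]}) == 1
        assert len({np.sign(v) for v in first[5:]}) == 1
        assert np.sign(first[0]) != np.sign(first[5])
        # closed form: centered indicator of a 5/7 split, unit norm
        ind = np.where(np.arange(12) < 5, 1.0, 0.0)
        ind -= ind.mean()
        ind /= np.linalg.norm(ind)
        assert np.allclose(first, ind) or np.allclose(first, -ind)
        assert set(np.unique(m.component_labels)) == {0, 1}

    def test_scaling_invariance(self):
        rng = np.random.default_rng(2)
        F = rng.uniform(0, 1, size=(20, 3))
        W = neuron_similarity_graph(F, k=4)
        m1 = diffusion_embedding(W, 4)
        m2 = diffusion_embedding(7.3 * W, 4)
        np.testing.assert_allclose(m1.embedding, m2.embedding, atol=1e-10)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-12)

    def test_spectrum_ordering_and_range(self):
        rng = np.random.default_rng(3)
        W = neuron_similarity_graph(rng.uniform(0, 1, size=(25, 4)), k=5)
        m = diffusion_embedding(W, 6)
        assert np.all(np.diff(m.eigenvalues) <= 1e-12)
        assert np.all(m.eigenvalues > 0) and np.all(m.eigenvalues <= 1 + 1e-12)

    def test_asymmetric_affinity_rejected(self):
        W = np.eye(4)
        W[0, 1] = 0.5
        with pytest.raises(ValidationError, match="symmetric"):
            diffusion_embedding(W, 2)


class TestTopology:
    def _manifold(self, coords):
        n = coords.shape[0]
        return EncodingManifold(
            embedding=coords,
            neuron_factors=np.zeros((n, 1)),
            eigenvalues=np.array([1.0]),
            graph_degree=np.ones(n),
        )

    def test_single_blob_is_one_component(self):
        rng = np.random.default_rng(0)
        stats = topology_stats(self._manifold(rng.standard_normal((40, 3))))
        assert stats["n_components"] == 1

    def test_two_far_blobs_have_large_gap(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(0, 0.1, size=(20, 2)) + 10.0
        stats = topology_stats(self._manifold(np.vstack([a, b])))
        assert stats["gap_ratio"] > 5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            topology_stats(self._manifold(np.zeros((2, 2))))


class TestPipelineEquivariance:
    def test_neuron_permutation_permutes_embedding(self, default_ensemble):
        """Permuting input neurons permutes encoding-manifold rows identically
        (single data-driven restart keeps every stage equivariant)."""
        cfg = PopulationConfig(
            neurons_per_class={"grating": 10, "flow-1dot": 10}, noise_scale=0.02
        )
        tensor, _ = simulate_population(default_ensemble, cfg, seed=8)
        rng = np.random.default_rng(0)
        perm = rng.permutation(tensor.n_neurons)
        permuted = ResponseTensor(
            tensor.activity[perm], tensor.bin_width, tensor.ensemble,
            [tensor.neuron_ids[i] for i in perm],
        )
        r1 = EncodingModel(tensor, rank=3, n_restarts=1, k_neighbors=4).fit()
        r2 = EncodingModel(permuted, rank=3, n_restarts=1, k_neighbors=4).fit()
        id_to_row1 = {nid: r1.manifold.embedding[i] for i, nid in
                      enumerate(r1.manifold.neuron_ids)}
        for i, nid in enumerate(r2.manifold.neuron_ids):
            np.testing.assert_allclose(
                r2.manifold.embedding[i], id_to_row1[nid], atol=1e-6
            )

    def test_discrete_classes_recovered_perfectly(self, default_ensemble):
        """Noiseless disjoint classes with distinct temporal profiles: the
        embedding clusters exactly by planted class (ARI = 1)."""
        classes = {"grating": 15, "flow-1dot": 15, "flow-3dot": 15}
        cfg = PopulationConfig(
            neurons_per_class=classes,
            class_profiles={"grating": "transient", "flow-1dot": "sustained",
                            "flow-3dot": "periodic"},
            kappa_range=(0.0, 0.0),
            cross_affinity=0.0,
            noise_scale=0.0,
        )
        tensor, truth = simulate_population(default_ensemble, cfg, seed=4)
        res = EncodingModel(tensor, rank=3, k_neighbors=5).fit()
        stats = res.topology(labels=truth.planted_class)
        assert stats["label_ari"] == 1.0
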