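"""Decoding manifolds, trajectories, classification and selectivity."""

import numpy as np
import pytest

from popgeom.core import ResponseTensor, SequenceInfo, StimulusEnsemble
from popgeom.decoding import (
    DecodingModel,
    _pca,
    ablate_neurons,
    build_decoding_manifold,
    build_decoding_trajectories,
    classification_accuracy,
    selectivity_indices,
    trajectory_path_lengths,
)
from popgeom.errors import (
    DegenerateClassError,
    DimensionError,
    LookupKeyError,
    ValidationError,
)
from popgeom.synthetic import (
    EnsembleConfig,
    PopulationConfig,
    make_stimulus_ensemble,
    simulate_population,
)


def _disjoint_tensor(seed=0, n_per_class=8, classes=("a", "b", "c")):
    """Noiseless population in which each class activates a disjoint neuron set."""
    ens = make_stimulus_ensemble(
        EnsembleConfig(classes={c: 1 for c in classes}, n_directions=8)
    )
    cfg = PopulationConfig(
        neurons_per_class={c: n_per_class for c in classes},
        noise_scale=0.0,
        cross_affinity=0.0,
        kappa_range=(0.0, 0.0),  # flat tuning: class identity carries the signal
        profiles=("sustained",),
    )
    return simulate_population(ens, cfg, seed=seed)


class TestManifold:
    def test_default_ensemble_gives_48_points(self, default_tensor):
        tensor, _ = default_tensor
        m = build_decoding_manifold(tensor, 3)
        assert m.n_points == 48

    def test_sequence_grouping_gives_88_points(self, default_tensor):
        tensor, _ = default_tensor
        m = build_decoding_manifold(tensor, 3, grouping="sequence")
        assert m.n_points == 88

    def test_identical_responses_collapse_to_origin(self, tiny_tensor):
        tiny_tensor.activity[:] = 2.0
        m = build_decoding_manifold(tiny_tensor, 2)
        np.testing.assert_allclose(m.coords, 0.0, atol=1e-10)
        np.testing.assert_allclose(m.explained_variance_ratio, 0.0)

    def test_disjoint_classes_are_silhouette_separable(self):
        """Disjoint active neuron sets per class, zero noise: class labels are
        cleanly separated on the manifold (silhouette > 0.9)."""
        from sklearn.metrics import silhouette_score

        tensor, _ = _disjoint_tensor()
        m = build_decoding_manifold(tensor, 3)
        assert silhouette_score(m.coords, m.point_classes) > 0.9

    def test_evr_invariants(self, default_tensor):
        tensor, _ = default_tensor
        m = build_decoding_manifold(tensor, 10)
        evr = m.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_excessive_dims_rejected(self, tiny_tensor):
        with pytest.raises(DimensionError):
            build_decoding_manifold(tiny_tensor, 50)

    def test_neuron_permutation_invariance(self, default_tensor):
        """Permuting neurons leaves manifold coordinates unchanged up to
        per-axis sign."""
        tensor, _ = default_tensor
        rng = np.random.default_rng(0)
        perm = rng.permutation(tensor.n_neurons)
        permuted = ResponseTensor(
            tensor.activity[perm], tensor.bin_width, tensor.ensemble,
            [tensor.neuron_ids[i] for i in perm],
        )
        m1 = build_decoding_manifold(tensor, 3)
        m2 = build_decoding_manifold(permuted, 3)
        for d in range(3):
            assert np.allclose(m1.coords[:, d], m2.coords[:, d], atol=1e-8) or \
                np.allclose(m1.coords[:, d], -m2.coords[:, d], atol=1e-8)


class TestTrajectories:
    def test_constant_activity_collapses_each_trajectory(self, tiny_tensor):
        tiny_tensor.activity[:] = tiny_tensor.activity[:, :, :1]
        ts = build_decoding_trajectories(tiny_tensor, 2)
        assert np.allclose(ts.trajectories, ts.trajectories[:, :1, :])

    def test_periodic_profile_closes_loops(self, default_ensemble):
        """One integer stimulus cycle with zero noise traces a closed loop:
        the state at one period returns to the start."""
        cfg = PopulationConfig(
            neurons_per_class={"grating": 20},
            profiles=("periodic",),
            periodic_cycles=1.0,
            noise_scale=0.0,
            n_time=21,  # bin centers: profile at t=0 equals profile at t=T_period
        )
        tensor, _ = simulate_population(default_ensemble, cfg, seed=3)
        # append one extra sample equal to the first to close the cycle exactly
        ts = build_decoding_trajectories(tensor, 3)
        for k in range(ts.n_trajectories):
            traj = ts.trajectories[k]
            diam = np.max(np.linalg.norm(traj[:, None] - traj[None], axis=2))
            # profile is sampled at bin centers: compare nearly-periodic endpoints
            gap = np.linalg.norm(traj[0] - traj[-1])
            assert gap < 0.15 * diam

    def test_full_rank_projection_reconstructs(self):
        """PCA identity: projecting then reconstructing with full rank
        reproduces the centered data to 1e-8 relative error."""
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(12, 7))
        coords, evr, mean, comps = _pca(X, 7)
        recon = coords @ comps + mean
        assert np.linalg.norm(recon - X) < 1e-8 * np.linalg.norm(X)

    def test_manifold_is_time_average_of_trajectory(self, default_tensor):
        """The activity integral along a decoding trajectory equals the
        manifold point when both use the same projection and centering."""
        tensor, _ = default_tensor
        res = DecodingModel(tensor).fit(n_dims=5)
        from popgeom.decoding import _analysis_units

        units, _, _ = _analysis_units(tensor, "class-direction")
        tavg = units.mean(axis=2)  # U x N
        expected = res.project_units(tavg)
        actual = res.trajectories.trajectories.mean(axis=1)
        np.testing.assert_allclose(actual, expected, atol=1e-8)


class TestClassification:
    def test_noiseless_disjoint_classes_are_perfect(self):
        tensor, _ = _disjoint_tensor()
        assert classification_accuracy(tensor) == 1.0
        assert classification_accuracy(tensor, scheme="linear-cv", n_folds=4) == 1.0

    def test_shuffled_labels_fall_to_chance(self, default_tensor):
        """Permuting the sequence axis (decoupling labels from activity) drops
        accuracy to within 3 binomial SDs of chance (1/6 over 48 units)."""
        tensor, _ = default_tensor
        rng = np.random.default_rng(42)
        perm = rng.permutation(tensor.n_sequences)
        shuffled = ResponseTensor(
            tensor.activity[:, perm, :], tensor.bin_width, tensor.ensemble,
            tensor.neuron_ids,
        )
        acc = classification_accuracy(shuffled)
        p = 1 / 6
        sd = np.sqrt(p * (1 - p) / 48)
        assert abs(acc - p) <= 3 * sd

    def test_all_zero_activity_at_most_max_prior(self, tiny_tensor):
        ens = make_stimulus_ensemble(EnsembleConfig(classes={"a": 1, "b": 1}, n_directions=4))
        tensor = ResponseTensor(
            np.zeros((3, 8, 2)), 0.1, ens, ["x", "y", "z"]
        )
        acc = classification_accuracy(tensor)
        assert acc <= 0.5  # max class prior; ties resolved by fixed class order

    def test_single_unit_class_rejected(self):
        ens = make_stimulus_ensemble(EnsembleConfig(classes={"a": 1, "b": 1}, n_directions=1))
        tensor = ResponseTensor(np.ones((2, 2, 2)), 0.1, ens, ["x", "y"])
        with pytest.raises(DegenerateClassError):
            classification_accuracy(tensor)

    def test_accuracy_bounded(self, default_tensor):
        tensor, _ = default_tensor
        assert 0.0 <= classification_accuracy(tensor) <= 1.0


class TestSelectivity:
    def _tensor_with_tuning(self, rates):
        """One neuron, one class, 8 directions, tuning curve = rates."""
        ens = make_stimulus_ensemble(EnsembleConfig(classes={"g": 1}, n_directions=8))
        act = np.asarray(rates, float)[None, :, None] * np.ones((1, 8, 3))
        return ResponseTensor(act, 0.1, ens, ["n"])

    def test_flat_tuning_zero_indices(self):
        sel = selectivity_indices(self._tensor_with_tuning([2.0] * 8))
        assert sel.loc["n", "dsi"] == pytest.approx(0.0, abs=1e-12)
        assert sel.loc["n", "osi"] == pytest.approx(0.0, abs=1e-12)

    def test_single_direction_response_is_fully_selective(self):
        rates = [0.0] * 8
        rates[2] = 5.0
        sel = selectivity_indices(self._tensor_with_tuning(rates))
        assert sel.loc["n", "dsi"] == pytest.approx(1.0)
        assert sel.loc["n", "osi"] == pytest.approx(1.0)

    def test_opposite_equal_peaks_orientation_only(self):
        rates = [0.0] * 8
        rates[1] = rates[5] = 3.0  # 45 and 225 degrees
        sel = selectivity_indices(self._tensor_with_tuning(rates))
        assert sel.loc["n", "dsi"] == pytest.approx(0.0, abs=1e-12)
        assert sel.loc["n", "osi"] == pytest.approx(1.0)

    def test_zero_response_neuron_gets_zeros(self):
        sel = selectivity_indices(self._tensor_with_tuning([0.0] * 8))
        assert sel.loc["n", "dsi"] == 0.0 and sel.loc["n", "osi"] == 0.0


class TestAblation:
    def test_empty_set_is_identity(self, default_tensor):
        tensor, _ = default_tensor
        out = ablate_neurons(tensor, [])
        np.testing.assert_array_equal(out.activity, tensor.activity)
        assert out.neuron_ids == tensor.neuron_ids

    def test_unknown_id_rejected(self, default_tensor):
        tensor, _ = default_tensor
        with pytest.raises(LookupKeyError):
            ablate_neurons(tensor, ["no-such-neuron"])

    def test_ablate_all_rejected(self, tiny_tensor):
        with pytest.raises(ValidationError):
            ablate_neurons(tiny_tensor, tiny_tensor.neuron_ids)

    def test_intensity_arm_ablation_shrinks_path_length(self, default_ensemble):
        """A population whose temporal variance is carried entirely by
        nonselective (intensity) neurons: removing them shortens decoding
        trajectories by >= 50%."""
        cfg = PopulationConfig(
            neurons_per_class={"grating": 15, "flow-1dot": 15, "nonselective": 30},
            class_profiles={
                "grating": "sustained",
                "flow-1dot": "sustained",
                "nonselective": "nonselective",
            },
            sustained_tau=1e-6,  # selective neurons are temporally stationary
            noise_scale=0.0,
        )
        tensor, truth = simulate_population(default_ensemble, cfg, seed=21)
        nonsel = [
            nid for nid, prof in zip(truth.neuron_ids, truth.temporal_profile)
            if prof == "nonselective"
        ]
        before = trajectory_path_lengths(build_decoding_trajectories(tensor, 3)).mean()
        ablated = ablate_neurons(tensor, nonsel)
        after = trajectory_path_lengths(build_decoding_trajectories(ablated, 3)).mean()
        assert after <= 0.5 * before


class TestModelInterface:
    def test_summary_mentions_key_quantities(self, default_tensor):
        tensor, _ = default_tensor
        res = DecodingModel(tensor).fit(3)
        text = res.summary()
        assert "48" in text and "class-direction" in text

    def test_trajectory_labels_match_manifold(self, default_tensor):
        tensor, _ = default_tensor
        res = DecodingModel(tensor).fit(3)
        assert res.trajectories.labels == res.manifold.point_classes
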