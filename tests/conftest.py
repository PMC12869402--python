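"""Shared fixtures: small synthetic tensors and bundle sets."""

import numpy as np
import pytest

from popgeom.core import ResponseTensor, SequenceInfo, StimulusEnsemble
from popgeom.synthetic import (
    EnsembleConfig,
    PopulationConfig,
    make_stimulus_ensemble,
    simulate_population,
)


@pytest.fixture(scope="session")
def default_ensemble():
    return make_stimulus_ensemble()


@pytest.fixture(scope="session")
def default_tensor(default_ensemble):
    """Default synthetic population: 6 classes x 20 neurons, mild noise."""
    tensor, truth = simulate_population(default_ensemble, seed=12345)
    return tensor, truth


@pytest.fixture(scope="session")
def noiseless_tensor(default_ensemble):
    cfg = PopulationConfig(noise_scale=0.0)
    tensor, truth = simulate_population(default_ensemble, cfg, seed=777)
    return tensor, truth


@pytest.fixture
def tiny_tensor():
    """Hand-built 2-neuron, 1-class, 4-direction, 3-bin tensor."""
    seqs = [SequenceInfo(f"s{d}", "grating", "v0", float(d)) for d in (0, 90, 180, 270)]
    ens = StimulusEnsemble(seqs, n_directions=4, class_names=["grating"])
    act = np.arange(2 * 4 * 3, dtype=float).reshape(2, 4, 3)
    return ResponseTensor(act, bin_width=0.1, ensemble=ens, neuron_ids=["a", "b"])


def segment_intersections(trajs):
    """Brute-force 2-D oracle: count cross-class trajectory pairs whose
    polylines intersect, one event per intersecting segment pair."""

    def seg_int(p1, p2, q1, q2):
        def orient(a, b, c):
            v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

        return (
            orient(q1, q2, p1) != orient(q1, q2, p2)
            and orient(p1, p2, q1) != orient(p1, p2, q2)
        )

    X = trajs.trajectories
    labels = np.asarray(trajs.labels)
    K, T, _ = X.shape
    events = 0
    for i in range(K):
        for j in range(K):
            if j <= i or labels[i] == labels[j]:
                continue
            for t in range(T - 1):
                if seg_int(X[i, t, :2], X[i, t + 1, :2], X[j, t, :2], X[j, t + 1, :2]):
                    events += 1
    return events
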