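"""Decoding manifolds and trajectories: stimulus separability in neural space.

A decoding manifold embeds *stimulus conditions* (analysis units) in
PCA-reduced neural coordinates: each unit's feature vector is its
time-averaged population activity. Decoding trajectories instead treat every
time step of every unit as a separate point, so each condition traces a
time-indexed path in the reduced space; the time-average of a trajectory,
pushed through the same projection, is the condition's decoding-manifold
location in that space.

Analysis-unit grouping:

* ``"class-direction"`` (default) — average over within-class variants,
  giving classes x directions units (48 under the default ensemble);
* ``"sequence"`` — one unit per unique sequence (88 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DecodingManifold, ResponseTensor, TrajectorySet
from .errors import (
    DegenerateClassError,
    DimensionError,
    LookupKeyError,
    ValidationError,
)

__all__ = [
    "DecodingModel",
    "DecodingResults",
    "build_decoding_manifold",
    "build_decoding_trajectories",
    "classification_accuracy",
    "selectivity_indices",
    "ablate_neurons",
    "trajectory_path_lengths",
]

GROUPINGS = ("class-direction", "sequence")


def _analysis_units(tensor: ResponseTensor, grouping: str):
    """Group the sequence axis into analysis units.

    Returns ``(unit_activity, classes, directions)`` where ``unit_activity``
    has shape (U, N, T): the population time course of each unit (variant
    averaged for class-direction grouping).
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}; got {grouping!r}")
    ens = tensor.ensemble
    act = tensor.activity  # N x S x T
    if grouping == "sequence":
        units = np.moveaxis(act, 0, 1)  # S x N x T
        classes = [s.base_class for s in ens.sequences]
        directions = np.array([s.direction for s in ens.sequences])
        return units, classes, directions
    keys: list[tuple[str, float]] = []
    groups: dict[tuple[str, float], list[int]] = {}
    for i, s in enumerate(ens.sequences):
        key = (s.base_class, float(s.direction))
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(i)
    units = np.stack([act[:, groups[k], :].mean(axis=1) for k in keys])
    classes = [k[0] for k in keys]
    directions = np.array([k[1] for k in keys])
    return units, classes, directions


def _pca(X: np.ndarray, n_dims: int):
    """Deterministic PCA of row-vectors X: returns (coords, evr, mean, components).

    Zero-variance input maps every point to the origin with zero explained
    variance. Component signs follow the largest-magnitude-entry-positive
    convention.
    """
    P, N = X.shape
    if n_dims > min(P, N):
        raise DimensionError(
            f"n_dims={n_dims} exceeds the feasible rank min(P={P}, N={N})"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: each principal axis' largest-|.| loading is positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    total = float(np.sum(s**2))
    evr = s[:n_dims] ** 2 / total if total > 0 else np.zeros(n_dims)
    coords = U[:, :n_dims] * s[:n_dims]
    return coords, evr, mean, Vt[:n_dims]


def build_decoding_manifold(
    tensor: ResponseTensor, n_dims: int = 3, grouping: str = "class-direction"
) -> DecodingManifold:
    """PCA embedding of time-averaged analysis-unit activity.

    Each unit's coordinate vector is its stimulus-time-averaged population
    activity, mean-centered across units and projected onto the top
    ``n_dims`` principal axes. No per-neuron variance scaling is applied, so
    activity-magnitude structure is preserved.
    """
    units, classes, directions = _analysis_units(tensor, grouping)
    X = units.mean(axis=2)  # U x N
    coords, evr, _, _ = _pca(X, n_dims)
    return DecodingManifold(
        coords=coords,
        point_classes=classes,
        point_directions=directions,
        explained_variance_ratio=evr,
    )


def build_decoding_trajectories(
    tensor: ResponseTensor, n_dims: int = 3, grouping: str = "class-direction"
) -> TrajectorySet:
    """Decoding trajectories: each time step treated as a separate data point.

    The PCA is fitted on the pooled (unit, time) point cloud in neuron space,
    so the trajectory space is related to — but not identical with — the
    manifold space, which is fitted on time averages.
    """
    trajs, _ = _fit_trajectories(tensor, n_dims, grouping)
    return trajs


def _fit_trajectories(tensor: ResponseTensor, n_dims: int, grouping: str):
    units, classes, directions = _analysis_units(tensor, grouping)
    if tensor.n_time < 2:
        raise ValidationError("decoding trajectories need T >= 2")
    U_, N, T = units.shape
    pooled = np.moveaxis(units, 2, 1).reshape(U_ * T, N)  # (U*T) x N, unit-major
    coords, evr, mean, components = _pca(pooled, n_dims)
    trajs = coords.reshape(U_, T, n_dims)
    tset = TrajectorySet(
        trajectories=trajs,
        labels=classes,
        time_axis=tensor.time_axis,
        directions=directions,
    )
    projection = _Projection(mean=mean, components=components, evr=evr)
    return tset, projection


@dataclass
class _Projection:
    """Fitted affine PCA projection: x -> (x - mean) @ components.T."""

    mean: np.ndarray
    components: np.ndarray
    evr: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.components.T


def classification_accuracy(
    tensor: ResponseTensor,
    scheme: str = "nearest-centroid-loo",
    grouping: str = "class-direction",
    n_folds: int = 5,
    ridge: float = 1.0,
    seed: int = 0,
) -> float:
    """Base-class classification accuracy from time-averaged unit activity.

    ``nearest-centroid-loo``: leave-one-unit-out nearest class centroid
    (Euclidean; ties broken by lowest class index). ``linear-cv``: stratified
    k-fold regularised linear classifier (ridge).
    """
    units, classes, _ = _analysis_units(tensor, grouping)
    X = units.mean(axis=2)
    y = np.asarray(classes)
    class_order = list(dict.fromkeys(classes))
    counts = {c: int(np.sum(y == c)) for c in class_order}
    if len(class_order) < 2:
        raise DegenerateClassError("classification needs >= 2 classes")
    if min(counts.values()) < 2:
        small = [c for c, k in counts.items() if k < 2]
        raise DegenerateClassError(f"classes with < 2 units: {small}")

    if scheme == "nearest-centroid-loo":
        correct = 0
        sums = {c: X[y == c].sum(axis=0) for c in class_order}
        for i in range(len(y)):
            dists = []
            for c in class_order:
                n_c = counts[c] - (1 if y[i] == c else 0)
                cen = (sums[c] - (X[i] if y[i] == c else 0)) / n_c
                dists.append(np.linalg.norm(X[i] - cen))
            pred = class_order[int(np.argmin(dists))]  # argmin: first (lowest index) wins ties
            correct += pred == y[i]
        return correct / len(y)

    if scheme == "linear-cv":
        from sklearn.linear_model import RidgeClassifier
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        folds = min(n_folds, min(counts.values()))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        clf = RidgeClassifier(alpha=ridge)
        return float(np.mean(cross_val_score(clf, X, y, cv=cv)))

    raise ValueError(f"unknown scheme {scheme!r}")


def selectivity_indices(tensor: ResponseTensor) -> pd.DataFrame:
    """Per-neuron orientation and direction selectivity (circular variance).

    The tuning curve is the time-and-variant-averaged response per direction
    for the base class of maximal response. With direction angles theta_d and
    responses r_d:

        dsi = |sum_d r_d e^{i theta_d}|   / sum_d r_d
        osi = |sum_d r_d e^{2 i theta_d}| / sum_d r_d

    A neuron with zero total response gets osi = dsi = 0.
    """
    ens = tensor.ensemble
    grid = ens.direction_grid
    theta = np.deg2rad(grid)
    # mean response per (neuron, class, direction), averaged over time & variants
    curves = np.zeros((tensor.n_neurons, len(ens.class_names), len(grid)))
    cnt = np.zeros((len(ens.class_names), len(grid)))
    cls_pos = {c: i for i, c in enumerate(ens.class_names)}
    dir_pos = {round(float(d), 6): i for i, d in enumerate(grid)}
    tavg = tensor.activity.mean(axis=2)  # N x S
    for j, s in enumerate(ens.sequences):
        ci, di = cls_pos[s.base_class], dir_pos[round(float(s.direction), 6)]
        curves[:, ci, di] += tavg[:, j]
        cnt[ci, di] += 1
    curves /= np.maximum(cnt, 1)[None]

    best_class = curves.sum(axis=2).argmax(axis=1)
    r = curves[np.arange(tensor.n_neurons), best_class]  # N x D
    total = r.sum(axis=1)
    safe = np.maximum(total, 1e-300)
    dsi = np.abs((r * np.exp(1j * theta)).sum(axis=1)) / safe
    osi = np.abs((r * np.exp(2j * theta)).sum(axis=1)) / safe
    dsi = np.where(total > 0, dsi, 0.0)
    osi = np.where(total > 0, osi, 0.0)
    return pd.DataFrame(
        {"osi": osi, "dsi": dsi, "preferred_class": [ens.class_names[i] for i in best_class]},
        index=pd.Index(tensor.neuron_ids, name="neuron_id"),
    )


def ablate_neurons(tensor: ResponseTensor, neuron_ids) -> ResponseTensor:
    """Remove the given neurons; returns the tensor restricted to the rest."""
    drop = set(neuron_ids)
    unknown = drop - set(tensor.neuron_ids)
    if unknown:
        raise LookupKeyError(f"unknown neuron ids: {sorted(unknown)[:5]}")
    keep = [i for i, nid in enumerate(tensor.neuron_ids) if nid not in drop]
    if not keep:
        raise ValidationError("ablating every neuron leaves an empty tensor")
    return ResponseTensor(
        activity=tensor.activity[keep],
        bin_width=tensor.bin_width,
        ensemble=tensor.ensemble,
        neuron_ids=[tensor.neuron_ids[i] for i in keep],
    )


def trajectory_path_lengths(trajs: TrajectorySet) -> np.ndarray:
    """Euclidean path length of each trajectory."""
    steps = np.diff(trajs.trajectories, axis=1)
    return np.linalg.norm(steps, axis=2).sum(axis=1)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class DecodingModel:
    """Decoding analysis of a response tensor.

    Parameters
    ----------
    tensor : ResponseTensor
    grouping : {"class-direction", "sequence"}
        Analysis-unit definition (variant-averaged by default).

    ``fit(n_dims)`` computes the decoding manifold and the decoding
    trajectories and returns a :class:`DecodingResults`.
    """

    def __init__(self, tensor: ResponseTensor, grouping: str = "class-direction"):
        if grouping not in GROUPINGS:
            raise ValueError(f"grouping must be one of {GROUPINGS}")
        self.tensor = tensor
        self.grouping = grouping

    def fit(self, n_dims: int = 3) -> "DecodingResults":
        manifold = build_decoding_manifold(self.tensor, n_dims, self.grouping)
        trajectories, projection = _fit_trajectories(self.tensor, n_dims, self.grouping)
        return DecodingResults(self, n_dims, manifold, trajectories, projection)


class DecodingResults:
    """Fitted decoding manifold and trajectories with convenience metrics."""

    def __init__(self, model, n_dims, manifold, trajectories, projection):
        self.model = model
        self.n_dims = n_dims
        self.manifold: DecodingManifold = manifold
        self.trajectories: TrajectorySet = trajectories
        self._projection = projection

    def project_units(self, unit_vectors: np.ndarray) -> np.ndarray:
        """Project neuron-space vectors through the fitted trajectory PCA."""
        return self._projection.transform(unit_vectors)

    def accuracy(self, scheme: str = "nearest-centroid-loo", **kw) -> float:
        return classification_accuracy(
            self.model.tensor, scheme=scheme, grouping=self.model.grouping, **kw
        )

    def selectivity(self) -> pd.DataFrame:
        return selectivity_indices(self.model.tensor)

    def summary(self) -> str:
        m = self.manifold
        lines = [
            "Decoding analysis",
            "=" * 40,
            f"grouping:            {self.model.grouping}",
            f"analysis units:      {m.n_points}",
            f"neurons:             {self.model.tensor.n_neurons}",
            f"time bins:           {self.model.tensor.n_time}",
            f"embedding dims:      {self.n_dims}",
            "explained variance:  "
            + ", ".join(f"{v:.3f}" for v in m.explained_variance_ratio),
            f"accuracy (NC-LOO):   {self.accuracy():.3f}",
        ]
        return "\n".join(lines)
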