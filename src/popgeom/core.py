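"""Core containers for population-geometry analyses.

The central object is the :class:`ResponseTensor`: a nonnegative ``neurons x
sequences x time`` array of trial-averaged activity (PSTHs) together with the
:class:`StimulusEnsemble` metadata describing each stimulus sequence — its
base class (e.g. a grating or a dot-flow pattern), its within-class variant
(e.g. spatial frequency) and its drift direction on a fixed circular grid.

Conventions
-----------
* Directions are degrees, counter-clockwise, 0 deg = rightward drift; grids are
  ascending and uniform (``n_directions`` points covering [0, 360)).
* Time bins are uniform; the first bin starts at stimulus onset, so bin
  centers are ``(i + 1/2) * bin_width`` seconds.
* Activity is in arbitrary nonnegative units (model activations or firing
  rates); containers validate nonnegativity and finiteness on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence as TypingSequence

import numpy as np

from .errors import (
    DegenerateClassError,
    InsufficientClassesError,
    LookupKeyError,
    ValidationError,
)

__all__ = [
    "SequenceInfo",
    "StimulusEnsemble",
    "ResponseTensor",
    "PSTHGrid",
    "GroundTruth",
    "DecodingManifold",
    "TrajectorySet",
    "EncodingManifold",
    "TubularityScores",
    "AlignmentReport",
    "psth_grid",
]


# ---------------------------------------------------------------------------
# Stimulus metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceInfo:
    """Metadata for one stimulus sequence.

    Parameters
    ----------
    sequence_id : str
        Unique identifier of the sequence.
    base_class : str
        Base-stimulus class label (one of the ensemble's ``class_names``).
    variant_id : str
        Variant label within the class, e.g. a spatial-frequency tag.
    direction : float
        Drift direction in degrees on the ensemble's direction grid.
    """

    sequence_id: str
    base_class: str
    variant_id: str
    direction: float


@dataclass
class StimulusEnsemble:
    """A set of parametric stimulus sequences on a shared direction grid.

    Every sequence is one (base_class, variant, direction) combination; the
    default synthetic ensemble has 6 base classes carrying 11 variants in
    total, each drifting in 8 directions, for 88 unique sequences.
    """

    sequences: list[SequenceInfo]
    n_directions: int
    class_names: list[str]

    def __post_init__(self) -> None:
        if self.n_directions < 1:
            raise ValidationError("n_directions must be >= 1")
        ids = [s.sequence_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValidationError("sequence_ids must be unique")
        triples = [(s.base_class, s.variant_id, s.direction) for s in self.sequences]
        if len(set(triples)) != len(triples):
            raise ValidationError("(base_class, variant_id, direction) triples must be unique")
        grid = set(np.round(self.direction_grid, 9))
        for s in self.sequences:
            if s.base_class not in self.class_names:
                raise ValidationError(
                    f"sequence {s.sequence_id!r} has base_class {s.base_class!r} "
                    f"not in class_names"
                )
            if round(float(s.direction), 9) not in grid:
                raise ValidationError(
                    f"sequence {s.sequence_id!r} direction {s.direction} is not on the "
                    f"{self.n_directions}-point grid"
                )
        for c in self.class_names:
            if not any(s.base_class == c for s in self.sequences):
                raise ValidationError(f"class {c!r} has no sequences")

    # -- derived views ------------------------------------------------------

    @property
    def direction_grid(self) -> np.ndarray:
        """Ascending direction grid in degrees, e.g. 0, 45, ..., 315."""
        return np.arange(self.n_directions) * (360.0 / self.n_directions)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def sequence_ids(self) -> list[str]:
        return [s.sequence_id for s in self.sequences]

    def index_of(self, sequence_id: str) -> int:
        for i, s in enumerate(self.sequences):
            if s.sequence_id == sequence_id:
                return i
        raise LookupKeyError(f"unknown sequence_id {sequence_id!r}")

    def variants_of(self, base_class: str) -> list[str]:
        """Sorted variant labels present for ``base_class``."""
        if base_class not in self.class_names:
            raise LookupKeyError(f"unknown base_class {base_class!r}")
        return sorted({s.variant_id for s in self.sequences if s.base_class == base_class})

    def find(self, base_class: str, variant_id: str, direction: float) -> int:
        """Index of the sequence with the given (class, variant, direction)."""
        for i, s in enumerate(self.sequences):
            if (
                s.base_class == base_class
                and s.variant_id == variant_id
                and np.isclose(s.direction, direction)
            ):
                return i
        raise LookupKeyError(
            f"no sequence with class={base_class!r} variant={variant_id!r} "
            f"direction={direction}"
        )


# ---------------------------------------------------------------------------
# Response tensor
# ---------------------------------------------------------------------------

@dataclass
class ResponseTensor:
    """Nonnegative ``neurons x sequences x time`` activity with metadata.

    Attributes
    ----------
    activity : ndarray, shape (N, S, T)
        Trial-averaged activity, finite and >= 0.
    bin_width : float
        Time-bin width in seconds.
    ensemble : StimulusEnsemble
        Metadata with exactly S sequences, axis-aligned with ``activity``.
    neuron_ids : list of str
        Length-N neuron identifiers.
    """

    activity: np.ndarray
    bin_width: float
    ensemble: StimulusEnsemble
    neuron_ids: list[str]

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=np.float64)
        if self.activity.ndim != 3:
            raise ValidationError(
                f"activity must be 3-axis (neurons, sequences, time); got {self.activity.ndim} axes"
            )
        if self.activity.size == 0:
            raise ValidationError("activity tensor is empty")
        bad = np.argwhere(~np.isfinite(self.activity))
        if bad.size:
            n, s, t = bad[0]
            raise ValidationError(
                f"non-finite activity at (neuron={n}, sequence={s}, bin={t})"
            )
        neg = np.argwhere(self.activity < 0)
        if neg.size:
            n, s, t = neg[0]
            raise ValidationError(
                f"negative activity at (neuron={n}, sequence={s}, bin={t})"
            )
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if self.activity.shape[1] != len(self.ensemble):
            raise ValidationError(
                f"sequence axis has {self.activity.shape[1]} entries but the ensemble "
                f"lists {len(self.ensemble)}"
            )
        if self.activity.shape[0] != len(self.neuron_ids):
            raise ValidationError(
                f"neuron axis has {self.activity.shape[0]} entries but neuron_ids "
                f"lists {len(self.neuron_ids)}"
            )
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValidationError("neuron_ids must be unique")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_sequences(self) -> int:
        return self.activity.shape[1]

    @property
    def n_time(self) -> int:
        return self.activity.shape[2]

    @property
    def time_axis(self) -> np.ndarray:
        """Bin centers in seconds; the first bin starts at stimulus onset."""
        return (np.arange(self.n_time) + 0.5) * self.bin_width

    def neuron_index(self, neuron_id: str) -> int:
        try:
            return self.neuron_ids.index(neuron_id)
        except ValueError:
            raise LookupKeyError(f"unknown neuron_id {neuron_id!r}") from None


# ---------------------------------------------------------------------------
# PSTH grid
# ---------------------------------------------------------------------------

@dataclass
class PSTHGrid:
    """Direction x time PSTH image for one (neuron, class, variant) triple.

    Rows are ordered by ascending direction; ``matrix[d, t]`` is the
    activity of the neuron at time bin ``t`` for the sequence drifting in
    ``directions[d]`` degrees.
    """

    matrix: np.ndarray
    directions: np.ndarray
    neuron_id: str
    base_class: str
    variant_id: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.directions = np.asarray(self.directions, dtype=np.float64)
        if self.matrix.shape[0] != self.directions.shape[0]:
            raise ValidationError("row count must equal number of directions")
        if np.any(self.matrix < 0):
            raise ValidationError("PSTH values must be >= 0")
        if np.any(np.diff(self.directions) <= 0):
            raise ValidationError("directions must be strictly ascending")


def psth_grid(
    tensor: ResponseTensor, neuron: str, base_class: str, variant: str
) -> PSTHGrid:
    """Extract the direction x time PSTH grid of one neuron for one stimulus.

    Row ``d`` of the grid is the exact activity time course of the sequence
    with the ``d``-th smallest direction of the (class, variant) pair.
    """
    n = tensor.neuron_index(neuron)
    ens = tensor.ensemble
    rows = [
        (s.direction, i)
        for i, s in enumerate(ens.sequences)
        if s.base_class == base_class and s.variant_id == variant
    ]
    if base_class not in ens.class_names:
        raise LookupKeyError(f"unknown base_class {base_class!r}")
    if not rows:
        raise LookupKeyError(
            f"unknown variant {variant!r} for class {base_class!r}"
        )
    if len(rows) != ens.n_directions:
        raise LookupKeyError(
            f"(class={base_class!r}, variant={variant!r}) has {len(rows)} directions; "
            f"expected {ens.n_directions}"
        )
    rows.sort()
    directions = np.array([d for d, _ in rows])
    matrix = tensor.activity[n, [i for _, i in rows], :]
    return PSTHGrid(matrix, directions, neuron, base_class, variant)


# ---------------------------------------------------------------------------
# Synthetic ground truth
# ---------------------------------------------------------------------------

VALID_PROFILES = ("transient", "sustained", "periodic", "ramp", "nonselective")


@dataclass
class GroundTruth:
    """Planted per-neuron parameters of a synthetic population.

    Used only for recovery tests: the generator records the class, preferred
    direction, von-Mises concentration ``kappa``, temporal profile and gain it
    planted for every neuron.
    """

    neuron_ids: list[str]
    planted_class: list[str]
    preferred_direction: np.ndarray
    kappa: np.ndarray
    temporal_profile: list[str]
    gain: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.neuron_ids)
        self.preferred_direction = np.asarray(self.preferred_direction, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        for name, val in [
            ("planted_class", self.planted_class),
            ("preferred_direction", self.preferred_direction),
            ("kappa", self.kappa),
            ("temporal_profile", self.temporal_profile),
            ("gain", self.gain),
        ]:
            if len(val) != n:
                raise ValidationError(f"{name} must have one entry per neuron")
        if np.any(self.kappa < 0):
            raise ValidationError("kappa must be >= 0")
        if np.any(self.gain <= 0):
            raise ValidationError("gain must be > 0")
        for p in self.temporal_profile:
            if p not in VALID_PROFILES:
                raise ValidationError(f"unknown temporal profile {p!r}")

    def to_frame(self):
        """Return the ground truth as a pandas DataFrame (one row per neuron)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "planted_class": self.planted_class,
                "preferred_direction": self.preferred_direction,
                "kappa": self.kappa,
                "temporal_profile": self.temporal_profile,
                "gain": self.gain,
            }
        )


# ---------------------------------------------------------------------------
# Analysis products
# ---------------------------------------------------------------------------

@dataclass
class DecodingManifold:
    """PCA embedding of analysis units (stimulus conditions) in neural space.

    One point per analysis unit — per unique sequence, or per (class,
    direction) pair after variant averaging — with the base class and drift
    direction carried as labels.
    """

    coords: np.ndarray  # P x D
    point_classes: list[str]
    point_directions: np.ndarray  # degrees; NaN where not applicable
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.point_directions = np.asarray(self.point_directions, dtype=float)
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(evr < -1e-12) or np.any(evr > 1 + 1e-9):
            raise ValidationError("explained_variance_ratio entries must lie in [0, 1]")
        if np.any(np.diff(evr) > 1e-9):
            raise ValidationError("explained_variance_ratio must be non-increasing")
        if evr.sum() > 1 + 1e-9:
            raise ValidationError("explained_variance_ratio must sum to <= 1")
        self.explained_variance_ratio = np.clip(evr, 0.0, 1.0)
        if self.coords.shape[0] != len(self.point_classes):
            raise ValidationError("one class label per point required")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass
class TrajectorySet:
    """K labeled trajectories of T time steps in a D-dimensional space."""

    trajectories: np.ndarray  # K x T x D
    labels: list[str]
    time_axis: np.ndarray | None = None
    directions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trajectories = np.asarray(self.trajectories, dtype=float)
        if self.trajectories.ndim != 3:
            raise ValidationError("trajectories must be a K x T x D array")
        if not np.all(np.isfinite(self.trajectories)):
            raise ValidationError("trajectories contain non-finite values")
        if len(self.labels) != self.trajectories.shape[0]:
            raise ValidationError("one label per trajectory required")
        if self.time_axis is None:
            self.time_axis = np.arange(self.trajectories.shape[1], dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.time_axis.shape[0] != self.trajectories.shape[1]:
            raise ValidationError("time_axis length must equal T")

    @property
    def n_trajectories(self) -> int:
        return self.trajectories.shape[0]

    @property
    def n_time(self) -> int:
        return self.trajectories.shape[1]

    @property
    def n_dims(self) -> int:
        return self.trajectories.shape[2]

    @property
    def classes(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def by_class(self) -> dict[str, np.ndarray]:
        """Map class label -> (k_c, T, D) sub-array of its trajectories."""
        lab = np.asarray(self.labels)
        return {c: self.trajectories[lab == c] for c in self.classes}

    def require_metric_ready(self) -> None:
        """Raise unless >= 2 classes with >= 2 trajectories each and T >= 2."""
        if self.n_time < 2:
            raise ValidationError("tubularity metrics need T >= 2")
        counts = {c: sum(1 for x in self.labels if x == c) for c in self.classes}
        if len(counts) < 2:
            raise InsufficientClassesError("tubularity metrics need >= 2 classes")
        for c, k in counts.items():
            if k < 2:
                raise DegenerateClassError(
                    f"class {c!r} has {k} trajectory; metrics need >= 2 per class"
                )


@dataclass
class EncodingManifold:
    """Diffusion embedding of neurons in stimulus-response space.

    ``embedding[i]`` places neuron ``i`` so that proximity means similar
    responses to similar stimuli; ``neuron_factors`` are its nonnegative
    tensor-factor loadings and ``graph_degree`` its affinity-graph degree.
    Disconnected affinity graphs are embedded per component; the component
    index of each neuron is in ``component_labels``.
    """

    embedding: np.ndarray  # N x D
    neuron_factors: np.ndarray  # N x R, nonnegative
    eigenvalues: np.ndarray  # length D, in (0, 1], non-increasing
    graph_degree: np.ndarray  # length N, positive
    neuron_ids: list[str] = field(default_factory=list)
    component_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float)
        self.neuron_factors = np.asarray(self.neuron_factors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.graph_degree = np.asarray(self.graph_degree, dtype=float)
        if np.any(self.neuron_factors < -1e-12):
            raise ValidationError("neuron_factors must be nonnegative")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValidationError("eigenvalues must be non-increasing")
        if np.any(self.eigenvalues <= 0) or np.any(self.eigenvalues > 1 + 1e-9):
            raise ValidationError("eigenvalues must lie in (0, 1]")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i}" for i in range(self.embedding.shape[0])]
        if self.component_labels is None:
            self.component_labels = np.zeros(self.embedding.shape[0], dtype=int)

    @property
    def n_neurons(self) -> int:
        return self.embedding.shape[0]


@dataclass
class TubularityScores:
    """Bundle-geometry summary of a trajectory set.

    ``s_tight`` in [0, 1] rewards tight, well separated class tubes;
    ``s_cross`` counts order-exchange events per cross-class trajectory pair
    per time step (in [0, 1] under that normalisation).
    """

    s_tight: float
    s_cross: float
    per_class_tightness: Mapping[str, float]
    cross_profile: np.ndarray | None = None
    metric_dim: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_tight <= 1.0):
            raise ValidationError("s_tight must lie in [0, 1]")
        if self.s_cross < 0:
            raise ValidationError("s_cross must be >= 0")
        for c, v in self.per_class_tightness.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"per-class tightness for {c!r} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "s_tight": float(self.s_tight),
            "s_cross": float(self.s_cross),
            "per_class_tightness": {k: float(v) for k, v in self.per_class_tightness.items()},
            "cross_profile": None
            if self.cross_profile is None
            else [float(x) for x in self.cross_profile],
            "metric_dim": self.metric_dim,
        }


@dataclass
class AlignmentReport:
    """The four-score representational-alignment battery and its mean.

    ``rsa`` and ``lp`` are correlations in [-1, 1]; ``cca`` and ``dsa`` lie
    in [0, 1]. ``lp`` is the mean of the two fit directions, stored
    separately as ``lp_xy`` / ``lp_yx`` since linear predictivity is the one
    directional member of the battery.
    """

    rsa: float
    cca: float
    lp: float
    dsa: float
    mean_score: float
    lp_xy: float | None = None
    lp_yx: float | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = float(np.mean([self.rsa, self.cca, self.lp, self.dsa]))
        if abs(self.mean_score - expected) > 1e-9:
            raise ValidationError("mean_score must equal the mean of the four scores")

    def to_dict(self) -> dict:
        return {
            "rsa": float(self.rsa),
            "cca": float(self.cca),
            "lp": float(self.lp),
            "dsa": float(self.dsa),
            "mean_score": float(self.mean_score),
            "lp_xy": None if self.lp_xy is None else float(self.lp_xy),
            "lp_yx": None if self.lp_yx is None else float(self.lp_yx),
            "config": self.config,
        }
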