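"""Synthetic stimulus ensembles and population responses with planted structure.

This module is the stand-in for activity one would record from a network or a
visual-system preparation: it generates

* a parametric stimulus ensemble (drifting gratings and dot-flow patterns in
  eight directions; the default composition yields 88 unique sequences over 6
  base classes),
* direction-tuned, temporally structured, noisy population responses whose
  ground truth (planted class, preferred direction, von-Mises concentration,
  temporal profile, gain) is returned alongside the tensor,
* purely geometric trajectory bundles with a known number of planted
  inter-bundle crossing events, used to validate the tubularity metrics, and
* trajectories of a linear dynamical system, used to validate dynamical
  similarity analysis.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    GroundTruth,
    ResponseTensor,
    SequenceInfo,
    StimulusEnsemble,
    TrajectorySet,
    VALID_PROFILES,
)
from .errors import ConfigError

__all__ = [
    "EnsembleConfig",
    "PopulationConfig",
    "BundleConfig",
    "make_stimulus_ensemble",
    "simulate_population",
    "make_trajectory_bundles",
    "simulate_linear_dynamics",
    "spectral_radius",
    "DEFAULT_CLASSES",
]

# Default composition: one grating class carrying six spatial-frequency
# variants plus five single-variant flow classes -> 11 variants x 8
# directions = 88 sequences over 6 base classes, averaging to 48
# class-direction analysis units.
DEFAULT_CLASSES: dict[str, int] = {
    "grating": 6,
    "flow-1dot": 1,
    "flow-3dot": 1,
    "flow-random": 1,
    "flow-radial": 1,
    "flow-rotation": 1,
}


@dataclass
class EnsembleConfig:
    """Composition of the stimulus ensemble.

    ``classes`` maps base-class name to its number of variants (spatial
    frequencies, dot densities, ...); every variant drifts in each of
    ``n_directions`` directions on a uniform circular grid.
    """

    classes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    n_directions: int = 8

    def validate(self) -> None:
        if not self.classes:
            raise ConfigError("ensemble needs at least one base class")
        if self.n_directions < 1:
            raise ConfigError("ensemble needs at least one direction")
        for c, v in self.classes.items():
            if v < 1:
                raise ConfigError(f"class {c!r} must have >= 1 variant")


def make_stimulus_ensemble(config: EnsembleConfig | None = None) -> StimulusEnsemble:
    """Build the stimulus ensemble: one sequence per (class, variant, direction)."""
    config = config or EnsembleConfig()
    config.validate()
    directions = np.arange(config.n_directions) * (360.0 / config.n_directions)
    sequences = []
    for cls, n_var in config.classes.items():
        for v in range(n_var):
            variant = f"v{v}"
            for d in directions:
                sequences.append(
                    SequenceInfo(f"{cls}:{variant}:{int(round(d))}", cls, variant, float(d))
                )
    return StimulusEnsemble(
        sequences=sequences,
        n_directions=config.n_directions,
        class_names=list(config.classes),
    )


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Parameters of the synthetic population.

    The response of neuron *n* to the sequence (class *c*, variant *v*,
    direction *d*) is the separable product

        gain_n * affinity(n, c) * vonMises(d; pref_n, kappa_n) * profile_n(t)

    plus noise, clipped at zero. ``affinity`` is 1 for the planted class and
    ``cross_affinity`` otherwise; neurons with the ``nonselective`` profile
    respond to every class and direction equally (the "intensity arm"
    phenotype: direction-independent rising activity).

    Parameters
    ----------
    neurons_per_class : dict
        Neuron count per planted class label. Labels usually match the
        ensemble's class names; extra labels (e.g. ``"nonselective"``) are
        allowed and treated as class-unselective.
    kappa_range : (float, float)
        Von-Mises concentration drawn uniformly from this range.
    profiles : sequence of str
        Temporal profiles sampled uniformly per neuron; subset of
        ``{"transient", "sustained", "periodic", "ramp", "nonselective"}``.
        Any neuron assigned ``nonselective`` gets kappa 0 and flat class
        affinity regardless of its planted class.
    noise_model : {"gaussian-truncated", "poisson-like"}
    noise_scale : float
        Gaussian SD (absolute, or per-sqrt-activity for poisson-like).
    n_time : int
        Number of time bins.
    bin_width : float
        Bin width in seconds.
    cross_affinity : float
        Response gain to non-preferred classes, in [0, 1).
    gain_range : (float, float)
    periodic_cycles : float
        Stimulus temporal-frequency cycles per trial for the periodic profile
        (integer values give closed trajectory loops).
    sustained_tau, nonselective_tau : float
        Saturation constants (fraction of trial length) of the sustained ramp
        and the nonselective intensity ramp.
    """

    neurons_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 20 for c in DEFAULT_CLASSES}
    )
    kappa_range: tuple[float, float] = (1.0, 4.0)
    profiles: tuple[str, ...] = ("transient", "sustained", "periodic", "ramp")
    noise_model: str = "gaussian-truncated"
    noise_scale: float = 0.05
    n_time: int = 20
    bin_width: float = 0.05
    cross_affinity: float = 0.1
    gain_range: tuple[float, float] = (0.8, 1.2)
    periodic_cycles: float = 2.0
    sustained_tau: float = 0.15
    nonselective_tau: float = 0.3
    transient_peak: float = 0.15
    class_profiles: dict[str, str] | None = None

    def validate(self) -> None:
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")
        if self.kappa_range[0] < 0 or self.kappa_range[1] < self.kappa_range[0]:
            raise ConfigError("kappa_range must be 0 <= lo <= hi")
        if self.noise_model not in ("gaussian-truncated", "poisson-like"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")
        if not self.neurons_per_class or sum(self.neurons_per_class.values()) < 1:
            raise ConfigError("population must contain at least one neuron")
        for p in self.profiles:
            if p not in VALID_PROFILES:
                raise ConfigError(f"unknown temporal profile {p!r}")
        for p in (self.class_profiles or {}).values():
            if p not in VALID_PROFILES:
                raise ConfigError(f"unknown temporal profile {p!r}")
        if not (0 <= self.cross_affinity < 1):
            raise ConfigError("cross_affinity must lie in [0, 1)")
        if self.n_time < 1:
            raise ConfigError("n_time must be >= 1")


def _temporal_profile(name: str, n_time: int, cfg: PopulationConfig) -> np.ndarray:
    """Unit-peak temporal profile evaluated at normalised bin centers."""
    t = (np.arange(n_time) + 0.5) / n_time
    if name == "transient":
        # gamma-shaped pulse peaking at transient_peak of the trial
        tau = cfg.transient_peak / 2.0
        prof = (t / tau) ** 2 * np.exp(-t / tau)
    elif name == "sustained":
        prof = 1.0 - np.exp(-t / cfg.sustained_tau)
    elif name == "periodic":
        prof = np.maximum(0.0, np.sin(2 * np.pi * cfg.periodic_cycles * t))
    elif name == "ramp":
        prof = t
    elif name == "nonselective":
        prof = 1.0 - np.exp(-t / cfg.nonselective_tau)
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown temporal profile {name!r}")
    peak = prof.max()
    return prof / peak if peak > 0 else prof


def von_mises_tuning(direction_deg, pref_deg: float, kappa: float) -> np.ndarray:
    """Unit-peak von-Mises direction-tuning curve, flat (=1) when kappa = 0."""
    theta = np.deg2rad(np.asarray(direction_deg, dtype=float) - pref_deg)
    return np.exp(kappa * (np.cos(theta) - 1.0))


def simulate_population(
    ensemble: StimulusEnsemble,
    pop_config: PopulationConfig | None = None,
    seed: int = 0,
) -> tuple[ResponseTensor, GroundTruth]:
    """Simulate a direction-tuned population responding to ``ensemble``.

    Returns the response tensor and the planted ground truth. Reproducible:
    the same (ensemble, config, seed) gives bit-identical output.
    """
    cfg = pop_config or PopulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    grid = ensemble.direction_grid

    neuron_ids: list[str] = []
    planted_class: list[str] = []
    prefs: list[float] = []
    kappas: list[float] = []
    profiles: list[str] = []
    gains: list[float] = []
    for cls, count in cfg.neurons_per_class.items():
        for i in range(count):
            neuron_ids.append(f"{cls}-{i}")
            planted_class.append(cls)
            if cfg.class_profiles and cls in cfg.class_profiles:
                profile = cfg.class_profiles[cls]
            else:
                profile = str(rng.choice(list(cfg.profiles)))
            nonsel = profile == "nonselective"
            profiles.append(profile)
            prefs.append(0.0 if nonsel else float(rng.choice(grid)))
            kappas.append(0.0 if nonsel else float(rng.uniform(*cfg.kappa_range)))
            gains.append(float(rng.uniform(*cfg.gain_range)))

    n_neurons, n_seq, n_time = len(neuron_ids), len(ensemble), cfg.n_time
    prof_cache = {p: _temporal_profile(p, n_time, cfg) for p in set(profiles)}

    seq_class = np.array([s.base_class for s in ensemble.sequences])
    seq_dir = np.array([s.direction for s in ensemble.sequences])

    clean = np.empty((n_neurons, n_seq, n_time))
    for n in range(n_neurons):
        if profiles[n] == "nonselective":
            affinity = np.ones(n_seq)
            tuning = np.ones(n_seq)
        else:
            affinity = np.where(seq_class == planted_class[n], 1.0, cfg.cross_affinity)
            tuning = von_mises_tuning(seq_dir, prefs[n], kappas[n])
        clean[n] = np.outer(gains[n] * affinity * tuning, prof_cache[profiles[n]])

    if cfg.noise_scale > 0:
        eps = rng.standard_normal(clean.shape)
        if cfg.noise_model == "gaussian-truncated":
            noisy = clean + cfg.noise_scale * eps
        else:  # poisson-like: variance proportional to the mean
            noisy = clean + cfg.noise_scale * np.sqrt(clean) * eps
        activity = np.clip(noisy, 0.0, None)
    else:
        activity = clean

    tensor = ResponseTensor(
        activity=activity,
        bin_width=cfg.bin_width,
        ensemble=ensemble,
        neuron_ids=neuron_ids,
    )
    truth = GroundTruth(
        neuron_ids=neuron_ids,
        planted_class=planted_class,
        preferred_direction=np.array(prefs),
        kappa=np.array(kappas),
        temporal_profile=profiles,
        gain=np.array(gains),
    )
    return tensor, truth


# ---------------------------------------------------------------------------
# Geometric trajectory bundles
# ---------------------------------------------------------------------------

@dataclass
class BundleConfig:
    """Geometry of a planted trajectory-bundle set.

    Each of ``n_bundles`` bundles is a smooth center curve plus
    ``n_traj`` trajectories offset from it by smooth random curves of RMS
    scale ``sigma``. ``family`` selects the center-curve shape; for the
    ``straight`` family, ``n_crossings`` center-level crossing events can be
    planted (adjacent bundles exchanging their lateral position at scheduled
    times); every center-level event makes all ``n_traj ** 2`` cross-bundle
    trajectory pairs cross once, so the returned planted count is
    ``n_crossings * n_traj**2``.

    ``centers``, when given, overrides the layout with explicit straight
    segments (array of shape ``(n_bundles, 2, n_dims)``: start and end
    point per bundle); planted crossings are then counted by 2-D segment
    intersection of the centers (first two coordinates).
    """

    n_bundles: int = 3
    n_traj: int = 5
    n_time: int = 30
    n_dims: int = 2
    family: str = "straight"
    sigma: float = 0.1
    n_crossings: int = 0
    separation: float = 5.0
    length: float = 10.0
    centers: np.ndarray | None = None

    def validate(self) -> None:
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.family not in ("straight", "arc", "loop"):
            raise ConfigError(f"unknown center-curve family {self.family!r}")
        if self.n_crossings < 0:
            raise ConfigError("n_crossings must be >= 0")
        if self.n_crossings and self.family != "straight":
            raise ConfigError("planted crossings are only supported for the straight family")
        if self.n_bundles < 1 or self.n_traj < 1:
            raise ConfigError("need >= 1 bundle and >= 1 trajectory per bundle")
        if self.n_dims < 2:
            raise ConfigError("bundles need n_dims >= 2")
        if self.n_crossings and self.n_bundles < 2:
            raise ConfigError("crossings need >= 2 bundles")
        if self.n_crossings > max(0, self.n_time - 2):
            raise ConfigError("too many planted crossings for this n_time")


def _segments_intersect(p1, p2, q1, q2) -> bool:
    """Proper 2-D segment intersection (shared endpoints count)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    d1, d2 = orient(q1, q2, p1), orient(q1, q2, p2)
    d3, d4 = orient(p1, p2, q1), orient(p1, p2, q2)
    return d1 != d2 and d3 != d4


def _straight_centers(cfg: BundleConfig, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Center curves (B, T, D) for the straight family, plus planted events."""
    B, T, D = cfg.n_bundles, cfg.n_time, cfg.n_dims
    x = np.linspace(0.0, cfg.length, T)
    centers = np.zeros((B, T, D))
    centers[:, :, 0] = x

    if cfg.centers is not None:
        endpoints = np.asarray(cfg.centers, dtype=float)
        if endpoints.shape != (B, 2, D):
            raise ConfigError(f"centers must have shape ({B}, 2, {D})")
        s = np.linspace(0.0, 1.0, T)[None, :, None]
        centers = endpoints[:, :1, :] * (1 - s) + endpoints[:, 1:, :] * s
        events = sum(
            _segments_intersect(
                endpoints[i, 0, :2], endpoints[i, 1, :2],
                endpoints[j, 0, :2], endpoints[j, 1, :2],
            )
            for i in range(B)
            for j in range(i + 1, B)
        )
        return centers, int(events)

    # Lateral slot per bundle over time; planted crossings are adjacent-slot
    # transpositions at evenly spaced interior times.
    slots = np.tile(np.arange(B, dtype=float), (T, 1))  # T x B, slot of bundle b
    if cfg.n_crossings:
        times = np.linspace(1, T - 2, cfg.n_crossings).round().astype(int)
        # keep event times distinct
        for k in range(1, len(times)):
            if times[k] <= times[k - 1]:
                times[k] = times[k - 1] + 1
        order = list(range(B))  # order[slot] = bundle
        for t_e in times:
            pos = int(rng.integers(0, B - 1))
            order[pos], order[pos + 1] = order[pos + 1], order[pos]
            for slot, b in enumerate(order):
                slots[t_e + 1 :, b] = slot
        # smooth the slot switches over one step by midpoint interpolation
        sm = slots.copy()
        sm[1:-1] = (slots[:-2] + 2 * slots[1:-1] + slots[2:]) / 4.0
        slots = sm
    centers[:, :, 1] = slots.T * cfg.separation
    return centers, cfg.n_crossings


def _curved_centers(cfg: BundleConfig) -> np.ndarray:
    """Arc or loop center curves, laterally offset per bundle."""
    B, T, D = cfg.n_bundles, cfg.n_time, cfg.n_dims
    centers = np.zeros((B, T, D))
    radius = cfg.length / 2.0
    if cfg.family == "arc":
        theta = np.linspace(0.0, np.pi, T)
    else:  # loop: closed circle (last point returns next to the first)
        theta = np.linspace(0.0, 2 * np.pi, T, endpoint=False)
    for b in range(B):
        r = radius + b * cfg.separation
        centers[b, :, 0] = r * np.cos(theta)
        centers[b, :, 1] = r * np.sin(theta)
    return centers


def _smooth_offsets(
    cfg: BundleConfig, rng: np.random.Generator, n_curves: int
) -> np.ndarray:
    """Smooth random offset curves (n_curves, T, D) of unit RMS, times sigma.

    Offsets are a random constant plus three low-frequency Fourier modes with
    1/m amplitude decay, normalised so the expected per-point RMS norm is
    one; multiplying by sigma therefore scales mean offset distance exactly
    linearly.
    """
    T, D = cfg.n_time, cfg.n_dims
    t = np.arange(T) / T
    basis = [np.ones(T)]
    for m in (1, 2, 3):
        basis.append(np.cos(2 * np.pi * m * t) / m)
        basis.append(np.sin(2 * np.pi * m * t) / m)
    basis = np.stack(basis)  # M x T
    coef = rng.standard_normal((n_curves, basis.shape[0], D))
    curves = np.einsum("kmd,mt->ktd", coef, basis)
    rms = np.sqrt(np.mean(np.sum(basis**2, axis=0)))  # expected point norm / sqrt(D)
    return cfg.sigma * curves / (rms * np.sqrt(D))


def make_trajectory_bundles(
    geom_config: BundleConfig | None = None, seed: int = 0
) -> tuple[TrajectorySet, int]:
    """Generate labeled trajectory bundles and the planted crossing count.

    Returns
    -------
    trajs : TrajectorySet
        ``n_bundles * n_traj`` trajectories labeled ``bundle0 ...``.
    planted_crossings : int
        Number of constructed cross-bundle trajectory-pair crossing events
        (center-curve events times ``n_traj ** 2``).
    """
    cfg = geom_config or BundleConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    if cfg.family == "straight":
        centers, center_events = _straight_centers(cfg, rng)
    else:
        centers = _curved_centers(cfg)
        center_events = 0

    offsets = _smooth_offsets(cfg, rng, cfg.n_bundles * cfg.n_traj)
    trajs = np.repeat(centers, cfg.n_traj, axis=0) + offsets
    labels = [f"bundle{b}" for b in range(cfg.n_bundles) for _ in range(cfg.n_traj)]
    planted = center_events * cfg.n_traj**2
    return TrajectorySet(trajs, labels), planted


# ---------------------------------------------------------------------------
# Linear dynamics
# ---------------------------------------------------------------------------

def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue magnitude of a square matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(A, dtype=float)))))


def simulate_linear_dynamics(
    A: np.ndarray,
    n_traj: int,
    T: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "dyn",
) -> TrajectorySet:
    """Simulate ``x(t+1) = A x(t) + noise`` from isotropic initial states.

    The caller is responsible for checking :func:`spectral_radius`; unstable
    systems are simulated as requested.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ConfigError(f"A must be square; got shape {A.shape}")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    D = A.shape[0]
    rng = np.random.default_rng(seed)
    X = np.empty((n_traj, T, D))
    X[:, 0] = rng.standard_normal((n_traj, D))
    for t in range(1, T):
        X[:, t] = X[:, t - 1] @ A.T
        if noise_sd > 0:
            X[:, t] += noise_sd * rng.standard_normal((n_traj, D))
    return TrajectorySet(X, [label] * n_traj)
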