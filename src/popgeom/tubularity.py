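"""Tubularity metrics: how tube-like are bundles of decoding trajectories?

Population trajectories evoked by the same stimulus class tend to form
"tubes" — tight, well separated bundles — in healthy visual representations.
Two scores quantify this geometry:

* **tightness** ``s_tight`` in [0, 1]: per time step, the ratio
  ``b(t) / (b(t) + 2 w(t))`` of mean between-centroid distance ``b`` to the
  tube diameter proxy ``2 w`` (``w`` = mean point-to-class-centroid
  distance), averaged over time. 1 means zero-width, separated tubes; 0.5
  means tubes whose spacing equals their combined spread (touching).
* **crossings** ``s_cross`` in [0, 1]: the rate at which cross-class
  trajectory pairs exchange order along the axis joining their class
  centroids, per pair per time step. Order exchanges late in the trial are
  the signature of entangled, noisy-looking but structured dynamics.

Both scores are invariant to global rotation, translation and uniform
scaling of the trajectory space. A seeded bootstrap (resampling trajectories
within class) compares two systems' scores with Bonferroni correction.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import TrajectorySet, TubularityScores
from .errors import ValidationError

__all__ = [
    "TubularityModel",
    "TubularityResults",
    "tightness_score",
    "crossings_score",
    "tubularity_scores",
    "compare_scores",
]


def _groups(trajs: TrajectorySet) -> dict[str, np.ndarray]:
    trajs.require_metric_ready()
    return trajs.by_class()


def _centroids(groups: dict[str, np.ndarray]) -> np.ndarray:
    return np.stack([g.mean(axis=0) for g in groups.values()])  # C x T x D


def _tightness(groups: dict[str, np.ndarray]):
    cent = _centroids(groups)
    C, T, _ = cent.shape
    # b(t): mean pairwise centroid distance
    iu, ju = np.triu_indices(C, k=1)
    b = np.linalg.norm(cent[iu] - cent[ju], axis=2).mean(axis=0) if C > 1 else np.zeros(T)
    # w(t): pooled and per-class mean point-to-centroid distance
    per_class_w = {}
    counts = {}
    for ci, (c, g) in enumerate(groups.items()):
        per_class_w[c] = np.linalg.norm(g - cent[ci], axis=2).mean(axis=0)  # T
        counts[c] = g.shape[0]
    total = sum(counts.values())
    w = sum(counts[c] * per_class_w[c] for c in groups) / total

    def ratio(bv, wv):
        denom = bv + 2 * wv
        out = np.zeros_like(bv)
        ok = denom > 0
        out[ok] = bv[ok] / denom[ok]
        return out  # b == 0 (incl. b == w == 0) contributes 0

    s_tight = float(ratio(b, w).mean())
    per_class = {c: float(ratio(b, per_class_w[c]).mean()) for c in groups}
    return s_tight, per_class


def tightness_score(trajs: TrajectorySet) -> tuple[float, dict[str, float]]:
    """Bundle tightness in [0, 1] plus the per-class breakdown.

    Convention: time steps where all class centroids coincide (b = 0)
    contribute 0; zero within-bundle spread with separated centroids gives 1.
    """
    return _tightness(_groups(trajs))


def _crossings(groups: dict[str, np.ndarray]):
    names = list(groups)
    cent = _centroids(groups)
    T = cent.shape[1]
    events_t = np.zeros(T - 1)
    n_pairs = 0
    for a in range(len(names)):
        for b_i in range(a + 1, len(names)):
            A, B = groups[names[a]], groups[names[b_i]]
            n_pairs += A.shape[0] * B.shape[0]
            u = cent[b_i] - cent[a]  # T x D
            norm = np.linalg.norm(u, axis=1)
            valid = norm > 0
            u_hat = np.where(valid[:, None], u / np.where(valid, norm, 1.0)[:, None], 0.0)
            rel = A[:, None, :, :] - B[None, :, :, :]  # ka x kb x T x D
            own = np.einsum("abtd,td->abt", rel, u_hat)  # rel(t) . u(t)
            nxt = np.einsum("abtd,td->abt", rel[:, :, :-1], u_hat[1:])  # rel(t) . u(t+1)
            prv = np.einsum("abtd,td->abt", rel[:, :, 1:], u_hat[:-1])  # rel(t+1) . u(t)
            # order flip assessed on both endpoint axes (time-reversal symmetric);
            # a degenerate (zero) axis defers to the other endpoint's axis
            flip_start = own[:, :, :-1] * prv < 0  # axis at t
            flip_end = nxt * own[:, :, 1:] < 0  # axis at t+1
            v0, v1 = valid[:-1], valid[1:]
            ev = (flip_start | ~v0) & (flip_end | ~v1) & (v0 | v1)
            events_t += ev.sum(axis=(0, 1))
    s_cross = float(events_t.sum() / (n_pairs * (T - 1)))
    return s_cross, events_t


def crossings_score(trajs: TrajectorySet) -> tuple[float, np.ndarray]:
    """Cross-class order-exchange rate plus its per-time-step profile.

    An event is a sign flip, between consecutive time steps, of the
    difference of the two trajectories' projections onto the axis joining
    their class centroids; the score is events per cross-class pair per step
    (hence in [0, 1]). The profile localises the events in time (length
    T - 1).
    """
    return _crossings(_groups(trajs))


def tubularity_scores(trajs: TrajectorySet) -> TubularityScores:
    """Compute both tubularity metrics as a :class:`TubularityScores`."""
    groups = _groups(trajs)
    s_tight, per_class = _tightness(groups)
    s_cross, profile = _crossings(groups)
    return TubularityScores(
        s_tight=s_tight,
        s_cross=s_cross,
        per_class_tightness=per_class,
        cross_profile=profile,
        metric_dim=trajs.n_dims,
    )


# ---------------------------------------------------------------------------
# Resampling comparison
# ---------------------------------------------------------------------------

_METRICS = {
    "tight": lambda g: _tightness(g)[0],
    "cross": lambda g: _crossings(g)[0],
}


def _resample(groups: dict[str, np.ndarray], rng) -> dict[str, np.ndarray]:
    return {
        c: g[rng.integers(0, g.shape[0], size=g.shape[0])] for c, g in groups.items()
    }


def compare_scores(
    trajsA: TrajectorySet,
    trajsB: TrajectorySet,
    metric: str = "tight",
    n_boot: int = 1000,
    seed: int = 0,
    n_comparisons: int = 1,
) -> tuple[float, float, float]:
    """Two-sided bootstrap comparison of a tubularity metric between systems.

    Trajectories are resampled with replacement within class, independently
    in each set; the p-value follows the centered-bootstrap convention

        p = (1 + #{ |delta*_b - delta_hat| >= |delta_hat| }) / (n_boot + 1)

    so identical inputs give delta = 0 and p = 1 exactly.

    Returns
    -------
    (delta, p, p_bonferroni) : delta = metric(A) - metric(B); p_bonferroni =
    min(1, p * n_comparisons).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; p-values will be coarse", stacklevel=2)
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    f = _METRICS[metric]
    gA, gB = _groups(trajsA), _groups(trajsB)
    delta = f(gA) - f(gB)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_boot):
        d_star = f(_resample(gA, rng)) - f(_resample(gB, rng))
        if abs(d_star - delta) >= abs(delta):
            extreme += 1
    p = (1 + extreme) / (n_boot + 1)
    return float(delta), float(p), float(min(1.0, p * n_comparisons))


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class TubularityModel:
    """Tubularity analysis of a labeled trajectory set."""

    def __init__(self, trajs: TrajectorySet):
        trajs.require_metric_ready()
        self.trajs = trajs

    def fit(self) -> "TubularityResults":
        return TubularityResults(self, tubularity_scores(self.trajs))


class TubularityResults:
    """Computed tubularity scores with a comparison method."""

    def __init__(self, model: TubularityModel, scores: TubularityScores):
        self.model = model
        self.scores = scores

    @property
    def s_tight(self) -> float:
        return self.scores.s_tight

    @property
    def s_cross(self) -> float:
        return self.scores.s_cross

    def compare(self, other, metric: str = "tight", **kw) -> tuple[float, float, float]:
        other_trajs = other.trajs if isinstance(other, TubularityModel) else (
            other.model.trajs if isinstance(other, TubularityResults) else other
        )
        return compare_scores(self.model.trajs, other_trajs, metric=metric, **kw)

    def summary(self) -> str:
        s = self.scores
        lines = [
            "Tubularity analysis",
            "=" * 40,
            f"trajectories:        {self.model.trajs.n_trajectories}"
            f" in {len(self.model.trajs.classes)} classes",
            f"time steps / dims:   {self.model.trajs.n_time} / {self.model.trajs.n_dims}",
            f"S_tight:             {s.s_tight:.4f}",
            f"S_cross:             {s.s_cross:.4f}",
            "per-class tightness: "
            + ", ".join(f"{c}={v:.3f}" for c, v in s.per_class_tightness.items()),
        ]
        return "\n".join(lines)
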