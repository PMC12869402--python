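"""Representational-alignment metrics between two systems.

Given two systems' responses to a shared, row-aligned set of stimulus
conditions (``X``: conditions x features_A, ``Y``: conditions x features_B)
and optionally their decoding trajectories, this module scores alignment
four ways and averages them:

* **RSA** — Spearman correlation between the two representational
  dissimilarity matrices (1 - Pearson across features, upper triangles);
* **CCA** — mean of the top canonical correlations after PCA reduction of
  each side (regularisation against rank deficiency);
* **LP** — cross-validated ridge regression from one system's features to
  the other's responses, scored by out-of-fold Pearson correlation per
  target feature (directional; both directions are reported and averaged);
* **DSA** — similarity of the rank-limited one-step linear dynamics
  operators fitted to each system's trajectories, compared up to an
  orthogonal change of basis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import spearmanr

from .core import AlignmentReport, TrajectorySet
from .errors import DimensionError, ValidationError

__all__ = [
    "AlignmentModel",
    "AlignmentResults",
    "rsa_score",
    "cca_score",
    "linear_predictivity",
    "dsa_score",
    "alignment_report",
]


def _check_conditions(X, Y, minimum=4):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"condition counts differ: {X.shape[0]} vs {Y.shape[0]} (rows must align)"
        )
    if X.shape[0] < minimum:
        raise ValidationError(f"need >= {minimum} shared conditions")
    return X, Y


# ---------------------------------------------------------------------------
# RSA
# ---------------------------------------------------------------------------

def _rdm(X: np.ndarray) -> np.ndarray:
    """Correlation-distance RDM: 1 - Pearson between condition rows."""
    return 1.0 - np.corrcoef(X)


def rsa_score(X, Y) -> float:
    """Representational similarity: Spearman correlation of the two RDMs.

    Conditions with zero feature variance on either side (Pearson undefined)
    are dropped from both and reported via a warning.
    """
    X, Y = _check_conditions(X, Y)
    bad = (X.std(axis=1) == 0) | (Y.std(axis=1) == 0)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} zero-variance conditions from both systems",
            stacklevel=2,
        )
        X, Y = X[~bad], Y[~bad]
    if X.shape[0] < 4:
        raise ValidationError("fewer than 4 usable conditions after dropping")
    iu = np.triu_indices(X.shape[0], k=1)
    rho = spearmanr(_rdm(X)[iu], _rdm(Y)[iu]).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

def _pca_scores(X: np.ndarray, dim: int) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return U[:, :dim] * s[:dim]


def cca_score(X, Y, n_components: int | None = None, pca_dim: int | None = None) -> float:
    """Mean of the top canonical correlations after PCA reduction.

    Each side is reduced to ``pca_dim`` principal components (default: the
    largest feasible value up to 10); the score is the mean of the top
    ``n_components`` canonical correlations (default: all ``pca_dim``).
    """
    X, Y = _check_conditions(X, Y)
    n_cond = X.shape[0]
    feasible = min(n_cond - 1, X.shape[1], Y.shape[1])
    if pca_dim is None:
        pca_dim = min(10, feasible)
    if n_components is None:
        n_components = pca_dim
    if not (n_cond >= pca_dim >= n_components >= 1):
        raise DimensionError(
            f"need conditions ({n_cond}) >= pca_dim ({pca_dim}) >= "
            f"n_components ({n_components}) >= 1"
        )
    if pca_dim > feasible:
        raise DimensionError(f"pca_dim {pca_dim} exceeds feasible rank {feasible}")

    corrs = []
    Xp, Yp = _pca_scores(X, pca_dim), _pca_scores(Y, pca_dim)
    # orthonormalise each side; canonical correlations are the singular
    # values of the product of the two orthonormal bases
    qx, rx = np.linalg.qr(Xp - Xp.mean(axis=0))
    qy, ry = np.linalg.qr(Yp - Yp.mean(axis=0))
    # guard rank deficiency: drop directions with negligible scale
    keep_x = np.abs(np.diag(rx)) > 1e-10 * max(1.0, np.abs(np.diag(rx)).max())
    keep_y = np.abs(np.diag(ry)) > 1e-10 * max(1.0, np.abs(np.diag(ry)).max())
    qx, qy = qx[:, keep_x], qy[:, keep_y]
    svals = np.linalg.svd(qx.T @ qy, compute_uv=False)
    corrs = np.zeros(n_components)
    m = min(n_components, len(svals))
    corrs[:m] = np.clip(svals[:m], 0.0, 1.0)
    return float(corrs.mean())


# ---------------------------------------------------------------------------
# Linear predictivity
# ---------------------------------------------------------------------------

def linear_predictivity(
    X, Y, folds: int = 5, ridge: float = 1.0, seed: int = 0
) -> float:
    """Cross-validated ridge regression X -> Y, scored per target feature.

    Out-of-fold predictions are pooled across folds; the score is the mean
    over target features of the Pearson correlation between predicted and
    true values. Zero-variance target features are excluded (warned); a
    degenerate (constant) prediction scores 0 for its feature.
    """
    from sklearn.linear_model import Ridge
    from sklearn.model_selection import KFold

    X, Y = _check_conditions(X, Y)
    n = X.shape[0]
    if not 2 <= folds <= n:
        raise ValidationError(f"need 2 <= folds <= conditions ({n})")
    keep = Y.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance target features", stacklevel=2
        )
    Y = Y[:, keep]
    if Y.shape[1] == 0:
        raise ValidationError("no target features with variance")

    pred = np.empty_like(Y)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in cv.split(X):
        model = Ridge(alpha=ridge).fit(X[train], Y[train])
        pred[test] = model.predict(X[test])

    scores = np.zeros(Y.shape[1])
    for j in range(Y.shape[1]):
        if pred[:, j].std() == 0:
            continue
        scores[j] = np.corrcoef(pred[:, j], Y[:, j])[0, 1]
    return float(scores.mean())


# ---------------------------------------------------------------------------
# DSA
# ---------------------------------------------------------------------------

def _reduced_states(trajs: TrajectorySet, rank: int) -> np.ndarray:
    K, T, D = trajs.trajectories.shape
    flat = trajs.trajectories.reshape(K * T, D)
    flat = flat - flat.mean(axis=0)
    U, s, _ = np.linalg.svd(flat, full_matrices=False)
    r = min(rank, D)
    return (U[:, :r] * s[:r]).reshape(K, T, r)


def _fit_operator(states: np.ndarray, ridge: float = 1e-9) -> np.ndarray:
    """Least-squares one-step predictor A: x(t+1) ~ A x(t), pooled over trajectories."""
    X0 = states[:, :-1].reshape(-1, states.shape[2])
    X1 = states[:, 1:].reshape(-1, states.shape[2])
    G = X0.T @ X0 + ridge * np.eye(states.shape[2])
    return np.linalg.solve(G, X0.T @ X1).T


def _skew(params: np.ndarray, d: int) -> np.ndarray:
    S = np.zeros((d, d))
    iu = np.triu_indices(d, k=1)
    S[iu] = params
    return S - S.T


def _conjugation_distance(Ax: np.ndarray, Ay: np.ndarray, n_restarts: int, seed: int) -> float:
    """min over orthogonal Q of ||Ax - Q Ay Q^T||_F via seeded multi-start."""
    d = Ax.shape[0]
    rng = np.random.default_rng(seed)
    n_par = d * (d - 1) // 2

    def objective_for(Q0):
        def f(p):
            Q = Q0 @ expm(_skew(p, d))
            return np.linalg.norm(Ax - Q @ Ay @ Q.T)

        return f

    starts = [np.eye(d), -np.eye(d) if d % 2 else np.diag([-1.0] + [1.0] * (d - 1))]
    while len(starts) < max(2, n_restarts):
        M = rng.standard_normal((d, d))
        Q, _ = np.linalg.qr(M)
        starts.append(Q)
    best = np.inf
    for Q0 in starts:
        f = objective_for(Q0)
        if n_par == 0:
            best = min(best, f(np.zeros(0)))
            continue
        res = minimize(f, np.zeros(n_par), method="L-BFGS-B")
        best = min(best, float(res.fun), f(np.zeros(n_par)))
    return float(best)


def dsa_score(
    trajsX: TrajectorySet,
    trajsY: TrajectorySet,
    rank: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
) -> float:
    """Dynamical similarity of two trajectory sets in [0, 1].

    Each set is reduced to its top-``rank`` principal components (pooled
    points), a one-step linear operator A is fitted, and the operators are
    compared up to an orthogonal change of basis:

        dissim = min_Q ||A_X - Q A_Y Q^T||_F / max(||A_X||_F, ||A_Y||_F)
        score  = 1 - min(1, dissim)

    The Q optimisation is a seeded multi-start over the orthogonal group
    (both determinant components) with local refinement.
    """
    for t in (trajsX, trajsY):
        if t.n_time < 3:
            raise ValidationError("DSA needs trajectories with T >= 3")
    rank = int(rank)
    for t in (trajsX, trajsY):
        n_trans = t.n_trajectories * (t.n_time - 1)
        if n_trans < rank:
            warnings.warn(
                f"only {n_trans} transitions; reducing DSA rank to {n_trans}", stacklevel=2
            )
            rank = n_trans
    sx = _reduced_states(trajsX, rank)
    sy = _reduced_states(trajsY, rank)
    r = min(sx.shape[2], sy.shape[2])
    Ax = _fit_operator(sx[:, :, :r])
    Ay = _fit_operator(sy[:, :, :r])
    denom = max(np.linalg.norm(Ax), np.linalg.norm(Ay))
    if denom == 0:
        return 1.0  # both systems are exactly static: identical dynamics
    dissim = _conjugation_distance(Ax, Ay, n_restarts, seed) / denom
    return float(1.0 - min(1.0, dissim))


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def alignment_report(
    X,
    Y,
    trajsX: TrajectorySet,
    trajsY: TrajectorySet,
    config: dict | None = None,
) -> AlignmentReport:
    """Compute the four-score battery and its arithmetic mean.

    ``lp`` is the mean of the two fit directions (linear predictivity is the
    one directional metric); both directions are stored on the report.
    """
    cfg = dict(config or {})
    rsa = rsa_score(X, Y)
    cca = cca_score(
        X, Y, n_components=cfg.get("cca_components"), pca_dim=cfg.get("cca_pca_dim")
    )
    lp_kw = dict(
        folds=cfg.get("lp_folds", 5),
        ridge=cfg.get("lp_ridge", 1.0),
        seed=cfg.get("seed", 0),
    )
    lp_xy = linear_predictivity(X, Y, **lp_kw)
    lp_yx = linear_predictivity(Y, X, **lp_kw)
    lp = (lp_xy + lp_yx) / 2.0
    dsa = dsa_score(
        trajsX,
        trajsY,
        rank=cfg.get("dsa_rank", 3),
        n_restarts=cfg.get("dsa_restarts", 10),
        seed=cfg.get("seed", 0),
    )
    mean = float(np.mean([rsa, cca, lp, dsa]))
    return AlignmentReport(
        rsa=rsa, cca=cca, lp=lp, dsa=dsa, mean_score=mean,
        lp_xy=lp_xy, lp_yx=lp_yx, config=cfg,
    )


class AlignmentModel:
    """Alignment battery between two systems on shared conditions.

    Parameters
    ----------
    X, Y : (conditions, features) arrays, row-aligned.
    trajsX, trajsY : TrajectorySet
        Decoding trajectories of the two systems (for DSA).
    config : dict
        Optional overrides (cca_pca_dim, lp_folds, dsa_rank, seed, ...).
    """

    def __init__(self, X, Y, trajsX: TrajectorySet, trajsY: TrajectorySet, config=None):
        self.X, self.Y = _check_conditions(X, Y)
        self.trajsX, self.trajsY = trajsX, trajsY
        self.config = dict(config or {})

    def fit(self) -> "AlignmentResults":
        return AlignmentResults(
            self, alignment_report(self.X, self.Y, self.trajsX, self.trajsY, self.config)
        )


class AlignmentResults:
    """Computed alignment battery with a summary table."""

    def __init__(self, model: AlignmentModel, report: AlignmentReport):
        self.model = model
        self.report = report

    def summary(self) -> str:
        r = self.report
        lines = [
            "Representational alignment",
            "=" * 40,
            f"conditions:          {self.model.X.shape[0]}",
            f"RSA:                 {r.rsa:.4f}",
            f"CCA:                 {r.cca:.4f}",
            f"LP (X->Y / Y->X):    {r.lp_xy:.4f} / {r.lp_yx:.4f}",
            f"DSA:                 {r.dsa:.4f}",
            f"mean score:          {r.mean_score:.4f}",
        ]
        return "\n".join(lines)
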