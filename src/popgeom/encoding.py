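"""Encoding manifolds: embedding neurons in stimulus-response space.

Whereas a decoding manifold embeds stimuli in neural coordinates, an encoding
manifold embeds *neurons* in the space of their responses across the whole
stimulus ensemble, exposing the global topology of the population (clustered
into discrete functional types, or continuous). The pipeline is

1. per-neuron normalisation of the ``neurons x conditions x time`` tensor,
2. non-negative CP (PARAFAC) decomposition by HALS alternating updates,
3. an adaptive-bandwidth Gaussian similarity graph on the neuron loadings,
4. a diffusion-map embedding of that graph, and
5. summary statistics of the embedding's topology (components, cluster gap,
   agreement with reference labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .core import EncodingManifold, ResponseTensor
from .errors import ValidationError

__all__ = [
    "EncodingModel",
    "EncodingResults",
    "NTFDecomposition",
    "encoding_tensor",
    "ntf_decompose",
    "neuron_similarity_graph",
    "diffusion_embedding",
    "topology_stats",
    "select_rank",
]


# ---------------------------------------------------------------------------
# Tensor preparation
# ---------------------------------------------------------------------------

def encoding_tensor(
    tensor: ResponseTensor, normalization: str = "per-neuron-max"
) -> tuple[np.ndarray, np.ndarray]:
    """Stack responses into a ``neurons x conditions x time`` array.

    Conditions are the flattened (class, variant, direction) combinations,
    i.e. the sequence axis. ``per-neuron-max`` rescales each neuron's slab to
    peak 1 so the embedding reflects response *shape* rather than gain;
    all-zero neurons are left at zero and flagged for exclusion downstream.

    Returns
    -------
    arr : ndarray (N, S, T)
    all_zero : bool ndarray (N,)
        True for neurons with no activity anywhere.
    """
    arr = tensor.activity.copy()
    peak = arr.max(axis=(1, 2))
    all_zero = peak == 0
    if normalization == "per-neuron-max":
        scale = np.where(all_zero, 1.0, peak)
        arr /= scale[:, None, None]
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return arr, all_zero


# ---------------------------------------------------------------------------
# Non-negative CP decomposition (HALS)
# ---------------------------------------------------------------------------

@dataclass
class NTFDecomposition:
    """Rank-R non-negative CP decomposition of a 3-way tensor.

    ``rel_error`` is ||X - X_hat||_F / ||X||_F for the best restart;
    ``trace`` is that restart's per-iteration objective (non-increasing).
    """

    neuron_factors: np.ndarray  # N x R
    condition_factors: np.ndarray  # C x R
    time_factors: np.ndarray  # T x R
    rel_error: float
    trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def rank(self) -> int:
        return self.neuron_factors.shape[1]

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.neuron_factors, self.condition_factors,
                         self.time_factors)


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _khatri_rao(B: np.ndarray, C: np.ndarray) -> np.ndarray:
    # column-wise Kronecker: rows index (b, c) pairs in C-major order
    return (B[:, None, :] * C[None, :, :]).reshape(-1, B.shape[1])


def _svd_init(X, rank):
    """Data-driven nonnegative init: |leading singular vectors| per unfolding.

    Deterministic and permutation-equivariant (a row permutation of any mode
    permutes the corresponding factor's rows), which keeps the whole encoding
    pipeline equivariant when a single restart is used.
    """
    factors = []
    for mode in range(3):
        M = _unfold(X, mode)
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        r = min(rank, U.shape[1])
        F = np.abs(U[:, :r]) * np.sqrt(s[:r])
        if r < rank:
            F = np.hstack([F, np.tile(F.mean(axis=1, keepdims=True), rank - r)])
        factors.append(F)
    return factors


def _hals_run(X, rank, rng, max_iter, tol, init="random"):
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        z = [np.zeros((d, rank)) for d in X.shape]
        return (*z, 0.0, np.zeros(1))
    if init == "svd":
        factors = _svd_init(X, rank)
    else:
        factors = [
            rng.uniform(0.1, 1.0, size=(dim, rank)) * (norm_x ** (1 / 3) / np.sqrt(rank))
            for dim in X.shape
        ]
    unfolds = [_unfold(X, m) for m in range(3)]
    trace = []
    prev = np.inf
    eps = 1e-16
    for _ in range(max_iter):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            KR = _khatri_rao(others[0], others[1])
            G = unfolds[mode] @ KR  # I_mode x R
            H = (others[0].T @ others[0]) * (others[1].T @ others[1])  # R x R
            A = factors[mode]
            for r in range(rank):
                h_rr = H[r, r]
                if h_rr < eps:
                    # dead component: reseed tiny to avoid division blow-up
                    A[:, r] = 0.0
                    continue
                update = A[:, r] + (G[:, r] - A @ H[:, r]) / h_rr
                A[:, r] = np.maximum(0.0, update)
        resid = np.linalg.norm(X - np.einsum("ir,jr,kr->ijk", *factors))
        rel = resid / norm_x
        trace.append(rel)
        if prev - rel < tol:
            break
        prev = rel
    return (*factors, trace[-1], np.asarray(trace))


def ntf_decompose(
    tensor3: np.ndarray,
    rank: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> NTFDecomposition:
    """Non-negative CP decomposition minimising Frobenius error (HALS).

    Runs ``n_restarts`` seeded random restarts of hierarchical alternating
    least squares and returns the best. The per-iteration objective of the
    winning run is available as ``trace`` and is non-increasing.
    """
    X = np.asarray(tensor3, dtype=float)
    if X.ndim != 3:
        raise ValidationError("ntf_decompose expects a 3-axis tensor")
    if not np.all(np.isfinite(X)):
        raise ValidationError("tensor contains non-finite values")
    if np.any(X < 0):
        raise ValidationError("tensor must be nonnegative")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    bound = min(np.prod(X.shape) // max(d, 1) for d in X.shape)
    if rank > min(X.shape[0] * X.shape[1], X.shape[1] * X.shape[2], X.shape[0] * X.shape[2]):
        warnings.warn(f"rank {rank} exceeds the feasible rank bound {bound}", stacklevel=2)

    rng_master = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        rng = np.random.default_rng(rng_master.integers(0, 2**31))
        # restart 0 is deterministic and data-driven (SVD magnitudes), so a
        # single-restart decomposition is permutation-equivariant
        A, B, C, rel, trace = _hals_run(
            X, rank, rng, max_iter, tol, init="svd" if restart == 0 else "random"
        )
        if best is None or rel < best.rel_error - 1e-12:
            best = NTFDecomposition(A, B, C, float(rel), trace)
    return best


def select_rank(
    tensor3: np.ndarray,
    max_rank: int = 8,
    improvement: float = 0.05,
    n_restarts: int = 3,
    seed: int = 0,
) -> int:
    """Elbow rule for the CP rank.

    Increases the rank while each extra component still lowers the relative
    error by at least ``improvement``; returns the last rank that cleared the
    bar (so a component buying < 5% error is never included).
    """
    prev_err = None
    chosen = 1
    for r in range(1, max_rank + 1):
        err = ntf_decompose(tensor3, r, n_restarts=n_restarts, seed=seed).rel_error
        if prev_err is not None and prev_err - err < improvement:
            break
        chosen = r
        prev_err = err
    return chosen


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------

def neuron_similarity_graph(neuron_factors: np.ndarray, k: int = 7) -> np.ndarray:
    """Adaptive-bandwidth Gaussian affinity between neurons.

    Factor rows are normalised to unit length (so similarity reflects the
    *pattern* of loadings, not their magnitude); the kernel uses a local
    scale per neuron — its distance to its k-th nearest neighbour:

        affinity_ij = exp(-d_ij^2 / (sigma_i sigma_j))

    Duplicate rows would give sigma = 0; their scale is floored at a
    machine-scaled epsilon and the duplicates are reported via a warning.
    """
    F = np.asarray(neuron_factors, dtype=float)
    n = F.shape[0]
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < N={n}")
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    Fn = F / np.where(norms > 0, norms, 1.0)
    d = cdist(Fn, Fn)
    kth = np.sort(d, axis=1)[:, k]  # column 0 is self (distance 0)
    floor = max(1.0, float(d.max())) * 1e-12
    dup = np.where(kth <= 0)[0]
    if dup.size:
        warnings.warn(
            f"{dup.size} neurons have duplicate factor rows (sigma floored): "
            f"{dup[:10].tolist()}",
            stacklevel=2,
        )
    sigma = np.maximum(kth, floor)
    W = np.exp(-(d**2) / np.outer(sigma, sigma))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 1.0)
    return W


# ---------------------------------------------------------------------------
# Diffusion embedding
# ---------------------------------------------------------------------------

def _embed_component(W: np.ndarray, n_dims: int, t: int):
    """Diffusion coordinates of one connected affinity block.

    Row-normalises W to a Markov matrix, takes the top nontrivial right
    eigenvectors (via the symmetric conjugate), and returns coordinates
    lambda^t * psi with the largest-magnitude entry of each psi positive.
    """
    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    S = W * np.outer(inv_sqrt, inv_sqrt)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # drop the trivial lambda = 1 stationary eigenvector (index 0 within a
    # connected block), keep positive eigenvalues only
    vals, vecs = vals[1:], vecs[:, 1:]
    keep = vals > 1e-12
    vals, vecs = vals[keep], vecs[:, keep]
    m = min(n_dims, len(vals))
    coords = np.zeros((W.shape[0], n_dims))
    lams = np.zeros(n_dims)
    for j in range(m):
        psi = inv_sqrt * vecs[:, j]
        psi /= np.linalg.norm(psi)
        i_max = np.argmax(np.abs(psi))
        if psi[i_max] < 0:
            psi = -psi
        coords[:, j] = min(vals[j], 1.0) ** t * psi
        lams[j] = min(vals[j], 1.0)
    return coords, lams, deg


def diffusion_embedding(
    affinity: np.ndarray, n_dims: int = 3, diffusion_time: int = 1
) -> EncodingManifold:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    Deterministic up to nothing: eigenvector signs follow the
    largest-magnitude-entry-positive convention. A disconnected graph is
    embedded per component — the leading coordinates become centered
    component indicators (the exact lambda = 1 eigenspace, orthogonal to the
    constant), so components separate by sign — and each neuron's component
    index is reported in ``component_labels``.
    """
    W = np.asarray(affinity, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[1] != n:
        raise ValidationError("affinity must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValidationError("affinity must be symmetric")
    if np.any(W < 0):
        raise ValidationError("affinity must be nonnegative")
    if not 0 < n_dims < n:
        raise ValidationError(f"need 0 < n_dims < N={n}")

    n_comp, comp = connected_components(csr_matrix(W > 0), directed=False)
    if n_comp == 1:
        coords, lams, deg = _embed_component(W, n_dims, diffusion_time)
        m = int(np.sum(lams > 0))
        return EncodingManifold(
            embedding=coords[:, :max(m, 1)],
            neuron_factors=np.zeros((n, 1)),
            eigenvalues=lams[:max(m, 1)] if m else np.array([1.0]),
            graph_degree=deg,
            component_labels=comp,
        )

    # disconnected: indicator coordinates first, then per-component diffusion
    coords = np.zeros((n, n_dims))
    lams = np.zeros(n_dims)
    deg = W.sum(axis=1)
    n_ind = min(n_comp - 1, n_dims)
    for j in range(n_ind):
        ind = (comp == j).astype(float)
        ind -= ind.mean()
        ind /= np.linalg.norm(ind)
        if ind[np.argmax(np.abs(ind))] < 0:
            ind = -ind
        coords[:, j] = ind
        lams[j] = 1.0
    rest = n_dims - n_ind
    if rest > 0:
        per: list[tuple[float, int, np.ndarray]] = []  # (lambda, comp, coord col)
        for c in range(n_comp):
            idx = np.where(comp == c)[0]
            if idx.size < 2:
                continue
            sub_dims = min(rest, idx.size - 1)
            sub_coords, sub_lams, _ = _embed_component(
                W[np.ix_(idx, idx)], sub_dims, diffusion_time
            )
            for j in range(sub_dims):
                if sub_lams[j] > 0:
                    col = np.zeros(n)
                    col[idx] = sub_coords[:, j]
                    per.append((float(sub_lams[j]), c, col))
        per.sort(key=lambda x: (-x[0], x[1]))
        for j, (lam, _, col) in enumerate(per[:rest]):
            coords[:, n_ind + j] = col
            lams[n_ind + j] = lam
    m = int(np.sum(lams > 0))
    return EncodingManifold(
        embedding=coords[:, :max(m, 1)],
        neuron_factors=np.zeros((n, 1)),
        eigenvalues=lams[:max(m, 1)] if m else np.array([1.0]),
        graph_degree=deg,
        component_labels=comp,
    )


# ---------------------------------------------------------------------------
# Topology statistics
# ---------------------------------------------------------------------------

def topology_stats(
    manifold: EncodingManifold,
    labels=None,
    k_graph: int = 10,
    max_clusters: int = 10,
    seed: int = 0,
) -> dict:
    """Summarise whether an embedding is clustered or continuous.

    Returns a dict with ``n_components`` (connected components of the
    symmetrised k-NN graph on the embedding), ``gap_ratio`` (mean nearest
    other-cluster distance over mean nearest same-cluster distance, clusters
    from seeded k-means at the silhouette-optimal k), ``n_clusters`` and —
    when reference ``labels`` are given — ``label_ari``.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score, silhouette_score
    from sklearn.neighbors import kneighbors_graph

    X = manifold.embedding
    n = X.shape[0]
    if n < 3:
        raise ValidationError("topology_stats needs at least 3 points")

    k = min(k_graph, n - 1)
    G = kneighbors_graph(X, n_neighbors=k, mode="connectivity")
    n_components, _ = connected_components(G, directed=False)

    n_distinct = np.unique(X, axis=0).shape[0]
    best_k, best_sil, best_assign = 2, -np.inf, None
    for kk in range(2, min(max_clusters, n_distinct, n - 1) + 1):
        km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        sil = silhouette_score(X, km.labels_)
        if sil > best_sil:
            best_k, best_sil, best_assign = kk, sil, km.labels_

    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    same = best_assign[:, None] == best_assign[None, :]
    with np.errstate(invalid="ignore"):
        within = np.where(same, d, np.inf).min(axis=1)
        between = np.where(~same, d, np.inf).min(axis=1)
    within = within[np.isfinite(within)]
    between = between[np.isfinite(between)]
    if not (within.size and between.size):
        gap_ratio = 0.0
    elif within.mean() == 0:  # exactly duplicated points within clusters
        gap_ratio = float(np.inf)
    else:
        gap_ratio = float(between.mean() / within.mean())

    out = {
        "n_components": int(n_components),
        "gap_ratio": gap_ratio,
        "n_clusters": int(best_k),
        "silhouette": float(best_sil),
    }
    if labels is not None:
        out["label_ari"] = float(adjusted_rand_score(np.asarray(labels), best_assign))
    return out


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class EncodingModel:
    """Encoding-manifold analysis of a response tensor.

    Parameters
    ----------
    tensor : ResponseTensor
    rank : int or "auto"
        CP rank; "auto" uses the elbow rule of :func:`select_rank`.
    normalization : {"per-neuron-max", "none"}
    k_neighbors : int
        Adaptive-kernel neighbour index (local bandwidth).
    n_dims : int
        Embedding dimensions to retain.
    """

    def __init__(
        self,
        tensor: ResponseTensor,
        rank="auto",
        normalization: str = "per-neuron-max",
        k_neighbors: int = 7,
        n_dims: int = 3,
        diffusion_time: int = 1,
        n_restarts: int = 5,
        seed: int = 0,
    ):
        self.tensor = tensor
        self.rank = rank
        self.normalization = normalization
        self.k_neighbors = k_neighbors
        self.n_dims = n_dims
        self.diffusion_time = diffusion_time
        self.n_restarts = n_restarts
        self.seed = seed

    def fit(self) -> "EncodingResults":
        arr, all_zero = encoding_tensor(self.tensor, self.normalization)
        keep = ~all_zero
        arr = arr[keep]
        kept_ids = [nid for nid, k in zip(self.tensor.neuron_ids, keep) if k]
        if arr.shape[0] < 3:
            raise ValidationError("too few active neurons for an encoding manifold")
        rank = (
            select_rank(arr, seed=self.seed)
            if self.rank == "auto"
            else int(self.rank)
        )
        ntf = ntf_decompose(arr, rank, n_restarts=self.n_restarts, seed=self.seed)
        k = min(self.k_neighbors, arr.shape[0] - 1)
        W = neuron_similarity_graph(ntf.neuron_factors, k=k)
        manifold = diffusion_embedding(
            W, n_dims=min(self.n_dims, arr.shape[0] - 1), diffusion_time=self.diffusion_time
        )
        manifold.neuron_factors = ntf.neuron_factors
        manifold.neuron_ids = kept_ids
        return EncodingResults(self, ntf, W, manifold, excluded=list(np.where(all_zero)[0]))


class EncodingResults:
    """Fitted encoding manifold: factors, affinity graph and embedding."""

    def __init__(self, model, ntf, affinity, manifold, excluded):
        self.model = model
        self.ntf: NTFDecomposition = ntf
        self.affinity = affinity
        self.manifold: EncodingManifold = manifold
        self.excluded_neurons = excluded

    def topology(self, labels=None, **kw) -> dict:
        return topology_stats(self.manifold, labels=labels, **kw)

    def summary(self) -> str:
        m = self.manifold
        lines = [
            "Encoding analysis",
            "=" * 40,
            f"neurons embedded:    {m.n_neurons}"
            + (f" ({len(self.excluded_neurons)} all-zero excluded)" if self.excluded_neurons else ""),
            f"CP rank:             {self.ntf.rank}",
            f"CP relative error:   {self.ntf.rel_error:.4f}",
            f"embedding dims:      {m.embedding.shape[1]}",
            "eigenvalues:         " + ", ".join(f"{v:.3f}" for v in m.eigenvalues),
            f"graph components:    {len(np.unique(m.component_labels))}",
        ]
        return "\n".join(lines)
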