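"""Spherical k-means clustering with cosine distance.

Standard k-means measures dissimilarity by squared Euclidean distance
(x - y)'(x - y); the spherical variant replaces it with cosine distance

    D_C(x, y) = 1 - x'y / (||x|| ||y||),

which is invariant to vector length and hence natural for L2-normalized
text embeddings.  On unit-norm data the two metrics rank candidate
centroids identically (||x - c||^2 = 2 D_C(x, c) for unit c), so the
point-to-cluster assignments coincide; the algorithms differ in the
centroid update, where spherical mode re-normalizes the member mean
back onto the unit sphere.

Bag-of-Terms vectors are intentionally not normalized (their L1 norm
carries information), so they are clustered in ``euclidean`` mode.

Multi-restart behaviour follows the usual protocol: ``n_init``
independent random initializations, keeping the solution with the
smallest total within-cluster distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingMatrix

MAX_ITER = 300


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cos(angle between x and y); range [0, 2]."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(x, y) / (nx * ny))


@dataclass
class ClusteringResult:
    """Output of one (best-of-restarts) k-means fit.

    ``soft`` holds the full n x k matrix of mode-distances to every
    centroid; ``assignment`` is its row-wise argmin; ``objective`` the
    sum over points of the distance to their own centroid.
    """

    centroids: np.ndarray
    assignment: np.ndarray
    soft: np.ndarray
    objective: float
    n_init_used: int
    seed: int
    mode: str
    n_iter: int
    converged: bool

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _distances(X: np.ndarray, centroids: np.ndarray, mode: str) -> np.ndarray:
    """n x k matrix of mode-distances from rows of X to centroids."""
    if mode == "spherical":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        cnorms = np.linalg.norm(centroids, axis=1, keepdims=True).T
        return 1.0 - (X @ centroids.T) / (norms * cnorms)
    # squared L2
    sq = (
        np.sum(X**2, axis=1, keepdims=True)
        - 2.0 * X @ centroids.T
        + np.sum(centroids**2, axis=1)
    )
    return np.maximum(sq, 0.0)


def _update_centroids(
    X: np.ndarray, assignment: np.ndarray, k: int, mode: str, old: np.ndarray
) -> np.ndarray:
    centroids = old.copy()
    for j in range(k):
        members = X[assignment == j]
        if members.shape[0] == 0:
            continue  # handled by the empty-cluster re-seed
        mean = members.mean(axis=0)
        if mode == "spherical":
            norm = np.linalg.norm(mean)
            # a zero mean (perfectly antipodal members) keeps the old centroid
            centroids[j] = mean / norm if norm > 1e-12 else old[j]
        else:
            centroids[j] = mean
    return centroids


def _lloyd(
    X: np.ndarray, k: int, mode: str, rng: np.random.Generator, debug: bool = False
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    assignment = np.full(n, -1, dtype=np.int64)
    prev_obj = np.inf
    converged = False
    for it in range(1, MAX_ITER + 1):
        dist = _distances(X, centroids, mode)
        new_assignment = np.argmin(dist, axis=1)  # ties -> lowest index
        # re-seed empty clusters with the point farthest from its centroid
        for j in range(k):
            if not np.any(new_assignment == j):
                own = dist[np.arange(n), new_assignment]
                far = int(np.argmax(own))
                centroids[j] = X[far]
                dist = _distances(X, centroids, mode)
                new_assignment = np.argmin(dist, axis=1)
        obj = float(dist[np.arange(n), new_assignment].sum())
        if debug and obj > prev_obj + 1e-9:
            raise AssertionError("k-means objective increased across iterations")
        prev_obj = obj
        if np.array_equal(new_assignment, assignment):
            converged = True
            assignment = new_assignment
            break
        assignment = new_assignment
        centroids = _update_centroids(X, assignment, k, mode, centroids)
    dist = _distances(X, centroids, mode)
    assignment = np.argmin(dist, axis=1)
    obj = float(dist[np.arange(n), assignment].sum())
    return centroids, assignment, obj, it, converged


def spherical_kmeans(
    X: EmbeddingMatrix,
    k: int,
    n_init: int = 10,
    seed: int = 0,
    mode: str = "spherical",
    debug: bool = False,
) -> ClusteringResult:
    """Best-of-``n_init`` Lloyd-style k-means under the chosen metric.

    Spherical mode requires honestly unit-normalized input
    (``X.normalized`` is trusted and enforced).  Restart seeds are
    derived from ``seed`` via a counter so results are reproducible.
    """
    if mode not in ("spherical", "euclidean"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "spherical" and not X.normalized:
        raise ValueError("spherical mode requires L2-normalized embeddings")
    n = X.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, n={n}]")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    data = X.values
    best = None
    for restart, child in enumerate(np.random.SeedSequence(seed).spawn(n_init)):
        rng = np.random.default_rng(child)
        centroids, assignment, obj, n_iter, converged = _lloyd(
            data, k, mode, rng, debug=debug
        )
        if best is None or obj < best[2] - 1e-12:
            best = (centroids, assignment, obj, n_iter, converged)
    centroids, assignment, obj, n_iter, converged = best
    if mode == "spherical":
        centroids = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    soft = _distances(data, centroids, mode)
    return ClusteringResult(
        centroids=centroids,
        assignment=np.argmin(soft, axis=1),
        soft=soft,
        objective=float(soft[np.arange(n), np.argmin(soft, axis=1)].sum()),
        n_init_used=n_init,
        seed=seed,
        mode=mode,
        n_iter=n_iter,
        converged=converged,
    )


def soft_membership(X: EmbeddingMatrix, result: ClusteringResult) -> np.ndarray:
    """Distances from each row of X to every centroid (n x k).

    This is the feature block the predictive models consume: for a
    record, the vector of mode-distances to the k cluster centres.
    Works for held-out rows, projecting them onto training centroids.
    """
    if X.dimension != result.centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has d={X.dimension}, "
            f"centroids have d={result.centroids.shape[1]}"
        )
    return _distances(X.values, result.centroids, result.mode)


def hard_membership(result: ClusteringResult) -> np.ndarray:
    """One-hot encoding of the hard assignments (n x k binary)."""
    n = result.assignment.shape[0]
    onehot = np.zeros((n, result.k), dtype=np.float64)
    onehot[np.arange(n), result.assignment] = 1.0
    return onehot


def serialize_result(result: ClusteringResult) -> dict:
    """JSON-ready summary (arrays as nested lists)."""
    return {
        "mode": result.mode,
        "k": result.k,
        "seed": result.seed,
        "n_init_used": result.n_init_used,
        "objective": result.objective,
        "converged": result.converged,
        "n_iter": result.n_iter,
        "assignment": result.assignment.tolist(),
        "centroids": result.centroids.tolist(),
    }
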