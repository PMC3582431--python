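"""Choosing the relevance units: K-means + AIC, and the kernel-width rule.

The number of relevance units M is selected by clustering the *unlabeled*
training features into M groups for each candidate M and scoring each
clustering with an AIC under a hard-assignment isotropic Gaussian mixture
(shared variance, mixing weights n_m/N).  The M with the best (lowest) AIC
wins; its cluster centers become the relevance units shared by every binary
classifier of one multiclass model.  The Gaussian kernel width is then set
from the spread of those centers: gamma = 1 / (2 d_max^2) with d_max the
maximum pairwise distance between centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

__all__ = [
    "ClusteringResult",
    "kmeans_centers",
    "clustering_aic",
    "select_complexity",
    "compute_gamma",
    "default_m_grid",
]


@dataclass
class ClusteringResult:
    centers: np.ndarray  # (M, d)
    assignments: np.ndarray  # (N,)
    sse: float  # within-cluster sum of squared distances

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.min(initial=0) < 0 or (
            self.assignments.size and self.assignments.max() >= self.centers.shape[0]
        ):
            raise ValueError("assignments index outside centers")
        if self.sse < 0:
            raise ValueError("sse must be nonnegative")

    @property
    def M(self) -> int:
        return self.centers.shape[0]


def kmeans_centers(features, M: int, seed: int = 0, restarts: int = 5) -> ClusteringResult:
    """Lloyd's K-means, best of ``restarts`` seeded random initializations.

    Initial centers are sampled uniformly from the data points; the restart
    with the smallest within-cluster SSE wins.  Deterministic given the seed.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    N = X.shape[0]
    if not 1 <= M <= N:
        raise ValueError(f"M must lie in [1, {N}], got {M}")
    km = KMeans(
        n_clusters=M, init="random", n_init=restarts,
        random_state=seed, algorithm="lloyd",
    ).fit(X)
    return ClusteringResult(
        centers=km.cluster_centers_,
        assignments=km.labels_,
        sse=float(km.inertia_),
    )


def clustering_aic(result: ClusteringResult, features) -> float:
    """AIC of a clustering under a hard-assigned isotropic Gaussian mixture.

    The model has M means (M*d parameters), M-1 free mixing proportions
    n_m/N, and one shared variance sigma^2 = SSE / (N*d):

        logL = sum_m n_m ln(n_m/N) - (N*d/2) (ln(2 pi sigma^2) + 1)
        AIC  = 2P - 2 logL,   P = M*d + (M - 1) + 1
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    N, d = X.shape
    if result.assignments.size != N:
        raise ValueError("clustering was not produced from these features")
    if result.sse <= 0.0:
        raise ValueError(
            "SSE is zero: the variance of the probabilistic interpretation is "
            "degenerate; cap the M grid below the number of distinct points"
        )
    M = result.M
    counts = np.bincount(result.assignments, minlength=M)
    nz = counts[counts > 0]
    sigma2 = result.sse / (N * d)
    loglik = float(np.sum(nz * np.log(nz / N))) - 0.5 * N * d * (
        np.log(2.0 * np.pi * sigma2) + 1.0
    )
    n_params = M * d + (M - 1) + 1
    return 2.0 * n_params - 2.0 * loglik


def select_complexity(
    features, M_grid, seed: int = 0, restarts: int = 5
) -> tuple[int, ClusteringResult]:
    """Pick the grid member with the lowest clustering AIC (ties: smallest M)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    grid = sorted(set(int(m) for m in M_grid))
    if not grid:
        raise ValueError("M grid is empty")
    if grid[-1] > X.shape[0]:
        raise ValueError("M grid exceeds the number of instances")
    best: tuple[float, int, ClusteringResult] | None = None
    for M in grid:
        res = kmeans_centers(X, M, seed=seed, restarts=restarts)
        aic = clustering_aic(res, X)
        if best is None or aic < best[0] - 1e-12:
            best = (aic, M, res)
    assert best is not None
    return best[1], best[2]


def compute_gamma(centers) -> float:
    """Kernel width from the cluster-center spread: gamma = 1 / (2 d_max^2)."""
    C = np.atleast_2d(np.asarray(centers, dtype=float))
    if C.shape[0] < 2:
        raise ValueError("need at least two centers to set the kernel width")
    d_max = float(pdist(C).max())
    if d_max <= 0.0:
        raise ValueError("all centers coincide; kernel width undefined")
    return 1.0 / (2.0 * d_max * d_max)


def default_m_grid(n: int, cap: int = 512) -> list[int]:
    """Doubling grid {2, 4, 8, ...} capped at min(cap, n // 2)."""
    top = min(cap, n // 2)
    grid = []
    m = 2
    while m <= top:
        grid.append(m)
        m *= 2
    return grid or [min(2, n)]
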