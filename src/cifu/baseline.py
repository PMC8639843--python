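"""Comparative non-functional clustering of the raw grid points.

Runs k-means, k-medoids (PAM) and a Gaussian mixture directly on the
180-dimensional grid values — treating the samples as points, not curves —
over a range of K, picking K by the Average Silhouette Width (ASW) and
reporting the Dunn index of the chosen partition as a separation measure.
These baselines serve as the contrast to the functional mixture: on cohorts
whose clusters differ in shape but not level they tend to collapse to K=2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .profiles import ProfileSet

logger = logging.getLogger(__name__)

METHODS = ("kmeans", "kmedoids", "gmm")


def silhouette(labels: np.ndarray, data: np.ndarray) -> float:
    """Average silhouette width s̄ = mean_i (b_i − a_i)/max(a_i, b_i).

    a_i is the mean distance to the own cluster, b_i the smallest mean
    distance to another cluster; singleton clusters contribute s_i = 0
    (scikit-learn's convention, matching the classical definition).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(silhouette_score(np.asarray(data, dtype=float), labels))


def dunn_index(labels: np.ndarray, data: np.ndarray) -> float:
    """min between-cluster point separation / max within-cluster diameter."""
    labels = np.asarray(labels)
    data = np.asarray(data, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    D = squareform(pdist(data))
    max_diam = 0.0
    for u in uniq:
        idx = np.flatnonzero(labels == u)
        if len(idx) > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    if max_diam == 0.0:
        raise ValueError("all intra-cluster diameters are zero; Dunn undefined")
    min_sep = np.inf
    for i, u in enumerate(uniq):
        for v in uniq[i + 1:]:
            iu = np.flatnonzero(labels == u)
            iv = np.flatnonzero(labels == v)
            min_sep = min(min_sep, float(D[np.ix_(iu, iv)].min()))
    return min_sep / max_diam


def _pam(data: np.ndarray, K: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning Around Medoids: greedy BUILD then SWAP to a local optimum
    of the total distance-to-medoid cost (Euclidean)."""
    n = data.shape[0]
    D = squareform(pdist(data))
    # BUILD: first medoid minimizes total distance; then greedy gain
    medoids = [int(D.sum(axis=1).argmin())]
    while len(medoids) < K:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    medoids_arr = np.array(medoids)
    for _ in range(max_iter):
        dist_to_med = D[:, medoids_arr]
        cost = dist_to_med.min(axis=1).sum()
        best_swap = None
        best_cost = cost
        non_medoids = np.setdiff1d(np.arange(n), medoids_arr)
        for mi in range(K):
            trial = medoids_arr.copy()
            others = np.delete(medoids_arr, mi)
            d_others = D[:, others].min(axis=1) if len(others) else np.full(n, np.inf)
            for h in non_medoids:
                new_cost = np.minimum(d_others, D[:, h]).sum()
                if new_cost < best_cost - 1e-12:
                    best_cost = new_cost
                    best_swap = (mi, h)
        if best_swap is None:
            break
        medoids_arr[best_swap[0]] = best_swap[1]
    return D[:, medoids_arr].argmin(axis=1)


@dataclass
class BaselineRun:
    """One baseline method scanned over K with ASW-based selection."""

    method: str
    K_values: list[int]
    labels: dict[int, np.ndarray]
    asw: dict[int, float]
    chosen_K: int
    dunn: float

    @property
    def chosen_labels(self) -> np.ndarray:
        return self.labels[self.chosen_K]


def cluster_points(
    profiles: ProfileSet | np.ndarray,
    method: str = "kmeans",
    K_range=range(2, 11),
    seed: int | None = None,
) -> BaselineRun:
    """Run a point-cloud clustering method over K_range; choose K by max ASW.

    kmeans: Lloyd with k-means++ and 10 restarts; kmedoids: PAM (BUILD+SWAP);
    gmm: EM with diagonal/spherical covariances chosen per K by BIC.
    """
    data = profiles.values if isinstance(profiles, ProfileSet) else np.asarray(profiles)
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    K_values = list(K_range)
    n = data.shape[0]
    if n <= max(K_values):
        raise ValueError(f"need n > max K, got n={n}")
    if np.unique(data, axis=0).shape[0] <= max(K_values):
        raise ValueError("too few distinct rows to cluster over this K range")
    rng = np.random.default_rng(seed)
    labels: dict[int, np.ndarray] = {}
    asw: dict[int, float] = {}
    for K in K_values:
        rs = int(rng.integers(2**31 - 1))
        if method == "kmeans":
            lab = KMeans(n_clusters=K, n_init=10, random_state=rs).fit_predict(data)
        elif method == "kmedoids":
            lab = _pam(data, K)
        else:
            best = None
            for cov in ("diag", "spherical"):
                gm = GaussianMixture(
                    n_components=K, covariance_type=cov, n_init=3,
                    random_state=rs, reg_covar=1e-8,
                ).fit(data)
                if best is None or gm.bic(data) < best.bic(data):
                    best = gm
            lab = best.predict(data)
        labels[K] = lab
        if len(np.unique(lab)) < 2:
            asw[K] = -1.0
        else:
            asw[K] = silhouette(lab, data)
    chosen = max(K_values, key=lambda K: (asw[K], -K))
    return BaselineRun(
        method=method,
        K_values=K_values,
        labels=labels,
        asw=asw,
        chosen_K=chosen,
        dunn=dunn_index(labels[chosen], data),
    )


def run_baselines(
    profiles: ProfileSet, K_range=range(2, 11), seed: int | None = None
) -> dict[str, BaselineRun]:
    rng = np.random.default_rng(seed)
    return {
        m: cluster_points(profiles, m, K_range, seed=int(rng.integers(2**31 - 1)))
        for m in METHODS
    }
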