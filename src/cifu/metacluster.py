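"""Sparse hierarchical metaclustering of functional clusters on clinical covariates.

The functional clusters found within an age stratum are themselves clustered
("metaclustered") on their mean clinical covariate vectors.  Feature
selection happens simultaneously: a nonnegative weight vector w over the
covariates with ‖w‖₂ ≤ 1 and ‖w‖₁ ≤ wbound is optimized so that the
weighted dissimilarity matrix carries as much of the between-row structure
as possible (the sparse clustering criterion of Witten & Tibshirani).  The
weighted dissimilarity then feeds a complete-linkage agglomeration; flat
cuts at a common normalized height give the metaclusters, and metaclusters
are matched across age strata on the top-weighted covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .profiles import COVARIATE_NAMES, CovariateTable

logger = logging.getLogger(__name__)


@dataclass
class ClusterCovariateMatrix:
    """Mean covariate vector per functional cluster (rows), with sizes.

    ``scale`` (optional) holds the pooled within-cluster sd of each covariate
    at the sample level; when present, dissimilarities are computed on
    standardized effect sizes (cluster-mean differences in units of that sd)
    rather than on row-z-scored columns.
    """

    means: pd.DataFrame            # index = cluster id, columns = covariates
    sizes: pd.Series               # index = cluster id
    scale: pd.Series | None = None  # per-covariate pooled within-cluster sd

    @property
    def q(self) -> int:
        return self.means.shape[1]


def cluster_covariate_means(
    sample_ids: np.ndarray,
    labels: np.ndarray,
    covariates: CovariateTable,
    covariate_list: tuple[str, ...] = COVARIATE_NAMES,
) -> ClusterCovariateMatrix:
    """Row k = mean covariate vector over the samples in cluster k.

    Missing covariate values are excluded pairwise (with a warning); a
    cluster with no covariate coverage at all is an error.
    """
    use = [c for c in covariate_list if c in covariates.covariates]
    if not use:
        raise ValueError("none of the requested covariates are in the table")
    df = covariates.loc(np.asarray(sample_ids))[use].copy()
    if df.isna().any().any():
        logger.warning(
            "missing covariate values excluded pairwise (%d cells)",
            int(df.isna().sum().sum()),
        )
    df["_cluster"] = np.asarray(labels)
    grouped = df.groupby("_cluster")
    means = grouped.mean()
    sizes = grouped.size()
    empty = means.index[means.isna().all(axis=1)]
    if len(empty):
        raise ValueError(f"clusters with zero covariate coverage: {list(empty)}")
    means.index.name = "cluster"
    # pooled within-cluster sd: the natural per-covariate scale for comparing
    # cluster means across covariates with incommensurate units
    resid = df[use] - means.loc[df["_cluster"]].to_numpy()
    dof = max(len(df) - len(sizes), 1)
    scale = np.sqrt((resid**2).sum(axis=0) / dof)
    if (scale == 0).any():
        # degenerate (e.g. single-sample clusters): fall back to overall sd
        overall = df[use].std(ddof=0)
        scale = scale.where(scale > 0, overall)
    return ClusterCovariateMatrix(means=means, sizes=sizes, scale=scale)


@dataclass
class MetaclusterResult:
    """Sparse-clustering output for one stratum."""

    weights: pd.Series           # per covariate, descending-informative
    dissimilarity: np.ndarray    # condensed weighted dissimilarity
    linkage_matrix: np.ndarray   # scipy linkage (complete)
    wbound: float
    objective: float             # Σ_j w_j a_j at convergence
    objective_trace: list[float]
    cluster_ids: np.ndarray      # row labels (functional cluster ids)
    sizes: pd.Series

    def metacluster_labels(self, height: float = 0.1,
                           rescale: bool = True) -> pd.Series:
        return cut_tree(self, height=height, rescale=rescale)


def _per_feature_dissimilarity(X: np.ndarray) -> np.ndarray:
    """(n_pairs, q) matrix of squared per-feature differences."""
    n, q = X.shape
    iu, ju = np.triu_indices(n, k=1)
    return (X[iu] - X[ju]) ** 2


def _soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    return np.maximum(a - delta, 0.0)


def _weights_for_bound(a: np.ndarray, wbound: float) -> np.ndarray:
    """w = S(a, Δ)/‖S(a, Δ)‖₂ with the smallest Δ ≥ 0 making ‖w‖₁ ≤ wbound."""
    a = np.maximum(a, 0.0)
    if not np.any(a > 0):
        return np.full_like(a, 1.0 / np.sqrt(len(a)))

    def l1_of(delta: float) -> float:
        w = _soft_threshold(a, delta)
        nrm = np.linalg.norm(w)
        return w.sum() / nrm if nrm > 0 else 0.0

    if l1_of(0.0) <= wbound:
        w = a / np.linalg.norm(a)
        return w
    lo, hi = 0.0, a.max()
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if l1_of(mid) > wbound:
            lo = mid
        else:
            hi = mid
    w = _soft_threshold(a, hi)
    return w / np.linalg.norm(w)


def sparse_hclust(
    M: ClusterCovariateMatrix,
    wbound: float,
    linkage_method: str = "complete",
    standardize: bool = True,
    max_iter: int = 30,
    tol: float = 1e-4,
) -> MetaclusterResult:
    """Complete-linkage hierarchical clustering with L1-sparse feature weights.

    Alternates u ∝ D w (unit norm over row pairs) and the soft-thresholded
    w maximizing Σ_j w_j (Dᵀu)_j under ‖w‖₂ ≤ 1, ‖w‖₁ ≤ wbound, w ≥ 0,
    then agglomerates the weighted dissimilarity Σ_j w_j d_{pair,j}.

    Standardization (the nine covariates carry incommensurate units): when
    the matrix carries a pooled within-cluster ``scale``, columns are divided
    by it, so dissimilarities compare standardized effect sizes and
    covariates that barely separate the clusters relative to their natural
    variability get little weight.  Without a scale, columns are z-scored
    across rows; zero-variance columns get zero weight either way.
    """
    if wbound < 1:
        raise ValueError("wbound must be >= 1")
    X = M.means.to_numpy(dtype=float)
    n, q = X.shape
    if n < 2 or q < 2:
        raise ValueError("need >= 2 clusters and >= 2 covariates")
    if standardize and M.scale is not None:
        sc = M.scale.reindex(M.means.columns).to_numpy(dtype=float)
        keep = np.isfinite(sc) & (sc > 0)
        if not keep.all():
            logger.warning(
                "covariates without a positive scale get zero weight: %s",
                list(M.means.columns[~keep]),
            )
        Xs = np.where(keep, (X - X.mean(axis=0)) / np.where(keep, sc, 1.0), 0.0)
    elif standardize:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "zero-variance covariates get zero weight: %s",
                list(M.means.columns[~keep]),
            )
        Xs = np.where(keep, (X - X.mean(axis=0)) / np.where(keep, sd, 1.0), 0.0)
    else:
        Xs = X
    D = _per_feature_dissimilarity(Xs)        # (n_pairs, q)
    if not np.any(D > 0):
        raise ValueError("all pairwise dissimilarities are zero")

    w = np.full(q, 1.0 / np.sqrt(q))
    objective_trace: list[float] = []
    for _ in range(max_iter):
        u = D @ w
        u_norm = np.linalg.norm(u)
        if u_norm == 0:
            raise ValueError("degenerate weighted dissimilarity (all zero)")
        u = u / u_norm
        a = D.T @ u
        w_new = _weights_for_bound(a, wbound)
        objective_trace.append(float(w_new @ a))
        if np.abs(w_new - w).sum() < tol:
            w = w_new
            break
        w = w_new
    dw = D @ w
    Z = linkage(dw, method=linkage_method)
    weights = pd.Series(w, index=M.means.columns).sort_values(ascending=False)
    return MetaclusterResult(
        weights=weights,
        dissimilarity=dw,
        linkage_matrix=Z,
        wbound=wbound,
        objective=objective_trace[-1],
        objective_trace=objective_trace,
        cluster_ids=M.means.index.to_numpy(),
        sizes=M.sizes,
    )


def cut_tree(result: MetaclusterResult, height: float = 0.1,
             rescale: bool = True) -> pd.Series:
    """Flat cut of the dendrogram at `height`.

    Heights are first rescaled so the root merge sits at 1, making a common
    threshold (default 0.1) comparable across strata with different raw
    dissimilarity scales.
    """
    Z = result.linkage_matrix.copy()
    root = Z[:, 2].max()
    if rescale and root > 0:
        Z[:, 2] = Z[:, 2] / root
    labels = fcluster(Z, t=height, criterion="distance")
    return pd.Series(labels, index=result.cluster_ids, name="metacluster")


def select_wbound(
    M: ClusterCovariateMatrix,
    wbounds=(2.0, 3.0, 4.0, 5.0),
    n_perm: int = 25,
    seed: int | None = None,
    **kwargs,
) -> tuple[float, pd.DataFrame]:
    """Pick wbound by the permutation gap statistic.

    gap(s) = log O(s) − mean_perm log O*(s), where O is the sparse-clustering
    objective on the data and O* on data with each covariate column permuted
    independently (destroying the joint structure).
    """
    rng = np.random.default_rng(seed)
    X = M.means.to_numpy(dtype=float)
    perms = []
    for _ in range(n_perm):
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        perms.append(
            ClusterCovariateMatrix(
                means=pd.DataFrame(Xp, index=M.means.index, columns=M.means.columns),
                sizes=M.sizes,
            )
        )
    rows = []
    for s in wbounds:
        obs = sparse_hclust(M, wbound=s, **kwargs).objective
        null = [np.log(sparse_hclust(Mp, wbound=s, **kwargs).objective)
                for Mp in perms]
        rows.append({"wbound": s, "objective": obs,
                     "gap": float(np.log(obs) - np.mean(null))})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["gap"].idxmax(), "wbound"])
    return best, table


def correspond_metaclusters(
    results: dict[int, MetaclusterResult],
    matrices: dict[int, ClusterCovariateMatrix],
    key_covariates: tuple[str, ...] = ("average_cdr", "cup_volume"),
    height: float = 0.1,
) -> dict[int, dict[int, int]]:
    """Match metaclusters across strata on the key covariates.

    Each metacluster is summarized by the size-weighted mean of its member
    clusters' covariate means on `key_covariates`; matching to the first
    stratum is greedy by ascending distance, and metaclusters beyond the
    smaller stratum's count get fresh "distinct" global labels.

    Returns stratum -> {local metacluster id -> global label}.
    """
    if len(results) < 2:
        raise ValueError("need at least two strata to correspond")

    def centers(stratum: int) -> dict[int, np.ndarray]:
        res = results[stratum]
        M = matrices[stratum]
        labels = cut_tree(res, height=height)
        out = {}
        for mc in np.unique(labels):
            ids = labels.index[labels == mc]
            w = M.sizes.loc[ids].to_numpy(dtype=float)
            V = M.means.loc[ids, list(key_covariates)].to_numpy(dtype=float)
            out[int(mc)] = (w @ V) / w.sum()
        return out

    strata = sorted(results)
    ref = strata[0]
    ref_centers = centers(ref)
    mapping: dict[int, dict[int, int]] = {ref: {mc: mc for mc in ref_centers}}
    next_label = max(ref_centers) + 1
    for s in strata[1:]:
        cs = centers(s)
        pairs = sorted(
            ((np.linalg.norm(cs[a] - ref_centers[b]), a, b)
             for a in cs for b in ref_centers)
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        local_map: dict[int, int] = {}
        for _, a, b in pairs:
            if a in used_a or b in used_b:
                continue
            local_map[a] = b
            used_a.add(a)
            used_b.add(b)
        for a in cs:
            if a not in local_map:
                local_map[a] = next_label
                next_label += 1
        mapping[s] = local_map
    return mapping
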