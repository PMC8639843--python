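"""Discriminative functional mixture (DFM) clustering of basis coefficients.

The coefficient vectors γ_i ∈ R^p follow a K-component Gaussian mixture
whose cluster structure lives in a low-dimensional discriminative subspace
spanned by an orthonormal U (p × d, d < p):

    f(γ) = Σ_k π_k N(γ; U μ_k, U Σ_k Uᵀ + Ξ),   Ξ = β (I − U Uᵀ),

i.e. cluster means and covariances Σ_k act inside the subspace while the
residual orthogonal energy is isotropic noise with variance β (per cluster
or shared).  Twelve model variants arise from constraining Σ_k
(full/diagonal/isotropic × cluster-specific/common) crossed with the noise
(cluster-specific/common).  Fitting alternates an E-step (responsibilities),
an F-step updating U from the generalized eigenproblem of the soft
between-cluster scatter against the total scatter (a Fisher criterion), and
an M-step for (π, μ, Σ, β) under the variant's constraints.  Model choice
uses AIC/BIC/ICL in maximize orientation, and the number of clusters is the
elbow of the BIC trace.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .basis import CoefficientSet

logger = logging.getLogger(__name__)

_RIDGE = 1e-8


@dataclass(frozen=True)
class DFMVariant:
    """One of the 12 covariance-constraint variants.

    latent: structure of the within-subspace covariance Σ_k
        ("full" | "diag" | "iso"); latent_shared pools Σ over clusters;
    noise_shared pools the residual variance β over clusters.
    """

    latent: str
    latent_shared: bool
    noise_shared: bool

    def __post_init__(self) -> None:
        if self.latent not in ("full", "diag", "iso"):
            raise ValueError(f"unknown latent structure {self.latent!r}")

    @property
    def code(self) -> str:
        lat = ("" if self.latent_shared else "k-") + self.latent
        noi = "common" if self.noise_shared else "per-cluster"
        return f"{lat}/{noi}-noise"


ALL_VARIANTS: tuple[DFMVariant, ...] = tuple(
    DFMVariant(latent, ls, ns)
    for latent, ls, ns in itertools.product(
        ("full", "diag", "iso"), (False, True), (False, True)
    )
)


def count_params(variant: DFMVariant, K: int, p: int, d: int) -> int:
    """Free-parameter count m of a variant: mixing + means + Stiefel subspace
    + latent covariance + noise."""
    m = (K - 1) + K * d + (p * d - d * (d + 1) // 2)
    if variant.latent == "full":
        lat = d * (d + 1) // 2
    elif variant.latent == "diag":
        lat = d
    else:
        lat = 1
    m += lat if variant.latent_shared else K * lat
    m += 1 if variant.noise_shared else K
    return m


@dataclass
class DFMModel:
    """A fitted discriminative functional mixture.

    Fitting operates on centered coefficients (grand mean removed, stored in
    ``center``): the model constrains component means to the subspace, so the
    shared mean curve — which carries no cluster information — is taken out
    first.
    """

    K: int
    d: int
    variant: DFMVariant
    center: np.ndarray         # (p,) grand mean of the coefficients
    U: np.ndarray              # (p, d) orthonormal
    pi: np.ndarray             # (K,)
    mu: np.ndarray             # (K, d)
    Sigma: np.ndarray          # (K, d, d)
    beta: np.ndarray           # (K,) residual variances (equal if shared)
    responsibilities: np.ndarray  # (n, K)
    loglik: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int

    @property
    def p(self) -> int:
        return self.U.shape[0]

    @property
    def n_params(self) -> int:
        return count_params(self.variant, self.K, self.p, self.d)

    @property
    def labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def _component_logpdf(
    gamma: np.ndarray, U: np.ndarray, mu: np.ndarray, Sigma: np.ndarray,
    beta: float,
) -> np.ndarray:
    """log N(γ; Uμ, UΣUᵀ + β(I − UUᵀ)) via the subspace decomposition.

    With y = γ − Uμ split into a = Uᵀy and the orthogonal residual r:
    −2·log = aᵀΣ⁻¹a + ‖r‖²/β + log|Σ| + (p−d)·log β + p·log 2π.
    """
    p, d = U.shape
    y = gamma - (U @ mu)[None, :]
    a = y @ U
    r2 = np.einsum("ij,ij->i", y, y) - np.einsum("ij,ij->i", a, a)
    r2 = np.maximum(r2, 0.0)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("latent covariance not positive definite")
    sol = np.linalg.solve(Sigma, a.T).T
    maha = np.einsum("ij,ij->i", a, sol)
    return -0.5 * (
        maha + r2 / beta + logdet + (p - d) * np.log(beta) + p * np.log(2 * np.pi)
    )


def _log_resp(gamma, model_params):
    U, pi, mu, Sigma, beta = model_params
    K = len(pi)
    lp = np.empty((gamma.shape[0], K))
    for k in range(K):
        lp[:, k] = np.log(pi[k]) + _component_logpdf(
            gamma, U, mu[k], Sigma[k], beta[k]
        )
    norm = logsumexp(lp, axis=1)
    return lp - norm[:, None], norm


def _f_step(gamma: np.ndarray, resp: np.ndarray, d: int) -> np.ndarray:
    """Discriminative subspace: top-d generalized eigenvectors of the soft
    between-cluster scatter against the total scatter, orthonormalized."""
    n, p = gamma.shape
    gbar = gamma.mean(axis=0)
    Xc = gamma - gbar
    S_T = Xc.T @ Xc / n
    nk = resp.sum(axis=0)
    means = (resp.T @ gamma) / nk[:, None]
    dm = means - gbar
    S_B = (dm.T * nk) @ dm / n
    S_T = S_T + _RIDGE * np.trace(S_T) / p * np.eye(p) + _RIDGE * np.eye(p)
    w, v = eigh(S_B, S_T)
    idx = np.argsort(w)[::-1][:d]
    U = v[:, idx]
    U, _ = np.linalg.qr(U)
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


def _m_step(gamma, resp, U, variant: DFMVariant):
    n, p = gamma.shape
    d = U.shape[1]
    K = resp.shape[1]
    nk = resp.sum(axis=0)
    pi = nk / n
    z = gamma @ U                       # (n, d)
    mu = (resp.T @ z) / nk[:, None]
    Sigma = np.empty((K, d, d))
    beta = np.empty(K)
    for k in range(K):
        zc = z - mu[k]
        Ck_lat = (zc.T * resp[:, k]) @ zc / nk[k]
        Sigma[k] = Ck_lat
        gbar_k = (resp[:, k] @ gamma) / nk[k]
        gc = gamma - gbar_k
        tr_full = float(np.einsum("ij,ij,i->", gc, gc, resp[:, k]) / nk[k])
        gcU = gc @ U
        tr_lat = float(np.einsum("ij,ij,i->", gcU, gcU, resp[:, k]) / nk[k])
        beta[k] = max((tr_full - tr_lat) / (p - d), 1e-10)
    if variant.latent_shared:
        pooled = np.einsum("k,kij->ij", pi, Sigma)
        Sigma = np.repeat(pooled[None], K, axis=0)
    if variant.latent == "diag":
        for k in range(K):
            Sigma[k] = np.diag(np.diag(Sigma[k]))
    elif variant.latent == "iso":
        for k in range(K):
            Sigma[k] = np.trace(Sigma[k]) / d * np.eye(d)
    Sigma += _RIDGE * np.eye(d)[None]
    if variant.noise_shared:
        beta[:] = float(pi @ beta)
    return pi, mu, Sigma, beta


class EMFitError(RuntimeError):
    """EM failed on all restarts (e.g. persistent empty clusters)."""


def _em_single(gamma, K, variant, d, init, rng, max_iter, tol):
    n, p = gamma.shape
    center = gamma.mean(axis=0)
    gamma = gamma - center
    if init == "kmeans":
        # initialize in the sphered space: whitening by the total covariance
        # exposes mean separations that shared high-variance directions mask
        w, V = np.linalg.eigh(gamma.T @ gamma / n)
        keep = w > 1e-10 * w.max()  # drop numerically dead directions
        white = gamma @ V[:, keep] / np.sqrt(w[keep])
        km = KMeans(n_clusters=K, n_init=10,
                    random_state=int(rng.integers(2**31 - 1)))
        hard = km.fit_predict(white)
        resp = np.zeros((n, K))
        resp[np.arange(n), hard] = 1.0
        # small smoothing keeps every component alive at the start
        resp = (resp + 1e-3) / (1 + K * 1e-3)
    elif init == "random":
        resp = rng.dirichlet(np.ones(K), size=n)
    else:
        raise ValueError(f"unknown init {init!r}")

    loglik_trace: list[float] = []
    params = None
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nk = resp.sum(axis=0)
        if np.any(nk < 1.0):
            raise EMFitError(f"empty cluster at iteration {it}")
        U = _f_step(gamma, resp, d)
        pi, mu, Sigma, beta = _m_step(gamma, resp, U, variant)
        new_params = (U, pi, mu, Sigma, beta)
        log_r, norm = _log_resp(gamma, new_params)
        new_loglik = float(norm.sum())
        if new_loglik < loglik - tol:
            # the F-step is not guaranteed monotone; keep the previous
            # parameters rather than record a decreasing trace
            break
        params = new_params
        gain = new_loglik - loglik
        loglik = new_loglik
        loglik_trace.append(loglik)
        resp = np.exp(log_r)
        if it > 1 and gain < tol:
            converged = True
            break
    if params is None:
        raise EMFitError("EM made no accepted iteration")
    U, pi, mu, Sigma, beta = params
    log_r, _ = _log_resp(gamma, params)
    return DFMModel(
        K=K, d=d, variant=variant, center=center,
        U=U, pi=pi, mu=mu, Sigma=Sigma, beta=beta,
        responsibilities=np.exp(log_r), loglik=loglik,
        loglik_trace=loglik_trace, converged=converged, n_iter=it,
    )


def em_fit(
    coeffs: CoefficientSet | np.ndarray,
    K: int,
    variant: DFMVariant = DFMVariant("full", False, False),
    d: int | None = None,
    init: str = "kmeans",
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> DFMModel:
    """Fit one (K, variant) DFM by EM; best of `n_restarts` by loglik.

    `d` defaults to min(K−1, p−1), the dimension of a K-class Fisher
    discriminant subspace.
    """
    gamma = coeffs.gamma if isinstance(coeffs, CoefficientSet) else np.asarray(coeffs)
    n, p = gamma.shape
    if K < 2:
        raise ValueError("K must be >= 2")
    if n <= K:
        raise ValueError(f"need n > K, got n={n}, K={K}")
    if d is None:
        d = min(K - 1, p - 1)
    if not 1 <= d <= min(p - 1, n - 1):
        raise ValueError(f"latent dimension d={d} invalid for p={p}")
    rng = np.random.default_rng(seed)
    best: DFMModel | None = None
    errors = []
    for _ in range(n_restarts):
        try:
            model = _em_single(gamma, K, variant, d, init, rng, max_iter, tol)
        except (EMFitError, np.linalg.LinAlgError) as exc:
            errors.append(exc)
            continue
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise EMFitError(
            f"all {n_restarts} restarts failed for K={K}, {variant.code}: {errors[-1]}"
        )
    return best


def predict_responsibilities(model: DFMModel, gamma: np.ndarray) -> np.ndarray:
    """Posterior cluster probabilities for (possibly new) coefficient vectors."""
    gamma = np.asarray(gamma, dtype=float) - model.center
    log_r, _ = _log_resp(
        gamma, (model.U, model.pi, model.mu, model.Sigma, model.beta)
    )
    return np.exp(log_r)


def criteria(model: DFMModel, n: int) -> tuple[float, float, float]:
    """(AIC, BIC, ICL) in maximize orientation.

    AIC = ℓ − m;  BIC = ℓ − (m/2)·log n;  ICL = BIC − Σ_ik t_ik log t_ik
    (the entropy term vanishes for hard responsibilities, so ICL ≤ BIC).
    """
    m = model.n_params
    aic = model.loglik - m
    bic = model.loglik - 0.5 * m * np.log(n)
    t = model.responsibilities
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(t > 0, t * np.log(t), 0.0))
    icl = bic - ent
    return float(aic), float(bic), float(icl)


@dataclass
class ClusterSolution:
    """select_K output: chosen K, per-sample labels, full criterion traces."""

    chosen_K: int
    labels: np.ndarray
    model: DFMModel
    trace: pd.DataFrame          # columns: K, variant, loglik, m, AIC, BIC, ICL
    models: dict[int, DFMModel]  # best model (by BIC) per K
    sample_id: np.ndarray | None = None


def _elbow(K_values: np.ndarray, bic: np.ndarray) -> int:
    """Largest second difference of the BIC trace; ties -> smaller K.

    If no K improves on the smallest, the trace is flat/decreasing and the
    smallest K wins outright.
    """
    if len(K_values) == 1:
        return int(K_values[0])
    if bic.argmax() == 0:
        return int(K_values[0])
    if len(K_values) == 2:
        return int(K_values[bic.argmax()])
    d2 = 2 * bic[1:-1] - bic[:-2] - bic[2:]
    best = int(np.argmax(d2))  # argmax takes the first (smallest K) on ties
    return int(K_values[1 + best])


def select_K(
    coeffs: CoefficientSet | np.ndarray,
    K_range=range(2, 13),
    variants: tuple[DFMVariant, ...] = ALL_VARIANTS,
    d: int | None = None,
    seed: int | None = None,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ClusterSolution:
    """Fit all (K, variant) pairs, pick the variant per K by best BIC, then
    choose K at the elbow of the BIC trace.

    The full criterion trace is retained so the automatic elbow can be
    overridden by inspection.
    """
    gamma = coeffs.gamma if isinstance(coeffs, CoefficientSet) else np.asarray(coeffs)
    sample_id = coeffs.sample_id if isinstance(coeffs, CoefficientSet) else None
    n = gamma.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    models: dict[int, DFMModel] = {}
    best_bic: dict[int, float] = {}
    for K in K_range:
        d_K = None if d is None else min(d, K - 1)
        for variant in variants:
            try:
                model = em_fit(
                    gamma, K, variant, d=d_K,
                    seed=int(rng.integers(2**31 - 1)),
                    n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                )
            except EMFitError as exc:
                logger.warning("K=%d %s failed: %s", K, variant.code, exc)
                continue
            aic, bic, icl = criteria(model, n)
            rows.append(
                {"K": K, "variant": variant.code, "loglik": model.loglik,
                 "m": model.n_params, "AIC": aic, "BIC": bic, "ICL": icl}
            )
            if K not in best_bic or bic > best_bic[K]:
                best_bic[K] = bic
                models[K] = model
    if not models:
        raise EMFitError("no (K, variant) combination converged")
    Ks = np.array(sorted(models))
    bic_trace = np.array([best_bic[K] for K in Ks])
    chosen = _elbow(Ks, bic_trace)
    model = models[chosen]
    return ClusterSolution(
        chosen_K=chosen,
        labels=model.labels,
        model=model,
        trace=pd.DataFrame(rows),
        models=models,
        sample_id=sample_id,
    )
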