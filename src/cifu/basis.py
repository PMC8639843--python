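"""Fourier basis representation of circular curves.

A curve on the circle is approximated by the first ``p`` (odd) terms of the
orthonormal Fourier system on [0, 360):

    ψ_1(t) = 1/√360,
    ψ_{2m}(t)   = √(2/360) · sin(2πmt/360),
    ψ_{2m+1}(t) = √(2/360) · cos(2πmt/360),   m = 1..(p-1)/2,

so X_i(t) ≈ Σ_j γ_ij ψ_j(t).  On the evenly spaced grid the least-squares
coefficients coincide with the discrete Fourier projection.  The module also
provides pointwise curve statistics, the total variation (TV) of a curve
set, the fraction of variation explained (FVE) by a p-term approximation,
and the FVE > 0.99 rule for choosing p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import AngularGrid, ProfileSet

logger = logging.getLogger(__name__)

PERIOD = 360.0


@dataclass(frozen=True)
class FourierBasis:
    """Orthonormal Fourier system on the circle of period 360 degrees."""

    p: int
    period: float = PERIOD

    def __post_init__(self) -> None:
        if self.p < 1 or self.p % 2 == 0:
            raise ValueError(f"p must be odd and >= 1, got {self.p}")

    @property
    def n_harmonics(self) -> int:
        return (self.p - 1) // 2

    def design(self, angles: np.ndarray) -> np.ndarray:
        """Evaluate ψ_1..ψ_p at `angles` (degrees); returns (len(angles), p)."""
        t = np.asarray(angles, dtype=float)
        T = self.period
        B = np.empty((t.size, self.p))
        B[:, 0] = 1.0 / np.sqrt(T)
        for m in range(1, self.n_harmonics + 1):
            w = 2.0 * np.pi * m * t / T
            B[:, 2 * m - 1] = np.sqrt(2.0 / T) * np.sin(w)
            B[:, 2 * m] = np.sqrt(2.0 / T) * np.cos(w)
        return B


@dataclass
class CoefficientSet:
    """Basis expansion coefficients γ (n × p) for a set of curves."""

    basis: FourierBasis
    gamma: np.ndarray
    sample_id: np.ndarray
    eye: np.ndarray | None = None
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("non-finite basis coefficients")

    @property
    def n(self) -> int:
        return self.gamma.shape[0]

    @property
    def p(self) -> int:
        return self.gamma.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"gamma_{j}" for j in range(1, self.p + 1)]
        df = pd.DataFrame(self.gamma, columns=cols)
        df.insert(0, "sample_id", self.sample_id)
        return df


@dataclass
class CurveStats:
    """Pointwise mean/sd over a curve set, and its total variation."""

    mean_curve: np.ndarray
    sd_curve: np.ndarray | None
    tv: float | None


def fourier_design(grid: AngularGrid, p: int) -> np.ndarray:
    """Design matrix of the orthonormal Fourier system on the grid.

    Columns are orthogonal on the uniform grid with Gram matrix
    ``(L/360)·I`` for harmonics below the Nyquist order.
    """
    if p % 2 == 0:
        raise ValueError(f"p must be odd (constant + sine/cosine pairs), got {p}")
    if not 1 <= p <= grid.n_points:
        raise ValueError(f"p must be in [1, L={grid.n_points}], got {p}")
    return FourierBasis(p).design(grid.angles)


def fit_coefficients(profiles: ProfileSet, p: int) -> CoefficientSet:
    """Least-squares projection of each curve onto the p-term Fourier basis.

    On the uniform grid this is the exact discrete Fourier projection: curves
    lying in the span of the basis are reproduced exactly.
    """
    B = fourier_design(profiles.grid, p)
    gamma, *_ = np.linalg.lstsq(B, profiles.values.T, rcond=None)
    return CoefficientSet(
        basis=FourierBasis(p),
        gamma=gamma.T,
        sample_id=profiles.sample_id.copy(),
        eye=profiles.eye.copy(),
        age=profiles.age.copy(),
    )


def reconstruct(coeffs: CoefficientSet, grid: AngularGrid) -> ProfileSet:
    """Evaluate the basis expansions on the grid: values = γ · Ψᵀ."""
    if grid.period != coeffs.basis.period:
        raise ValueError(
            f"grid period {grid.period} != basis period {coeffs.basis.period}"
        )
    B = coeffs.basis.design(grid.angles)
    n = coeffs.n
    return ProfileSet(
        grid=grid,
        values=coeffs.gamma @ B.T,
        sample_id=coeffs.sample_id.copy(),
        eye=coeffs.eye.copy() if coeffs.eye is not None
        else np.array(["OD"] * n, dtype=object),
        age=coeffs.age.copy() if coeffs.age is not None else np.full(n, np.nan),
    )


def curve_stats(values: np.ndarray | ProfileSet, step: float | None = None) -> CurveStats:
    """Pointwise mean and sd (n−1 denominator) and total variation.

    TV = (1/(n−1)) Σ_i ∮ (X_i − X̄)² dt with the circular rectangle rule,
    which equals Δt times the trace of the pointwise sample covariance.
    """
    if isinstance(values, ProfileSet):
        step = values.grid.step
        values = values.values
    elif step is None:
        raise ValueError("step (degrees) required when passing a bare matrix")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n < 2:
        raise ValueError("need n >= 2 curves for sd and total variation")
    sd = values.std(axis=0, ddof=1)
    tv = float((sd**2).sum() * step)
    return CurveStats(mean_curve=mean, sd_curve=sd, tv=tv)


def fve(profiles: ProfileSet, p: int) -> float:
    """Fraction of variation explained by the p-term basis approximation.

    FVE = (TV − (1/(n−1)) Σ_i ∮ (X_i^p − X_i)² dt) / TV.
    """
    stats = curve_stats(profiles)
    if stats.tv <= 0:
        raise ValueError("total variation is zero; FVE undefined")
    recon = reconstruct(fit_coefficients(profiles, p), profiles.grid)
    resid = profiles.values - recon.values
    rss = (resid**2).sum() * profiles.grid.step / (profiles.n - 1)
    return float((stats.tv - rss) / stats.tv)


@dataclass
class PSelection:
    """Result of the FVE-based basis-order scan."""

    p: int
    threshold: float
    fve_trace: dict[int, float]
    satisfied: bool  # False if no candidate exceeded the threshold


def select_p(
    profiles: ProfileSet,
    threshold: float = 0.99,
    candidates: tuple[int, ...] | range | None = None,
) -> PSelection:
    """Smallest odd p with FVE above `threshold` (default 99%).

    Falls back to the largest candidate (``satisfied=False``) when none
    qualifies.
    """
    if candidates is None:
        candidates = tuple(range(1, 42, 2))
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("empty candidate list for p")
    if list(candidates) != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    trace: dict[int, float] = {}
    for p in candidates:
        trace[p] = fve(profiles, p)
        if trace[p] > threshold:
            return PSelection(p=p, threshold=threshold, fve_trace=trace,
                              satisfied=True)
    logger.warning(
        "no candidate p reached FVE > %.4g; returning the largest (%d)",
        threshold, candidates[-1],
    )
    return PSelection(p=candidates[-1], threshold=threshold, fve_trace=trace,
                      satisfied=False)


@dataclass
class ClusterTemplate:
    """Per-cluster summary: size, mean curve (with basis coefficients), TV."""

    label: object
    size: int
    stats: CurveStats
    mean_coefficients: np.ndarray  # basis coefficients of the mean curve


def cluster_templates(
    profiles: ProfileSet, labels: np.ndarray, p: int = 11
) -> dict[object, ClusterTemplate]:
    """Mean curve, size and total variation per cluster.

    TV is reported only for clusters with at least two members.  Mean-curve
    basis coefficients are fit at the pipeline's working order ``p``.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != profiles.n:
        raise ValueError("labels length mismatch")
    B = fourier_design(profiles.grid, p)
    out: dict[object, ClusterTemplate] = {}
    for lab in pd.unique(labels):
        members = profiles.subset(labels == lab)
        if members.n == 0:
            raise ValueError(f"cluster {lab!r} has no members")
        if members.n >= 2:
            stats = curve_stats(members)
        else:
            stats = CurveStats(mean_curve=members.values.mean(axis=0),
                               sd_curve=None, tv=None)
        coef, *_ = np.linalg.lstsq(B, stats.mean_curve, rcond=None)
        out[lab] = ClusterTemplate(
            label=lab, size=members.n, stats=stats, mean_coefficients=coef
        )
    return out


def templates_to_frame(templates: dict[object, ClusterTemplate]) -> pd.DataFrame:
    """Template export table: cluster id, size, basis coefficients, TV."""
    records = []
    for lab, t in templates.items():
        rec = {"cluster": lab, "size": t.size}
        for j, c in enumerate(t.mean_coefficients, start=1):
            rec[f"coef_{j}"] = c
        rec["total_variation"] = t.stats.tv if t.stats.tv is not None else np.nan
        records.append(rec)
    return pd.DataFrame(records)
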