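"""Circular curve panels, metacluster dendrograms and covariate contours."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import cm
from scipy.cluster.hierarchy import dendrogram
from scipy.stats import gaussian_kde

from .basis import ClusterTemplate
from .metacluster import MetaclusterResult
from .profiles import CovariateTable, ProfileSet

logger = logging.getLogger(__name__)

_AXIS_LABELS = {
    "average_cdr": "Average CDR",
    "cup_volume": "Cup volume (mm³)",
}


def _cluster_color(index: int):
    return cm.tab10(index % 10)


def _polar_axes(fig, pos=111):
    """TSNIT polar axes: 0° at the temporal position, running clockwise."""
    ax = fig.add_subplot(pos, projection="polar")
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(-1)
    return ax


def _close_curve(angles_deg: np.ndarray, values: np.ndarray):
    th = np.deg2rad(np.append(angles_deg, angles_deg[0] + 360.0))
    v = np.append(values, values[..., :1], axis=-1)
    return th, v


def plot_circular(
    profiles: ProfileSet,
    labels: np.ndarray,
    templates: dict[object, ClusterTemplate],
    outdir,
    stem: str = "cluster",
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """One polar panel per cluster: member curves in the cluster color, the
    mean-curve template overlaid as a bold black circle-closing curve."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    files: list[Path] = []
    for i, lab in enumerate(sorted(templates)):
        fig = plt.figure(figsize=(4.5, 4.5))
        ax = _polar_axes(fig)
        members = profiles.values[labels == lab]
        color = _cluster_color(i)
        for row in members:
            th, v = _close_curve(profiles.grid.angles, row)
            ax.plot(th, v, color=color, alpha=0.25, lw=0.6)
        th, v = _close_curve(profiles.grid.angles, templates[lab].stats.mean_curve)
        ax.plot(th, v, color="black", lw=2.2)
        ax.set_title(f"cluster {lab} (n={templates[lab].size})")
        for fmt in formats:
            f = outdir / f"{stem}_{lab}.{fmt}"
            fig.savefig(f, bbox_inches="tight")
            files.append(f)
        plt.close(fig)
    return files


def plot_dendrogram(
    result: MetaclusterResult, cut_height: float, path, rescale: bool = True
) -> Path:
    """Dendrogram of the functional clusters with the flat-cut line drawn and
    subtrees below the cut colored by metacluster."""
    Z = result.linkage_matrix.copy()
    root = Z[:, 2].max()
    if rescale and root > 0:
        Z[:, 2] = Z[:, 2] / root
    fig, ax = plt.subplots(figsize=(5, 4))
    dendrogram(
        Z,
        labels=[str(c) for c in result.cluster_ids],
        color_threshold=cut_height,
        ax=ax,
    )
    ax.axhline(cut_height, color="grey", ls="--", lw=1)
    ax.set_ylabel("distance between metaclusters" + (" (root = 1)" if rescale else ""))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_contours(
    covariates: CovariateTable,
    metacluster_of_sample: dict[str, int],
    outdir,
    x: str = "average_cdr",
    y: str = "cup_volume",
    min_samples: int = 10,
    stem: str = "metacluster",
) -> list[Path]:
    """Kernel-density contour panel per metacluster on the two key covariates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = covariates.data
    groups: dict[int, list[str]] = {}
    for sid, mc in metacluster_of_sample.items():
        groups.setdefault(mc, []).append(sid)
    files: list[Path] = []
    for i, (mc, sids) in enumerate(sorted(groups.items())):
        sub = df.loc[[s for s in sids if s in df.index], [x, y]].dropna()
        if len(sub) < min_samples:
            logger.warning(
                "metacluster %s has %d samples (< %d); contour skipped",
                mc, len(sub), min_samples,
            )
            continue
        kde = gaussian_kde(sub.to_numpy().T)
        xg = np.linspace(sub[x].min(), sub[x].max(), 60)
        yg = np.linspace(sub[y].min(), sub[y].max(), 60)
        XX, YY = np.meshgrid(xg, yg)
        ZZ = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
        fig, ax = plt.subplots(figsize=(4.2, 4))
        ax.contour(XX, YY, ZZ, levels=6, colors=[_cluster_color(i)])
        ax.set_xlabel(_AXIS_LABELS.get(x, x))
        ax.set_ylabel(_AXIS_LABELS.get(y, y))
        ax.set_title(f"metacluster {mc} (n={len(sub)})")
        f = outdir / f"{stem}_{mc}.png"
        fig.savefig(f, bbox_inches="tight")
        plt.close(fig)
        files.append(f)
    return files
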