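"""End-to-end orchestration: stratify → basis selection → QC → DFM clustering
→ templates → metaclustering → correspondence → baselines → plots.

The per-stratum sequence follows the analysis design: curves are stratified
by age, outliers removed by the threshold rule on raw thickness, normalized
to circular densities (optional), expanded in the Fourier basis at a fixed
or FVE-selected order, clustered by the discriminative functional mixture
with the number of clusters chosen on the BIC elbow, and the resulting
clusters are metaclustered on their mean clinical covariates with sparse
feature selection.  A JSON manifest records the counts at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline as baseline_mod
from . import metacluster as meta_mod
from . import qc as qc_mod
from .basis import (
    cluster_templates,
    fit_coefficients,
    fve,
    select_p,
    templates_to_frame,
)
from .dfm import ALL_VARIANTS, select_K
from .profiles import (
    COVARIATE_NAMES,
    CovariateTable,
    ProfileSet,
    read_covariates,
    read_profiles,
    stratify_by_age,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline run needs; all stages have sensible defaults."""

    output_dir: str = "cifu_output"
    profiles_path: str | None = None
    covariates_path: str | None = None
    p: int | None = None                  # fixed basis order; None -> FVE rule
    fve_threshold: float = 0.99
    p_candidates: tuple[int, ...] = tuple(range(1, 42, 2))
    outlier_factor: float = 3.5
    normalize: bool = True
    stratify: bool = True
    K_range: tuple[int, ...] = tuple(range(2, 13))
    n_variants: int = 12                  # leading subset of the 12 variants
    d: int | None = None
    wbounds: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    cut_height: float = 0.1
    metacluster_covariates: tuple[str, ...] = COVARIATE_NAMES
    key_covariates: tuple[str, ...] = ("average_cdr", "cup_volume")
    baseline_K_range: tuple[int, ...] = tuple(range(2, 11))
    run_baselines: bool = True
    make_plots: bool = True
    seed: int = 0
    n_restarts: int = 5
    em_max_iter: int = 200
    em_tol: float = 1e-6


@dataclass
class StratumResult:
    stratum: int
    n_in: int
    n_outliers: int
    p: int
    fve_at_p: float
    chosen_K: int
    cluster_sizes: dict
    labels: pd.Series
    solution: object
    templates: dict
    metacluster: object | None
    metacluster_labels: pd.Series | None
    wbound: float | None
    baselines: dict | None


def run_pipeline(
    config: PipelineConfig,
    profiles: ProfileSet | None = None,
    covariates: CovariateTable | None = None,
) -> dict:
    """Run the full analysis; writes CSV/JSON artifacts and returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if profiles is None:
        if config.profiles_path is None:
            raise ValueError("either profiles or profiles_path is required")
        profiles = read_profiles(config.profiles_path)
    if covariates is None and config.covariates_path is not None:
        covariates = read_covariates(config.covariates_path)

    rng = np.random.default_rng(config.seed)
    strata = stratify_by_age(profiles) if config.stratify else {0: profiles}
    strata = {s: ps for s, ps in strata.items() if ps.n >= 10}
    variants = ALL_VARIANTS[: config.n_variants]

    manifest: dict = {"n_in": profiles.n, "strata": {}, "stages": []}
    results: dict[int, StratumResult] = {}
    for s, ps in sorted(strata.items()):
        stage_seed = int(rng.integers(2**31 - 1))
        clean, report = qc_mod.remove_outliers(ps, config.outlier_factor)
        report.to_frame().to_csv(out / f"qc_stratum{s}.csv", index=False)
        logger.info("stratum %s: %d in, %d outliers removed", s, ps.n,
                    report.n_flagged)
        working = qc_mod.normalize(clean) if config.normalize else clean
        if config.p is None:
            sel = select_p(working, config.fve_threshold, config.p_candidates)
            p = sel.p
        else:
            p = config.p
        fve_p = fve(working, p)
        coeffs = fit_coefficients(working, p)
        coeffs.to_frame().to_csv(out / f"coefficients_stratum{s}.csv", index=False)
        solution = select_K(
            coeffs,
            K_range=config.K_range,
            variants=variants,
            d=config.d,
            seed=stage_seed,
            n_restarts=config.n_restarts,
            max_iter=config.em_max_iter,
            tol=config.em_tol,
        )
        solution.trace.to_csv(out / f"criteria_stratum{s}.csv", index=False)
        labels = pd.Series(solution.labels, index=working.sample_id,
                           name="cluster")
        labels.rename_axis("sample_id").to_csv(out / f"labels_stratum{s}.csv")
        templates = cluster_templates(working, solution.labels, p)
        templates_to_frame(templates).to_csv(
            out / f"templates_stratum{s}.csv", index=False
        )

        meta_res = None
        meta_labels = None
        wbound = None
        if covariates is not None and solution.chosen_K >= 2:
            M = meta_mod.cluster_covariate_means(
                working.sample_id, solution.labels, covariates,
                config.metacluster_covariates,
            )
            wbound, gap_table = meta_mod.select_wbound(
                M, wbounds=config.wbounds, seed=stage_seed
            )
            gap_table.to_csv(out / f"wbound_gap_stratum{s}.csv", index=False)
            meta_res = meta_mod.sparse_hclust(M, wbound=wbound)
            meta_res.weights.rename("weight").rename_axis("covariate").to_csv(
                out / f"weights_stratum{s}.csv"
            )
            meta_labels = meta_mod.cut_tree(meta_res, config.cut_height)
            meta_labels.rename_axis("cluster").to_csv(
                out / f"metaclusters_stratum{s}.csv"
            )
            results_M = M
        else:
            results_M = None

        baselines = None
        if config.run_baselines:
            baselines = baseline_mod.run_baselines(
                working, K_range=config.baseline_K_range, seed=stage_seed
            )
            pd.DataFrame(
                [
                    {"method": m, "chosen_K": r.chosen_K, "dunn": r.dunn,
                     **{f"asw_K{K}": r.asw[K] for K in r.K_values}}
                    for m, r in baselines.items()
                ]
            ).to_csv(out / f"baselines_stratum{s}.csv", index=False)

        results[s] = StratumResult(
            stratum=s, n_in=ps.n, n_outliers=report.n_flagged, p=p,
            fve_at_p=fve_p, chosen_K=solution.chosen_K,
            cluster_sizes=pd.Series(solution.labels).value_counts().to_dict(),
            labels=labels, solution=solution, templates=templates,
            metacluster=meta_res, metacluster_labels=meta_labels,
            wbound=wbound, baselines=baselines,
        )
        results[s].M = results_M  # type: ignore[attr-defined]
        manifest["strata"][str(s)] = {
            "n_in": ps.n,
            "n_outliers_removed": report.n_flagged,
            "n_clustered": clean.n,
            "normalized": config.normalize,
            "p": p,
            "fve_at_p": fve_p,
            "chosen_K": solution.chosen_K,
            "cluster_sizes": {str(k): int(v)
                              for k, v in results[s].cluster_sizes.items()},
            "wbound": wbound,
            "n_metaclusters": (
                int(meta_labels.nunique()) if meta_labels is not None else None
            ),
            "baseline_chosen_K": (
                {m: r.chosen_K for m, r in baselines.items()} if baselines else None
            ),
            "baseline_dunn": (
                {m: r.dunn for m, r in baselines.items()} if baselines else None
            ),
        }

    # cross-stratum correspondence of metaclusters
    meta_results = {s: r.metacluster for s, r in results.items()
                    if r.metacluster is not None}
    if len(meta_results) >= 2:
        matrices = {s: results[s].M for s in meta_results}  # type: ignore[attr-defined]
        correspondence = meta_mod.correspond_metaclusters(
            meta_results, matrices, key_covariates=config.key_covariates,
            height=config.cut_height,
        )
        manifest["metacluster_correspondence"] = {
            str(s): {str(a): int(b) for a, b in m.items()}
            for s, m in correspondence.items()
        }
        with open(out / "correspondence.json", "w") as fh:
            json.dump(manifest["metacluster_correspondence"], fh, indent=2)

    if config.make_plots:
        from . import viz

        for s, r in results.items():
            working_labels = r.labels
            ps_clean = strata[s]
            clean, _ = qc_mod.remove_outliers(ps_clean, config.outlier_factor)
            working = qc_mod.normalize(clean) if config.normalize else clean
            viz.plot_circular(
                working, r.labels.to_numpy(), r.templates,
                out / "plots", stem=f"stratum{s}_cluster", formats=("png",),
            )
            if r.metacluster is not None:
                viz.plot_dendrogram(
                    r.metacluster, config.cut_height,
                    out / "plots" / f"dendrogram_stratum{s}.png",
                )
                if covariates is not None:
                    mc_of_cluster = r.metacluster_labels
                    mc_of_sample = {
                        str(sid): int(mc_of_cluster.loc[lab])
                        for sid, lab in r.labels.items()
                    }
                    viz.plot_contours(
                        covariates, mc_of_sample, out / "plots",
                        x=config.key_covariates[0], y=config.key_covariates[1],
                        stem=f"stratum{s}_metacluster",
                    )

    manifest["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["_results"] = results
    return manifest
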