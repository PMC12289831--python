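"""End-to-end orchestration: preprocess -> correlations -> clr-PCA ->
clustering -> kriging -> risk -> distance/land-use validation.

Every stage writes plain CSV (plus a JSON manifest recording the config,
seed, and output registry), so a run is fully diff-able and reproducible
from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import log_pearson_matrix, mcd_correlation_matrix
from .cluster import select_k
from .compositional import (
    clr_transform,
    distribution_diagnostics,
    impute_censored,
    summarize,
)
from .geostat import empirical_variogram, fit_variogram, ordinary_krige
from .pca import CompositionalPCA
from .references import CHALCOPHILE, default_references
from .risk import (
    cohort_enrichment,
    landuse_risk_summary,
    risk_factors,
    screen_thresholds,
)
from .survey import SurveyTable
from .trends import decay_validation


@dataclass
class PipelineConfig:
    """Per-stage knobs with auditable defaults."""

    censoring_policy: str = "half_dl"
    exclusion_threshold: float = 0.30
    k_range: tuple[int, int] = (2, 6)
    variogram_family: str = "spherical"
    cell_size: float = 100.0
    source_xy: tuple[float, float] = (0.0, 0.0)
    mcd_support_fraction: float = 0.75
    alpha_outlier: float = 0.05
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("k_range", "source_xy"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResults:
    """In-memory bundle of every stage's output."""

    survey: SurveyTable
    summary: pd.DataFrame
    diagnostics: pd.DataFrame
    pearson: object
    mcd: object
    pca: object                       # CompositionalPCAResults, oriented
    cluster: object                   # ClusterSolution
    surface: object                   # KrigedSurface (PC1)
    variogram: object
    risk: object                      # RiskTable
    exceedance: object
    landuse_summary: pd.DataFrame
    trend: object                     # TrendResult
    enrichment: pd.Series
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    survey: SurveyTable,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResults:
    """Execute the full analysis on a survey; optionally write all tables."""
    config = config or PipelineConfig()
    refs = default_references()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        timings[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    if survey.n_sites < 10:
        raise ValueError(
            f"pipeline needs >= 10 sites (got {survey.n_sites}): "
            "PCA, clustering and kriging preconditions fail below that"
        )

    summary = summarize(survey)
    diagnostics = distribution_diagnostics(survey)
    tick("summaries")

    pearson = log_pearson_matrix(survey, config.exclusion_threshold)
    mcd = mcd_correlation_matrix(
        survey, config.mcd_support_fraction, config.exclusion_threshold,
        seed=config.seed,
    )
    tick("association")

    matrix, imputation = impute_censored(survey, policy=config.censoring_policy)
    clr = clr_transform(matrix)
    pca = CompositionalPCA(clr).fit().orient(
        [el for el in CHALCOPHILE if el in clr.columns]
    )
    tick("clr_pca")

    retained = max(pca.n_retained, 1)
    scores = pca.retained_scores(retained)
    cluster = select_k(
        scores, range(config.k_range[0], config.k_range[1] + 1), seed=config.seed
    )
    tick("clustering")

    pc1 = scores.iloc[:, 0].to_numpy()
    lag_table = empirical_variogram(survey.coords, pc1)
    variogram = fit_variogram(lag_table, config.variogram_family)
    surface = ordinary_krige(
        variogram, survey.coords, pc1, cell_size=config.cell_size
    )
    tick("kriging")

    risk = risk_factors(survey, refs, config.censoring_policy)
    exceedance = screen_thresholds(survey, refs)
    landuse = landuse_risk_summary(risk)
    enrichment = cohort_enrichment(
        survey, refs.baselines["european_agricultural"]
    )
    tick("risk")

    trend = decay_validation(
        pc1, survey.coords, config.source_xy,
        survey.data["land_use"].to_numpy(),
        risk=risk, cluster_labels=cluster.labels,
    )
    tick("validation")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "censoring_policy": imputation.policy,
        "excluded_from_correlations": pearson.excluded,
        "retained_components": int(retained),
        "chosen_k": int(cluster.k),
        "variogram": {
            "family": variogram.family,
            "nugget": variogram.nugget,
            "psill": variogram.psill,
            "range_m": variogram.range_,
        },
        "stage_seconds": timings,
    }
    results = PipelineResults(
        survey=survey, summary=summary, diagnostics=diagnostics,
        pearson=pearson, mcd=mcd, pca=pca, cluster=cluster,
        surface=surface, variogram=variogram, risk=risk,
        exceedance=exceedance, landuse_summary=landuse, trend=trend,
        enrichment=enrichment, manifest=manifest,
    )
    if out_dir is not None:
        write_results(results, out_dir)
    return results


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_results(results: PipelineResults, out_dir: str | Path) -> dict:
    """Write every stage table as CSV plus a JSON manifest; returns manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = {}

    def save(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=index)
        registry[name] = _checksum(path)

    save("summary", results.summary)
    save("diagnostics", results.diagnostics)
    save("correlation_pearson", results.pearson.matrix)
    save("correlation_pearson_p", results.pearson.p_values)
    save("correlation_mcd", results.mcd.matrix)
    save("pca_loadings", results.pca.loadings)
    save(
        "pca_eigenvalues",
        pd.DataFrame(
            {
                "eigenvalue": results.pca.eigenvalues,
                "variance_percent": results.pca.variance_fraction,
            },
            index=results.pca.loadings.columns,
        ),
    )
    save("pca_scores", results.pca.scores)
    save("pca_outliers", results.pca.t2_q(alpha=0.05))
    save(
        "clusters",
        results.cluster.membership(results.survey.data["site"]),
        index=False,
    )
    save("cluster_panel", results.cluster.panel)
    save("kriged_pc1", results.surface.to_frame(), index=False)
    save("risk_table", results.risk.to_frame())
    save("exceedance", results.exceedance.table)
    save("landuse_risk", results.landuse_summary)
    save("trend", results.trend.to_frame(), index=False)
    if results.trend.cluster_ef is not None:
        save("cluster_enrichment", results.trend.cluster_ef)
    save("cohort_enrichment", results.enrichment.to_frame())

    manifest = dict(results.manifest)
    manifest["outputs"] = registry
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results.manifest = manifest
    return manifest
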