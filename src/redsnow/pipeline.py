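"""High-level pipeline runs: quantify a scene, build a time series,
compare communities. Each run function is a pure library call; the CLI
is a thin wrapper around these.

Configuration is a single YAML file with sections ``paths``,
``thresholds``, ``calibration`` and ``stats``; explicit function
arguments (and CLI flags) override config values. Every JSON report
embeds the resolved parameters, the seed and a hash of the resolved
configuration so re-runs are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    CountTable,
    bray_curtis,
    normalize_log,
    pca,
    per_feature_anova,
    permanova,
    select_top_variable,
    simprof_cluster,
)
from .errors import ConfigError, DataError
from .quantify import (
    CATEGORY_NODATA,
    BiomassSummary,
    CalibrationCurve,
    classify_categories,
    summarize,
    timeseries_report,
)
from .reflectance import scene_band_ratio
from .scene import SceneBundle, read_scene, write_singleband
from .snow_mask import NDSI_THRESHOLD, NIR_THRESHOLD, scene_snow_mask

log = logging.getLogger("redsnow")


@dataclass
class RunConfig:
    """Resolved run parameters for the pipeline commands."""

    ndsi_threshold: float = NDSI_THRESHOLD
    nir_threshold: float = NIR_THRESHOLD
    ratio_threshold: float = 1.0
    calibration_slope: float = 5000.0
    category_bounds: list | None = None
    category_means: list | None = None
    permutations: int = 999
    alpha: float = 0.05
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ndsi_threshold", "nir_threshold", "ratio_threshold"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.permutations < 1:
            raise ConfigError("permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
        thresholds = raw.get("thresholds", {}) or {}
        calibration = raw.get("calibration", {}) or {}
        stats = raw.get("stats", {}) or {}
        merged = {
            "ndsi_threshold": thresholds.get("ndsi", NDSI_THRESHOLD),
            "nir_threshold": thresholds.get("nir", NIR_THRESHOLD),
            "ratio_threshold": thresholds.get("ratio", 1.0),
            "calibration_slope": calibration.get("slope", 5000.0),
            "category_bounds": calibration.get("bounds"),
            "category_means": calibration.get("means"),
            "permutations": stats.get("permutations", 999),
            "alpha": stats.get("alpha", 0.05),
            "top_k": stats.get("top_k", 10),
            "seed": stats.get("seed", 0),
        }
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**merged)

    def calibration(self) -> CalibrationCurve:
        bounds = (
            tuple(tuple(b) for b in self.category_bounds)
            if self.category_bounds
            else CalibrationCurve().category_bounds
        )
        return CalibrationCurve(
            slope=self.calibration_slope,
            category_bounds=bounds,
            category_mean_biomass=(
                tuple(self.category_means) if self.category_means else None
            ),
            anchor_ratio=self.ratio_threshold,
        )

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "config_hash": self.digest(),
            "software_version": __version__,
            "parameters": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()
            },
        }


def quantify_scene(
    bundle: SceneBundle, config: RunConfig | None = None
) -> tuple[BiomassSummary, dict]:
    """Full single-scene chain: reflectance -> mask -> classify -> summarize.

    Returns the summary plus the intermediate rasters (ratio map, snow
    mask, category map) for writing or inspection.
    """
    config = config if config is not None else RunConfig()
    calib = config.calibration()
    log.info(
        "quantify: ndsi>%s nir>%s ratio>%s slope=%s",
        config.ndsi_threshold,
        config.nir_threshold,
        config.ratio_threshold,
        config.calibration_slope,
    )
    ratio = scene_band_ratio(bundle)
    mask = scene_snow_mask(bundle, config.ndsi_threshold, config.nir_threshold)
    catmap = classify_categories(ratio, mask, calib)
    summary = summarize(catmap, mask, calib, bundle.pixel_size_m)
    rasters = {"ratio": ratio, "snow_mask": mask, "categories": catmap}
    return summary, rasters


def run_quantify(
    scene_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    meta_path: str | Path | None = None,
) -> BiomassSummary:
    """File-level quantify command: read a scene, write rasters + reports."""
    config = config if config is not None else RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = read_scene(scene_path, meta_path)
    summary, rasters = quantify_scene(bundle, config)
    if summary.snow_area_m2 == 0:
        log.warning("scene %s contains no snow pixels", scene_path)
    write_singleband(rasters["ratio"].values, out / "ratio.tif", np.float64)
    write_singleband(
        rasters["snow_mask"].mask.astype(np.uint8), out / "snow_mask.tif", np.uint8
    )
    write_singleband(rasters["categories"].values, out / "categories.tif", np.uint8)
    report = {**summary.to_dict(), **config.provenance()}
    (out / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    pd.DataFrame([summary.to_dict()]).drop(
        columns=["area_per_category_m2", "percent_per_category"]
    ).to_csv(out / "summary.csv", index=False)
    return summary


def run_timeseries(
    scene_paths: list[str | Path],
    out_dir: str | Path,
    config: RunConfig | None = None,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Quantify dated scenes and report consecutive percent changes."""
    config = config if config is not None else RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles = [read_scene(p) for p in scene_paths]
    if years is None:
        years = [b.year for b in bundles]
        if any(y is None for y in years):
            raise ConfigError(
                "every scene needs a YEAR sidecar key or an explicit years list"
            )
    if len(years) != len(bundles):
        raise ConfigError("years list does not match number of scenes")
    if len(set(years)) != len(years):
        raise ConfigError(f"duplicate years in time series: {years}")
    order = np.argsort(years)
    if not np.array_equal(order, np.arange(len(years))):
        log.info("scenes supplied out of year order; auto-sorting")
    dated = sorted(
        ((int(years[i]), bundles[i]) for i in range(len(bundles))),
        key=lambda t: t[0],
    )
    summaries = [(y, quantify_scene(b, config)[0]) for y, b in dated]
    table = timeseries_report(summaries)
    per_year = pd.DataFrame(
        [{"year": y, **s.to_dict()} for y, s in summaries]
    ).drop(columns=["area_per_category_m2", "percent_per_category"])
    per_year.to_csv(out / "per_year_summaries.csv", index=False)
    table.to_csv(out / "changes.csv", index=False)
    report = {
        "per_year": per_year.to_dict(orient="records"),
        "changes": table.to_dict(orient="records"),
        **config.provenance(),
    }
    (out / "timeseries.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return table


def compare_communities(
    table: CountTable, config: RunConfig | None = None
) -> dict:
    """Community comparison: normalize -> distances -> PERMANOVA +
    SIMPROF + top-k PCA + per-feature ANOVA, as one JSON-able report."""
    config = config if config is not None else RunConfig()
    sizes = table.groups.value_counts()
    if (sizes < 2).any():
        raise DataError(
            f"groups below the two-sample minimum: {sizes[sizes < 2].to_dict()}"
        )
    normalized = normalize_log(table)
    dist = bray_curtis(normalized)
    perm = permanova(
        dist, table.groups, n_permutations=config.permutations, seed=config.seed
    )
    sim = simprof_cluster(
        normalized,
        alpha=config.alpha,
        seed=config.seed,
    )
    k = min(config.top_k, len(normalized.index))
    top = select_top_variable(normalized, k)
    pca_res = pca(top)
    anova = per_feature_anova(normalized, table.groups)
    return {
        "permanova": perm.to_dict(),
        "simprof": {
            "n_clusters": sim.n_clusters,
            "clusters": sim.labels.to_dict(),
            "newick": sim.newick,
            "tests": [
                {
                    "samples": t.samples,
                    "pi": t.pi,
                    "p_value": t.p_value,
                    "significant": t.significant,
                }
                for t in sim.tests
            ],
        },
        "pca": {
            "top_k": k,
            "percent_variance": pca_res.percent_variance.tolist(),
            "scores": {s: row.tolist() for s, row in pca_res.scores.iterrows()},
        },
        "anova": anova.reset_index(names="feature").to_dict(orient="records"),
        **config.provenance(),
    }


def run_compare(
    counts_path: str | Path,
    groups_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict:
    """File-level compare command: read TSVs, write the stats bundle."""
    config = config if config is not None else RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = CountTable.read_tsv(counts_path, groups_path)
    report = compare_communities(table, config)
    (out / "community_stats.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    pd.DataFrame(report["anova"]).to_csv(out / "anova.csv", index=False)
    (out / "dendrogram.nwk").write_text(report["simprof"]["newick"] + "\n")
    return report
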