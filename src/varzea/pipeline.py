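"""Config-driven orchestration of the full analysis.

A YAML run configuration selects the input source (files or the synthetic
generator), metric and model settings, and seeds for every stochastic stage;
``run_pipeline`` executes core data ingestion -> dissimilarity -> clustering
and ordination -> alpha/gamma diversity -> climate quantile models, writing
every intermediate artifact to the output directory.  Reruns with the same
config and seeds reproduce the tables exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import alphadiv, betadiv, quantreg, structure
from .core import (
    CommunityTable,
    SiteMetadata,
    read_community_table,
    read_inventory_summary,
    read_site_metadata,
    read_two_column_map,
    summary_from_table,
    tally_taxa,
)
from .simulate import MetacommunityConfig, generate_dataset

logger = logging.getLogger(__name__)

_ALLOWED_KEYS = {
    "source", "community_path", "metadata_path", "summary_path", "synonym_map_path",
    "family_map_path", "metric", "k_min", "k_max", "taus", "qr_response",
    "qr_covariates", "bootstrap_B", "n_permutations", "n_curves", "nmds_starts",
    "seed", "outdir", "strict_biomes", "synthetic_overrides",
}


@dataclass
class RunConfig:
    source: str = "synthetic"          # "synthetic" | "files"
    community_path: str | None = None
    metadata_path: str | None = None
    summary_path: str | None = None
    synonym_map_path: str | None = None
    family_map_path: str | None = None
    metric: str = "forbes"
    k_min: int = 4
    k_max: int = 8
    taus: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    qr_response: str = "alpha"         # "alpha" | "log_alpha"
    qr_covariates: tuple[str, ...] = ("mat", "map_mm", "p_seasonality", "t_seasonality")
    bootstrap_B: int = 1000
    n_permutations: int = 999
    n_curves: int = 10
    nmds_starts: int = 20
    seed: int | None = None
    outdir: str = "varzea_run"
    strict_biomes: bool = True
    #: keyword overrides for MetacommunityConfig when source == "synthetic"
    synthetic_overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and fully validate a YAML run config; all errors listed at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config must be a YAML mapping"]
    unknown = sorted(set(raw) - _ALLOWED_KEYS)
    if unknown:
        errors.append(f"unknown config keys: {unknown}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in _ALLOWED_KEYS})
    if cfg.source not in ("synthetic", "files"):
        errors.append(f"source must be 'synthetic' or 'files', got {cfg.source!r}")
    if cfg.metric not in ("forbes", "simpson"):
        errors.append(f"metric must be one of ['forbes', 'simpson'], got {cfg.metric!r}")
    if cfg.qr_response not in ("alpha", "log_alpha"):
        errors.append(f"qr_response must be 'alpha' or 'log_alpha', got {cfg.qr_response!r}")
    if cfg.seed is None:
        errors.append("seed is required (stochastic stages: simulation, NMDS, "
                      "permutations, bootstrap, accumulation curves)")
    if cfg.source == "files":
        for key in ("community_path", "metadata_path"):
            p = getattr(cfg, key)
            if p is None:
                errors.append(f"{key} is required when source is 'files'")
            elif not Path(p).exists():
                errors.append(f"{key} does not exist: {p}")
    if not all(0 < t < 1 for t in cfg.taus):
        errors.append("all taus must lie in (0, 1)")
    if cfg.k_min < 2 or cfg.k_max < cfg.k_min:
        errors.append("need 2 <= k_min <= k_max")
    cfg.taus = tuple(float(t) for t in cfg.taus)
    cfg.qr_covariates = tuple(cfg.qr_covariates)
    return (cfg if not errors else None), errors


@dataclass
class ReportBundle:
    """Everything a run produced, with provenance."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)
    config: RunConfig | None = None
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv")
        meta = {
            "package_version": __version__,
            "seed": self.config.seed if self.config else None,
            "config_hash": self.config.config_hash() if self.config else None,
            "scalars": self.scalars,
            "stage_seconds": self.timings,
        }
        (outdir / "report.json").write_text(json.dumps(meta, indent=2, default=float))
        if self.config:
            (outdir / "config_echo.yaml").write_text(yaml.safe_dump(asdict(self.config)))


def _load_inputs(cfg: RunConfig):
    if cfg.source == "synthetic":
        ds = generate_dataset(MetacommunityConfig(**cfg.synthetic_overrides, seed=cfg.seed))
        return ds.community, ds.metadata, ds.summary
    synonym_map = read_two_column_map(cfg.synonym_map_path) if cfg.synonym_map_path else None
    table = read_community_table(cfg.community_path, synonym_map=synonym_map)
    metadata = read_site_metadata(cfg.metadata_path, strict_biomes=cfg.strict_biomes)
    metadata.check_covers(table)
    if cfg.summary_path:
        summary = read_inventory_summary(cfg.summary_path)
    else:
        summary = summary_from_table(table)
    return table, metadata, summary


def run_pipeline(cfg: RunConfig, write: bool = True) -> ReportBundle:
    """Execute every stage; artifacts land in ``cfg.outdir``.

    Stage failures propagate with the stage name attached; previously
    written artifacts are retained.
    """
    bundle = ReportBundle(config=cfg)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ("curves", "nmds", "perm", "bootstrap"), ss.spawn(4))}
    stage = "ingest"
    t0 = time.perf_counter()
    try:
        table, metadata, summary = _load_inputs(cfg)
        biome_of = metadata.biome_of()
        family_map = (
            read_two_column_map(cfg.family_map_path) if cfg.family_map_path else None
        )
        tallies = tally_taxa(table, metadata, family_map)
        bundle.tables["taxon_tallies"] = tallies.per_biome
        bundle.scalars.update(
            n_sites=len(table.sites), n_species=tallies.n_species,
            n_genera=tallies.n_genera,
        )
        bundle.timings[stage] = time.perf_counter() - t0

        stage = "betadiv"
        t0 = time.perf_counter()
        d_main = betadiv.dissimilarity_matrix(table, cfg.metric)
        other = "simpson" if cfg.metric == "forbes" else "forbes"
        d_other = betadiv.dissimilarity_matrix(table, other)
        bundle.scalars["dissim_metric_correlation"] = betadiv.matrix_correlation(
            d_main, d_other
        )
        bundle.tables["dissimilarity"] = betadiv.matrix_to_frame(d_main)
        bundle.timings[stage] = time.perf_counter() - t0

        stage = "structure"
        t0 = time.perf_counter()
        tree = structure.ward_cluster(d_main)
        best_k, k_path = structure.select_k(
            tree, biome_of, range(cfg.k_min, cfg.k_max + 1)
        )
        match = structure.cut_and_match(tree, best_k, biome_of)
        bundle.tables["cluster_assignments"] = match.assignments.set_index("site_id")
        bundle.tables["k_selection"] = k_path.rename("adjusted_rand").to_frame()
        bundle.scalars.update(best_k=best_k, mismatch_rate=match.mismatch_overall)
        ordp = structure.pcoa(d_main)
        bundle.tables["pcoa_coordinates"] = ordp.coordinates.iloc[:, :2]
        bundle.scalars["pcoa_axis1_pct"] = 100 * float(ordp.proportion_explained[0])
        bundle.scalars["pcoa_axis2_pct"] = 100 * float(ordp.proportion_explained[1])
        ordn = structure.nmds(d_main, n_starts=cfg.nmds_starts, seed=seeds["nmds"])
        ordn = structure.rotate_to_reference(ordn, ordp.coordinates["axis_1"])
        bundle.tables["nmds_coordinates"] = ordn.coordinates
        bundle.scalars["nmds_stress"] = float(ordn.stress)
        climate = metadata.climate()
        complete = climate.dropna()
        retained, dropped = structure.decorrelate_variables(complete)
        vectors = structure.fit_climate_vectors(
            ordp, complete[retained], n_perm=cfg.n_permutations, seed=seeds["perm"]
        )
        bundle.tables["climate_vectors"] = pd.DataFrame(
            [
                {"variable": v.variable, "r2": v.r2, "p": v.p_value,
                 "significant": v.significant,
                 **{f"cos_{i+1}": c for i, c in enumerate(v.direction)}}
                for v in vectors
            ]
        ).set_index("variable")
        bundle.timings[stage] = time.perf_counter() - t0

        stage = "alphadiv"
        t0 = time.perf_counter()
        alphas = alphadiv.alpha_records(summary.df)
        alphas["biome"] = alphas["site_id"].map(biome_of)
        bundle.tables["fishers_alpha"] = alphas.set_index("site_id")
        bundle.tables["alpha_by_biome"] = (
            alphas.groupby("biome")["alpha"].agg(["count", "mean", "std"])
        )
        curves = alphadiv.accumulation_curves(
            table, biome_of, n_curves=cfg.n_curves, seed=seeds["curves"]
        )
        mean_stems = (
            summary.df.set_index("site_id")["n_individuals"]
            .groupby(biome_of).mean()
        )
        curve_frames = []
        for label, curve in curves.items():
            if label in mean_stems.index:
                curve = alphadiv.rescale_to_individuals(curve, float(mean_stems[label]))
            curve_frames.append(curve.to_frame())
        bundle.tables["accumulation_curves"] = pd.concat(curve_frames, ignore_index=True)
        cov_rows, cov_frames = [], []
        for biome, grp in alphas.groupby("biome"):
            sites = grp["site_id"].tolist()
            if len(sites) < 2:
                continue
            inc = alphadiv.incidence_frequencies(table, sites)
            c_hat, deficit = alphadiv.sample_coverage(inc)
            cov_rows.append({"biome": biome, "coverage": c_hat, "deficit": deficit,
                             "T": inc.T, "S_obs": inc.S_obs, "Q1": inc.Q1, "Q2": inc.Q2})
            cov_frames.append(alphadiv.coverage_curve(inc).to_frame().assign(label=biome))
        bundle.tables["coverage"] = pd.DataFrame(cov_rows).set_index("biome")
        bundle.tables["coverage_curves"] = pd.concat(cov_frames, ignore_index=True)
        occ = alphadiv.occupancy_table(table, biome_of)
        bundle.tables["occupancy"] = occ.counts
        bundle.scalars.update(
            n_exclusive_species=occ.n_exclusive, n_all_biome_species=occ.n_all_biomes
        )
        bundle.timings[stage] = time.perf_counter() - t0

        stage = "climate_quantiles"
        t0 = time.perf_counter()
        merged = alphas.merge(
            metadata.df[["site_id"] + [c for c in cfg.qr_covariates
                                       if c in metadata.df.columns]],
            on="site_id",
        ).dropna(subset=["alpha"])
        resp = (
            merged["alpha"] if cfg.qr_response == "alpha" else np.log(merged["alpha"])
        )
        qr_rows = []
        for j, cov in enumerate(cfg.qr_covariates):
            if cov not in merged.columns:
                continue
            for tau in cfg.taus:
                fit = quantreg.quantile_fit(resp, merged[cov], tau)
                boot = quantreg.bootstrap_qr(
                    resp, merged[cov], tau, B=cfg.bootstrap_B,
                    seed=seeds["bootstrap"] + j,
                )
                qr_rows.append(
                    {"covariate": cov, "tau": tau, "intercept": fit.intercept,
                     "slope": fit.slope, "se_slope": boot.se_slope,
                     "slope_lo": boot.ci_slope[0], "slope_hi": boot.ci_slope[1]}
                )
        bundle.tables["quantile_fits"] = pd.DataFrame(qr_rows)
        aov = quantreg.anova_log_alpha(alphas.set_index("site_id")["alpha"], biome_of)
        bundle.scalars.update(anova_F=aov.F, anova_p=aov.p, anova_df2=aov.df2)
        bundle.tables["tukey"] = aov.tukey
        bundle.tables["biome_letters"] = pd.Series(aov.letters, name="letters").to_frame()
        bundle.timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if write:
        bundle.write(cfg.outdir)
    return bundle
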