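"""Synthetic metacommunity generator.

Emulates the statistical structure the downstream analysis assumes, with
known ground truth so every stage can be checked for parameter recovery:

* biome-structured species pools with controlled pairwise overlap;
* per-site species abundances drawn by a Hoppe-urn (Ewens) scheme whose
  species-abundance law is Fisher's log-series, making Fisher's alpha the
  true per-site diversity parameter and the total stem count exactly N;
* per-biome Gaussian climate (defaults follow published biome-level
  climate averages for the five Brazilian biomes);
* right-skewed site diversity whose *upper* conditional quantiles shift
  linearly with climate while lower quantiles do not — a log-normal
  location-scale base law with an additive climate term switched on above a
  quantile threshold tau0.

A single global seed feeds named per-component substreams, so any stage is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import CommunityTable, InventorySummary, SiteMetadata, build_community_table

__all__ = [
    "MetacommunityConfig",
    "TruthRecord",
    "build_species_pools",
    "sample_site_community",
    "generate_dataset",
    "default_config",
]


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent generator configurations."""


@dataclass
class MetacommunityConfig:
    """Generator parameters.  Defaults mirror the five-biome study system.

    ``pairwise_overlap[j][k]`` is the fraction of the smaller of the two
    pools shared between biomes j and k (symmetric, unit diagonal).
    ``alpha_model`` is (log-location mu0, log-scale sigma0, quantile
    threshold tau0, per-covariate upper-quantile slopes): conditional
    quantiles of site alpha are ``exp(mu0 + sigma0 * z_tau)`` plus, for
    tau > tau0, ``(tau - tau0)/(1 - tau0) * sum_j beta_j (x_j - ref_j)``.
    The reference ref_j sits at the edge of the climate support (minimum for
    positive slopes, maximum for negative ones) so the shift is non-negative
    everywhere, the site law stays monotone in its latent quantile, and the
    stated slopes are exactly the conditional-quantile slopes.
    """

    biomes: tuple[str, ...] = ("Amazon", "Atlantic Forest", "Cerrado", "Caatinga", "Pampas")
    # regional pools comfortably exceed the richness any one site can draw
    pool_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "Amazon": 1500, "Atlantic Forest": 1100, "Cerrado": 1000,
            "Caatinga": 500, "Pampas": 450,
        }
    )
    # modest background sharing; stronger between the savanna-belt biomes
    pairwise_overlap: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Amazon", "Atlantic Forest"): 0.08,
            ("Amazon", "Cerrado"): 0.12,
            ("Amazon", "Caatinga"): 0.05,
            ("Amazon", "Pampas"): 0.03,
            ("Atlantic Forest", "Cerrado"): 0.25,
            ("Atlantic Forest", "Caatinga"): 0.10,
            ("Atlantic Forest", "Pampas"): 0.25,
            ("Cerrado", "Caatinga"): 0.35,
            ("Cerrado", "Pampas"): 0.08,
            ("Caatinga", "Pampas"): 0.05,
        }
    )
    site_counts: dict[str, int] = field(
        default_factory=lambda: {
            "Amazon": 63, "Atlantic Forest": 58, "Cerrado": 50,
            "Caatinga": 12, "Pampas": 13,
        }
    )
    # lognormal (mean, sd) of stems per site; means follow observed
    # per-biome individuals-per-inventory averages
    stems_per_site: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Amazon": (1327.0, 800.0), "Atlantic Forest": (1586.0, 900.0),
            "Cerrado": (1169.0, 700.0), "Caatinga": (679.0, 400.0),
            "Pampas": (1440.0, 800.0),
        }
    )
    # per-biome climate means/sds: (dry_months, map_mm, p_seasonality, mat, t_seasonality)
    climate_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Amazon": dict(dry_months=2.0, map_mm=2557, p_seasonality=42.8, mat=26.8, t_seasonality=42.2),
            "Atlantic Forest": dict(dry_months=5.11, map_mm=1426, p_seasonality=56.4, mat=20.1, t_seasonality=228.4),
            "Cerrado": dict(dry_months=5.67, map_mm=1337, p_seasonality=75.7, mat=23.6, t_seasonality=139.1),
            "Caatinga": dict(dry_months=8.44, map_mm=957, p_seasonality=92.8, mat=26.1, t_seasonality=105.0),
            "Pampas": dict(dry_months=1.92, map_mm=1440, p_seasonality=13.6, mat=18.6, t_seasonality=347.0),
        }
    )
    climate_sds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Amazon": dict(dry_months=1.5, map_mm=463, p_seasonality=15.1, mat=0.5, t_seasonality=11.4),
            "Atlantic Forest": dict(dry_months=2.0, map_mm=208, p_seasonality=22.1, mat=2.1, t_seasonality=35.5),
            "Cerrado": dict(dry_months=0.8, map_mm=186, p_seasonality=9.6, mat=2.1, t_seasonality=40.1),
            "Caatinga": dict(dry_months=1.9, map_mm=314, p_seasonality=16.8, mat=1.2, t_seasonality=40.3),
            "Pampas": dict(dry_months=1.5, map_mm=156, p_seasonality=3.9, mat=0.8, t_seasonality=26.1),
        }
    )
    alpha_mu0: float = float(np.log(12.0))   # median site alpha ~ 12
    alpha_sigma0: float = 0.55               # right-skewed log-normal base law
    alpha_tau0: float = 0.8                  # climate couples only above this quantile
    # upper-quantile slopes, alpha units per covariate unit
    alpha_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "mat": 6.0, "map_mm": 0.01, "p_seasonality": -0.25, "t_seasonality": -0.05,
        }
    )
    alpha_floor: float = 0.5                 # site alpha never clipped below this
    seed: int = 0

    def validate(self) -> None:
        for b in self.biomes:
            if self.pool_sizes.get(b, 0) < 1:
                raise ConfigError(f"pool size for {b!r} must be >= 1")
            if self.site_counts.get(b, 0) < 1:
                raise ConfigError(f"site count for {b!r} must be >= 1")
        for (j, k), o in self.pairwise_overlap.items():
            if not (0.0 <= o <= 1.0):
                raise ConfigError(f"overlap for {(j, k)} outside [0, 1]: {o}")
        for b, sds in self.climate_sds.items():
            if any(v < 0 for v in sds.values()):
                raise ConfigError(f"negative climate sd for {b!r}")

    def overlap(self, j: str, k: str) -> float:
        if j == k:
            return 1.0
        return self.pairwise_overlap.get((j, k), self.pairwise_overlap.get((k, j), 0.0))


def default_config(seed: int = 0) -> MetacommunityConfig:
    return MetacommunityConfig(seed=seed)


@dataclass
class TruthRecord:
    """Ground truth of a generated dataset, for recovery tests."""

    site_truth: pd.DataFrame           # site_id, biome, true_alpha, true_N, u (latent quantile)
    pools: dict[str, list[str]]
    alpha_slopes: dict[str, float]
    alpha_tau0: float
    alpha_mu0: float
    alpha_sigma0: float
    climate_reference: dict[str, float]  # covariate means used for centering

    def generating_slope(self, covariate: str, tau: float) -> float:
        """The true conditional-quantile slope of alpha on a covariate at tau."""
        g = max(0.0, (tau - self.alpha_tau0) / (1.0 - self.alpha_tau0))
        return g * self.alpha_slopes.get(covariate, 0.0)


def _int_to_epithet(i: int, length: int = 5) -> str:
    letters = []
    for _ in range(length):
        letters.append(chr(ord("a") + i % 26))
        i //= 26
    return "".join(reversed(letters))


def _species_name(idx: int) -> str:
    # ~4 species per genus, roughly the ratio seen in large regional floras
    genus = "Synth" + _int_to_epithet(idx // 4, length=3)
    return f"{genus.capitalize()} {_int_to_epithet(idx)}"


def build_species_pools(config: MetacommunityConfig) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Construct per-biome species pools realizing the pairwise overlaps.

    Each requested pairwise overlap is realized as a block of species shared
    by exactly that biome pair (shared count = round(overlap * smaller pool)),
    the remainder of each pool being biome-exclusive.  Returns the pools and
    the realized-overlap table.  Overlap systems whose per-biome shared totals
    exceed the pool size are infeasible and rejected.
    """
    config.validate()
    biomes = list(config.biomes)
    shared: dict[tuple[str, str], int] = {}
    for i, j in [(a, b) for ai, a in enumerate(biomes) for b in biomes[ai + 1:]]:
        o = config.overlap(i, j)
        shared[(i, j)] = int(round(o * min(config.pool_sizes[i], config.pool_sizes[j])))
    demand = {b: 0 for b in biomes}
    for (i, j), s in shared.items():
        demand[i] += s
        demand[j] += s
    for b in biomes:
        if demand[b] > config.pool_sizes[b]:
            raise ConfigError(
                f"infeasible overlap system: biome {b!r} needs {demand[b]} shared "
                f"species but its pool holds only {config.pool_sizes[b]}"
            )
    pools: dict[str, list[str]] = {b: [] for b in biomes}
    idx = 0
    for (i, j), s in shared.items():
        for _ in range(s):
            name = _species_name(idx)
            idx += 1
            pools[i].append(name)
            pools[j].append(name)
    for b in biomes:
        while len(pools[b]) < config.pool_sizes[b]:
            pools[b].append(_species_name(idx))
            idx += 1
    rows = []
    for i, j in shared:
        inter = len(set(pools[i]) & set(pools[j]))
        rows.append(
            {
                "biome_a": i, "biome_b": j, "shared": inter,
                "requested_fraction": config.overlap(i, j),
                "realized_fraction": inter / min(config.pool_sizes[i], config.pool_sizes[j]),
            }
        )
    return pools, pd.DataFrame(rows)


def sample_site_community(
    pool: list[str], alpha: float, N: int, rng: np.random.Generator,
    pool_limit: str = "error",
) -> dict[str, int]:
    """Draw one site's species abundances with Fisher's alpha as true parameter.

    Hoppe-urn scheme: individual i (0-based) founds a new species with
    probability alpha/(alpha + i), otherwise joins the species of a uniformly
    chosen earlier individual.  The expected species count is
    sum_{i<N} alpha/(alpha+i) ~= alpha * ln(1 + N/alpha), the species-abundance
    law converges to Fisher's log-series with x = N/(N+alpha), and the total
    abundance is exactly N.

    ``pool_limit`` controls behaviour when the urn wants more species than the
    pool holds: ``"error"`` (default) raises, ``"cap"`` stops founding new
    species once the pool is exhausted (finite-pool urn; later individuals
    join existing species).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if N < 1:
        raise ValueError("N must be >= 1")
    i = np.arange(N)
    new_species = rng.random(N) < alpha / (alpha + i)
    new_species[0] = True
    parent = (rng.random(N) * i).astype(np.int64)  # uniform in [0, i)
    labels = np.empty(N, dtype=np.int64)
    n_species = 0
    for k in range(N):
        if new_species[k] and (pool_limit == "error" or n_species < len(pool)):
            labels[k] = n_species
            n_species += 1
        else:
            labels[k] = labels[parent[k]]
    if n_species > len(pool):
        raise ValueError(
            f"drew {n_species} species but the pool holds only {len(pool)}; "
            "enlarge the biome's species pool"
        )
    chosen = rng.choice(len(pool), size=n_species, replace=False)
    counts = np.bincount(labels, minlength=n_species)
    return {pool[chosen[s]]: int(counts[s]) for s in range(n_species)}


def _site_alpha(
    u: float, climate_centered: dict[str, float], config: MetacommunityConfig
) -> float:
    base = float(np.exp(config.alpha_mu0 + config.alpha_sigma0 * norm.ppf(u)))
    if u > config.alpha_tau0:
        g = (u - config.alpha_tau0) / (1.0 - config.alpha_tau0)
        shift = g * sum(
            beta * climate_centered.get(var, 0.0) for var, beta in config.alpha_slopes.items()
        )
        base = base + shift
    return max(base, config.alpha_floor)


@dataclass
class SyntheticDataset:
    community: CommunityTable
    metadata: SiteMetadata
    summary: InventorySummary
    truth: TruthRecord
    realized_overlap: pd.DataFrame


def generate_dataset(config: MetacommunityConfig | None = None) -> SyntheticDataset:
    """Generate a full metacommunity dataset plus ground truth.

    Substreams (pools are deterministic given the config): climate, site
    sizes, latent diversity quantiles, and community draws each consume an
    independent child of the global seed.
    """
    config = config or default_config()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_climate, rng_sizes, rng_u, rng_comm = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    pools, realized = build_species_pools(config)

    rows_meta, rows_truth = [], []
    site_defs = []
    for biome in config.biomes:
        for s in range(config.site_counts[biome]):
            site_id = f"{biome.replace(' ', '')}_{s + 1:03d}"
            clim = {}
            for var in config.climate_means[biome]:
                m = config.climate_means[biome][var]
                sd = config.climate_sds[biome][var]
                # truncate at +-3 sd so the climate support is bounded and the
                # edge-anchored quantile slopes hold exactly
                clim[var] = float(np.clip(rng_climate.normal(m, sd), m - 3 * sd, m + 3 * sd))
            if "map_mm" in clim:
                clim["map_mm"] = max(clim["map_mm"], 50.0)
            if "dry_months" in clim:
                clim["dry_months"] = float(np.clip(clim["dry_months"], 0.0, 12.0))
            site_defs.append((site_id, biome, clim))

    # edge-of-support reference for each coupled covariate (fixed by config,
    # not data-dependent): minimum for positive slopes, maximum for negative
    ref = {}
    for var in next(iter(config.climate_means.values())):
        beta = config.alpha_slopes.get(var, 0.0)
        lows = [config.climate_means[b][var] - 3 * config.climate_sds[b][var]
                for b in config.biomes]
        highs = [config.climate_means[b][var] + 3 * config.climate_sds[b][var]
                 for b in config.biomes]
        ref[var] = min(lows) if beta >= 0 else max(highs)

    records = []
    for site_id, biome, clim in site_defs:
        mean_n, sd_n = config.stems_per_site[biome]
        # lognormal parameterized by its own mean/sd
        cv2 = (sd_n / mean_n) ** 2
        sigma_ln = float(np.sqrt(np.log1p(cv2)))
        mu_ln = float(np.log(mean_n) - 0.5 * sigma_ln**2)
        N = max(int(round(rng_sizes.lognormal(mu_ln, sigma_ln))), 20)
        u = float(rng_u.uniform())
        centered = {var: clim[var] - ref[var] for var in ref}
        alpha = _site_alpha(u, centered, config)
        comm = sample_site_community(pools[biome], alpha, N, rng_comm, pool_limit="cap")
        for sp, cnt in comm.items():
            records.append((site_id, sp, cnt))
        rows_meta.append({"site_id": site_id, "biome": biome,
                          "latitude": np.nan, "longitude": np.nan, **clim})
        rows_truth.append({"site_id": site_id, "biome": biome, "true_alpha": alpha,
                           "true_N": N, "u": u})

    community = build_community_table(pd.DataFrame(records))
    metadata = SiteMetadata(df=pd.DataFrame(rows_meta))
    truth_df = pd.DataFrame(rows_truth)
    summary = InventorySummary(
        df=pd.DataFrame(
            {
                "site_id": truth_df["site_id"],
                "n_individuals": truth_df["true_N"],
                "n_species": community.site_richness().reindex(truth_df["site_id"]).values,
            }
        )
    )
    truth = TruthRecord(
        site_truth=truth_df,
        pools=pools,
        alpha_slopes=dict(config.alpha_slopes),
        alpha_tau0=config.alpha_tau0,
        alpha_mu0=config.alpha_mu0,
        alpha_sigma0=config.alpha_sigma0,
        climate_reference=ref,
    )
    return SyntheticDataset(
        community=community, metadata=metadata, summary=summary,
        truth=truth, realized_overlap=realized,
    )
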