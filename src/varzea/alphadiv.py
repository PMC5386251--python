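"""Alpha and regional (gamma) diversity: Fisher's alpha, accumulation curves,
coverage-based rarefaction/extrapolation for incidence data, biome occupancy.

Fisher's alpha is the parameter of Fisher's log-series, defined implicitly by
``S = alpha * ln(1 + N / alpha)`` for ``S`` species among ``N`` individuals.
Regional richness is compared both by sampling effort (random site
accumulation, optionally rescaled to individuals) and by sample completeness
(coverage), where coverage is the estimated proportion of incidences that
belong to already-detected species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "fishers_alpha",
    "alpha_records",
    "AlphaRecord",
    "IncidenceSummary",
    "RarefactionCurve",
    "accumulation_curves",
    "exact_accumulation",
    "rescale_to_individuals",
    "incidence_frequencies",
    "sample_coverage",
    "coverage_curve",
    "occupancy_table",
]


def fishers_alpha(S: int, N: float) -> float:
    """Solve ``S = alpha * ln(1 + N / alpha)`` for alpha.

    Returns ``nan`` (the undefined flag) when ``S == N``: the left side
    approaches N only as alpha -> infinity, so no finite root exists.  Raises
    for the impossible case ``S > N``.  The root is bracketed in
    [1e-8, 1e8] with outward expansion and polished to |S - alpha ln(1+N/alpha)|
    < 1e-10.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if S > N:
        raise ValueError(f"S={S} exceeds N={N}")
    if S == N:
        return float("nan")

    def f(a: float) -> float:
        return a * math.log1p(N / a) - S

    lo, hi = 1e-8, 1e8
    while f(hi) < 0:  # S very close to N: expected S at alpha=hi still below S
        hi *= 10
        if hi > 1e300:
            return float("nan")
    alpha = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    assert abs(f(alpha)) < 1e-8 * max(1.0, S)
    return float(alpha)


@dataclass(frozen=True)
class AlphaRecord:
    site_id: str
    S: int
    N: int
    alpha: float  # nan == undefined (S == N)


def alpha_records(summary_df: pd.DataFrame) -> pd.DataFrame:
    """Fisher's alpha for every site of an (S, N) summary table.

    Returns a frame with columns site_id, S, N, alpha; sites where every
    individual is a distinct species (S == N) get ``alpha = NaN`` and a
    logged count — these are excluded from alpha-based models downstream.
    """
    out = pd.DataFrame(
        {
            "site_id": summary_df["site_id"],
            "S": summary_df["n_species"].astype(int),
            "N": summary_df["n_individuals"].astype(int),
        }
    )
    out["alpha"] = [fishers_alpha(s, n) for s, n in zip(out["S"], out["N"])]
    n_undef = int(out["alpha"].isna().sum())
    if n_undef:
        logger.info("%d sites with S == N (alpha undefined), flagged NaN", n_undef)
    return out


# ---------------------------------------------------------------------------
# size-based accumulation


@dataclass
class RarefactionCurve:
    """Expected richness along an effort axis.

    ``mode`` is ``size`` (effort = sampling units or individuals) or
    ``coverage``.  ``spread`` holds the min/max envelope across random
    orderings (size mode) and is empty for analytic curves.
    """

    effort: np.ndarray
    richness: np.ndarray
    mode: str
    label: str = ""
    spread_low: np.ndarray | None = None
    spread_high: np.ndarray | None = None
    coverage: np.ndarray | None = None
    extrapolated: np.ndarray | None = None  # bool mask, coverage mode

    def to_frame(self) -> pd.DataFrame:
        d = {"effort": self.effort, "richness": self.richness}
        if self.spread_low is not None:
            d["spread_low"] = self.spread_low
            d["spread_high"] = self.spread_high
        if self.coverage is not None:
            d["coverage"] = self.coverage
        if self.extrapolated is not None:
            d["extrapolated"] = self.extrapolated
        return pd.DataFrame(d).assign(mode=self.mode, label=self.label)


def _site_incidence(table: CommunityTable, sites: list[str]) -> list[frozenset[str]]:
    sets = table.site_sets()
    return [sets[s] for s in sites]


def accumulation_curves(
    table: CommunityTable,
    biome_of: pd.Series | None = None,
    n_curves: int = 10,
    seed: int | None = None,
    include_pooled: bool = True,
) -> dict[str, RarefactionCurve]:
    """Random species-accumulation curves per biome (plus pooled all-sites).

    ``n_curves`` random orderings of sites without replacement; the curve is
    the mean cumulative distinct-species count per number of sites, with the
    min/max envelope across orderings as spread.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    if biome_of is not None:
        for site in table.sites:
            groups.setdefault(str(biome_of[site]), []).append(site)
    if include_pooled or biome_of is None:
        groups["all"] = table.sites
    out = {}
    for label, sites in groups.items():
        incid = _site_incidence(table, sites)
        t = len(sites)
        curves = np.empty((n_curves, t), dtype=float)
        for ci in range(n_curves):
            order = rng.permutation(t)
            seen: set[str] = set()
            for k, idx in enumerate(order):
                seen |= incid[idx]
                curves[ci, k] = len(seen)
        out[label] = RarefactionCurve(
            effort=np.arange(1, t + 1, dtype=float),
            richness=curves.mean(axis=0),
            spread_low=curves.min(axis=0),
            spread_high=curves.max(axis=0),
            mode="size",
            label=label,
        )
    return out


def exact_accumulation(table: CommunityTable, sites: list[str] | None = None) -> RarefactionCurve:
    """Analytic mean accumulation curve over *all* site orderings.

    The expectation over random orderings at k sites is the classic
    sample-based rarefaction ``E[S(k)] = sum_i (1 - C(T - Y_i, k)/C(T, k))``.
    """
    sites = sites if sites is not None else table.sites
    inc = incidence_frequencies(table, sites)
    T = inc.T
    k = np.arange(1, T + 1)
    rich = np.array([_interp_richness(inc, kk) for kk in k])
    return RarefactionCurve(effort=k.astype(float), richness=rich, mode="size", label="exact")


def rescale_to_individuals(curve: RarefactionCurve, mean_stems_per_site: float) -> RarefactionCurve:
    """Re-express the effort axis in individuals via the mean stems per site."""
    if mean_stems_per_site <= 0:
        raise ValueError("mean stems per site must be positive")
    return RarefactionCurve(
        effort=curve.effort * mean_stems_per_site,
        richness=curve.richness,
        spread_low=curve.spread_low,
        spread_high=curve.spread_high,
        mode=curve.mode,
        label=curve.label,
    )


# ---------------------------------------------------------------------------
# coverage-based rarefaction (incidence data)


@dataclass
class IncidenceSummary:
    """Incidence-frequency summary of a region's sampling units.

    T sampling units; Y_i = number of units in which species i occurs;
    U = sum of Y_i; Q1/Q2 = number of uniques/duplicates.
    """

    T: int
    Y: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=int)
        if self.T < 1 or len(self.Y) == 0:
            raise ValueError("need at least one sampling unit and one species")
        if self.Y.min() < 1 or self.Y.max() > self.T:
            raise ValueError("incidence counts must satisfy 1 <= Y_i <= T")

    @property
    def S_obs(self) -> int:
        return len(self.Y)

    @property
    def U(self) -> int:
        return int(self.Y.sum())

    @property
    def Q1(self) -> int:
        return int((self.Y == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.Y == 2).sum())


def incidence_frequencies(table: CommunityTable, sites: list[str] | None = None) -> IncidenceSummary:
    """Exact per-species incidence counts over a region's sites."""
    sites = sites if sites is not None else table.sites
    if not sites:
        raise ValueError("region has no sites")
    sets = table.site_sets()
    counts: dict[str, int] = {}
    for s in sites:
        for sp in sets[s]:
            counts[sp] = counts.get(sp, 0) + 1
    return IncidenceSummary(T=len(sites), Y=np.array(sorted(counts.values())))


def sample_coverage(inc: IncidenceSummary) -> tuple[float, float]:
    """Estimated sample coverage (C_hat, deficit = 1 - C_hat) at full effort.

    ``C_hat = 1 - (Q1/U) * [(T-1) Q1 / ((T-1) Q1 + 2 Q2)]``.
    """
    if inc.T < 2:
        raise ValueError("coverage estimator undefined for T < 2 sampling units")
    if inc.Q1 == 0:
        return 1.0, 0.0
    c_hat = 1.0 - (inc.Q1 / inc.U) * ((inc.T - 1) * inc.Q1 / ((inc.T - 1) * inc.Q1 + 2 * inc.Q2))
    return float(c_hat), float(1.0 - c_hat)


def _lchoose(n: np.ndarray | int, k: int) -> np.ndarray | float:
    """log C(n, k), elementwise; -inf where n < k."""
    from scipy.special import gammaln

    n = np.asarray(n, dtype=float)
    res = gammaln(n + 1) - gammaln(np.maximum(n - k, 0) + 1) - gammaln(k + 1)
    return np.where(n >= k, res, -np.inf)


def _interp_richness(inc: IncidenceSummary, t: int) -> float:
    """E[S] among t of T units: S_obs - sum_i C(T-Y_i, t)/C(T, t)."""
    T, Y = inc.T, inc.Y
    lc_T = _lchoose(T, t)
    lc = _lchoose(T - Y, t)
    return float(inc.S_obs - np.sum(np.exp(lc - lc_T)))


def _interp_coverage(inc: IncidenceSummary, t: int) -> float:
    """Estimated coverage among t < T units.

    Good-Turing form ``1 - sum_i (Y_i/U) C(T-Y_i, t) / C(T-1, t)``; the
    unbiased denominator C(T-1, t) makes the curve continuous with the
    full-sample estimator at t = T.
    """
    T, Y = inc.T, inc.Y
    lc_T1 = _lchoose(T - 1, t)
    lc = _lchoose(T - Y, t)
    return float(1.0 - np.sum((Y / inc.U) * np.exp(lc - lc_T1)))


def chao_undetected(inc: IncidenceSummary) -> float:
    """Chao2-type estimate of undetected species Q0_hat.

    ``((T-1)/T) * Q1^2 / (2 Q2)``; when Q2 = 0 the bias-corrected
    ``((T-1)/T) * Q1 (Q1 - 1) / 2`` convention is used with a warning.
    """
    T, Q1, Q2 = inc.T, inc.Q1, inc.Q2
    if Q2 > 0:
        return (T - 1) / T * Q1**2 / (2 * Q2)
    logger.warning("Q2 = 0; falling back to Q1(Q1-1)/2 undetected-species convention")
    return (T - 1) / T * Q1 * (Q1 - 1) / 2


def coverage_curve(
    inc: IncidenceSummary, t_grid: np.ndarray | None = None, max_extrapolation: int | None = None
) -> RarefactionCurve:
    """Coverage-based rarefaction/extrapolation curve over sampling units.

    Interpolated richness uses the exact hypergeometric expectation;
    extrapolated richness (t > T) follows the Chao-type asymptote
    ``S_obs + Q0_hat * (1 - (1 - Q1/(Q1 + T*Q0_hat))**(t - T))``.  Coverage at
    t > T decays geometrically toward 1.
    """
    T = inc.T
    if T < 2:
        raise ValueError("coverage curve requires T >= 2 sampling units")
    if max_extrapolation is None:
        max_extrapolation = 2 * T
    if t_grid is None:
        t_grid = np.arange(1, max_extrapolation + 1)
    t_grid = np.asarray(t_grid, dtype=int)
    if t_grid.min() < 1:
        raise ValueError("effort grid must be positive")
    if t_grid.max() > max_extrapolation:
        raise ValueError("effort grid exceeds the extrapolation bound")
    c_full, _ = sample_coverage(inc)
    q0 = chao_undetected(inc)
    rich = np.empty(len(t_grid))
    cov = np.empty(len(t_grid))
    extrap = t_grid > T
    for i, t in enumerate(t_grid):
        if t < T:
            rich[i] = _interp_richness(inc, int(t))
            cov[i] = _interp_coverage(inc, int(t))
        elif t == T:
            rich[i] = inc.S_obs
            cov[i] = c_full
        else:
            tstar = t - T
            if q0 > 0:
                rich[i] = inc.S_obs + q0 * (1.0 - (1.0 - inc.Q1 / (inc.Q1 + T * q0)) ** tstar)
            else:
                rich[i] = inc.S_obs
            if inc.Q1 > 0:
                ratio = (T - 1) * inc.Q1 / ((T - 1) * inc.Q1 + 2 * inc.Q2)
                cov[i] = 1.0 - (inc.Q1 / inc.U) * ratio ** (tstar + 1)
            else:
                cov[i] = 1.0
    return RarefactionCurve(
        effort=t_grid.astype(float),
        richness=rich,
        coverage=cov,
        extrapolated=extrap,
        mode="coverage",
    )


# ---------------------------------------------------------------------------
# biome occupancy


@dataclass
class OccupancyTable:
    """Counts of species occurring in exactly 1..B biomes, per biome and overall."""

    counts: pd.DataFrame       # index biome, columns 1..B (+ 'total')
    proportions: pd.DataFrame  # same shape, rows sum to 1 over 1..B
    n_exclusive: int           # species in exactly one biome, overall
    n_all_biomes: int          # species present in every biome
    n_species: int

    def to_frame(self) -> pd.DataFrame:
        return self.counts


def occupancy_table(table: CommunityTable, biome_of: pd.Series) -> OccupancyTable:
    """Tabulate species' biome occupancy from incidence.

    For each biome, the number (and proportion) of its species occurring in
    exactly k biomes, k = 1..B.
    """
    unlabeled = sorted(set(table.sites) - set(biome_of.index))
    if unlabeled:
        raise ValueError(f"sites without a biome label: {unlabeled}")
    df = table.df.assign(biome=table.df["site_id"].map(biome_of))
    sp_biomes = df.groupby("species")["biome"].agg(lambda b: frozenset(b))
    n_occ = sp_biomes.map(len)
    biomes = sorted(set(biome_of))
    B = len(biomes)
    counts = pd.DataFrame(0, index=biomes, columns=range(1, B + 1))
    for bs, k in zip(sp_biomes, n_occ):
        for b in bs:
            counts.loc[b, k] += 1
    counts["total"] = counts.sum(axis=1)
    props = counts[range(1, B + 1)].div(counts["total"], axis=0)
    return OccupancyTable(
        counts=counts,
        proportions=props,
        n_exclusive=int((n_occ == 1).sum()),
        n_all_biomes=int((n_occ == B).sum()),
        n_species=len(sp_biomes),
    )
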