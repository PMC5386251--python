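"""Presence-absence compositional dissimilarity between sites.

Pairwise dissimilarity is computed from the 2x2 incidence counts of a site
pair: ``a`` shared species, ``b`` species only in the first site, ``c`` only
in the second.  Two metrics are provided:

* Forbes F' — a similarity corrected for partial sampling,
  ``F' = a(n + sqrt(n)) / (a(n + sqrt(n)) + 3/2 * b * c)`` with ``n = a+b+c``;
  we return the dissimilarity ``1 - F'`` throughout.
* Simpson turnover ``beta_sim = min(b, c) / (a + min(b, c))``, insensitive to
  richness differences (0 for nested pairs).

Both use incidence only, so abundance-collection differences between source
inventories cannot leak into the dissimilarity structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .core import CommunityTable

__all__ = [
    "PairCounts",
    "pair_counts",
    "forbes_fprime",
    "simpson_dissim",
    "dissimilarity_matrix",
    "matrix_correlation",
    "mantel_test",
]


@dataclass(frozen=True)
class PairCounts:
    """Incidence cross-tabulation of one site pair."""

    a: int  # shared
    b: int  # only in first
    c: int  # only in second

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c


def pair_counts(x: frozenset | set, y: frozenset | set) -> PairCounts:
    """Exact shared / unique species counts for two presence sets."""
    a = len(x & y)
    return PairCounts(a=a, b=len(x) - a, c=len(y) - a)


def forbes_fprime(pc: PairCounts) -> float:
    """Forbes F' dissimilarity (1 - F'), in [0, 1].

    Nested or identical pairs (b*c = 0 with shared species) score 0; fully
    disjoint pairs score 1.  Undefined when either set is empty.
    """
    if pc.n == 0 or (pc.a == 0 and pc.b * pc.c == 0):
        raise ValueError("Forbes F' undefined for an empty site")
    if pc.b == 0 or pc.c == 0:
        return 0.0
    if pc.a == 0:
        return 1.0
    n = pc.n
    num = pc.a * (n + np.sqrt(n))
    return float(1.0 - num / (num + 1.5 * pc.b * pc.c))


def simpson_dissim(pc: PairCounts) -> float:
    """Simpson presence-absence dissimilarity min(b,c)/(a+min(b,c))."""
    m = min(pc.b, pc.c)
    if pc.a + m == 0:
        raise ValueError("Simpson dissimilarity undefined for an empty site")
    return float(m / (pc.a + m))


def _incidence_matrix(table: CommunityTable) -> tuple[np.ndarray, list[str]]:
    sites = table.sites
    species = table.species
    sp_index = {s: i for i, s in enumerate(species)}
    site_index = {s: i for i, s in enumerate(sites)}
    X = np.zeros((len(sites), len(species)), dtype=np.int64)
    X[
        table.df["site_id"].map(site_index).to_numpy(),
        table.df["species"].map(sp_index).to_numpy(),
    ] = 1
    return X, sites


def dissimilarity_matrix(table: CommunityTable, metric: str = "forbes") -> DistanceMatrix:
    """All pairwise site dissimilarities under ``forbes`` or ``simpson``.

    Site order follows first appearance in the table.  Empty sites cannot
    occur in a valid :class:`~varzea.core.CommunityTable` (abundance > 0), but
    fewer than two sites is an error.
    """
    if metric not in ("forbes", "simpson"):
        raise ValueError(f"metric must be 'forbes' or 'simpson', got {metric!r}")
    X, sites = _incidence_matrix(table)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for a dissimilarity matrix")
    A = X @ X.T                      # shared species counts
    richness = np.diag(A).astype(float)
    B = richness[:, None] - A        # only in row site
    C = richness[None, :] - A        # only in column site
    if metric == "forbes":
        n = A + B + C
        num = A * (n + np.sqrt(n))
        with np.errstate(invalid="ignore", divide="ignore"):
            D = 1.0 - num / (num + 1.5 * B * C)
        D[(B == 0) | (C == 0)] = 0.0
        D[(A == 0) & (B > 0) & (C > 0)] = 1.0
    else:
        m = np.minimum(B, C)
        D = m / (A + m)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # symmetric by construction; guard float noise
    return DistanceMatrix(D, ids=sites)


def matrix_correlation(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson r between two dissimilarity matrices over lower-triangle pairs."""
    if list(d1.ids) != list(d2.ids):
        raise ValueError("site orders differ between matrices")
    return float(stats.pearsonr(d1.condensed_form(), d2.condensed_form())[0])


def rank_correlation(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Spearman rank correlation over lower-triangle pairs."""
    if list(d1.ids) != list(d2.ids):
        raise ValueError("site orders differ between matrices")
    return float(stats.spearmanr(d1.condensed_form(), d2.condensed_form())[0])


def mantel_test(
    d1: DistanceMatrix, d2: DistanceMatrix, permutations: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Optional Mantel permutation test (r, p) for matrix association."""
    from skbio.stats.distance import mantel

    r, p, _ = mantel(d1, d2, permutations=permutations, seed=seed)
    return float(r), float(p)


def matrix_to_frame(d: DistanceMatrix) -> pd.DataFrame:
    """Square data frame with site ids as header row/column (CSV export form)."""
    return pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids))
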