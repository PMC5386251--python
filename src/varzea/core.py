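"""Data model and I/O for site x species community tables.

The single ingestion format is a long ("three-column") table of
(site_id, species_name, abundance) records.  Species names are normalized to
canonical ``Genus epithet`` form, obviously non-binomial determinations
("sp.", "indet.", single tokens) are flagged and dropped, duplicate
(site, species) rows are summed, and non-positive abundances are rejected.

Abundance is stored as a positive real: some source inventories report
importance values rather than stem counts, so operations that need integer
counts (rarefaction by individuals) round half-to-even and warn.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five Brazilian phytogeographic domains used as reference labels.
BRAZILIAN_BIOMES = ("Amazon", "Atlantic Forest", "Cerrado", "Caatinga", "Pampas")

#: Regexes marking a normalized name as an invalid (non-binomial) determination.
#: Users may pass their own list to loosen or tighten the exclusion predicate.
DEFAULT_INVALID_PATTERNS: tuple[str, ...] = (
    r"^\S+$",            # single token: genus only
    r"(?i)\bspp?\.?$",   # "Cedrela sp.", "Inga spp"
    r"(?i)\bindet",      # indeterminate
    r"(?i)\bcf\.",       # uncertain determination
    r"(?i)\baff\.",
)


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


def normalize_species_name(raw: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Return the canonical form of a species name.

    Trims, collapses internal whitespace, turns underscores into spaces,
    capitalizes the genus and lower-cases the remaining tokens.  A synonym
    map (old canonical name -> accepted name) is applied *after*
    normalization.  Validity is a separate question: see
    :func:`is_valid_binomial`.
    """
    if not raw or not str(raw).strip():
        raise ValueError("empty species name")
    name = re.sub(r"[\s_]+", " ", str(raw)).strip()
    tokens = name.split(" ")
    tokens = [tokens[0].capitalize()] + [t.lower() for t in tokens[1:]]
    name = " ".join(tokens)
    if synonym_map:
        name = synonym_map.get(name, name)
    return name


def is_valid_binomial(name: str, invalid_patterns: Sequence[str] = DEFAULT_INVALID_PATTERNS) -> bool:
    """True if a normalized name looks like a valid binomial determination."""
    return not any(re.search(p, name) for p in invalid_patterns)


@dataclass
class CommunityTable:
    """Aggregated long-format site x species abundance records.

    ``df`` has columns ``site_id`` (str), ``species`` (canonical binomial str)
    and ``abundance`` (positive float); at most one row per (site, species).
    """

    df: pd.DataFrame
    n_input_rows: int = 0
    n_dropped_nonpositive: int = 0
    invalid_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = {"site_id", "species", "abundance"} - set(self.df.columns)
        if missing:
            raise FormatError(f"community table missing columns: {sorted(missing)}")
        if (self.df["abundance"] <= 0).any():
            raise ValueError("community table contains non-positive abundances")
        if self.df.duplicated(["site_id", "species"]).any():
            raise ValueError("community table contains unaggregated duplicate records")

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.df["site_id"]))

    @property
    def species(self) -> list[str]:
        return sorted(pd.unique(self.df["species"]))

    @property
    def n_records(self) -> int:
        return len(self.df)

    def site_sets(self) -> dict[str, frozenset[str]]:
        """Per-site species sets (presence-absence view)."""
        return {
            site: frozenset(grp["species"])
            for site, grp in self.df.groupby("site_id", sort=False)
        }

    def site_totals(self) -> pd.Series:
        """Total abundance per site (N), rounded half-to-even to integers."""
        totals = self.df.groupby("site_id", sort=False)["abundance"].sum()
        if not np.allclose(totals, np.round(totals)):
            logger.warning(
                "non-integer site abundance totals (importance values?); "
                "rounding half-to-even for individual counts"
            )
        return totals.round().astype(int)

    def site_richness(self) -> pd.Series:
        return self.df.groupby("site_id", sort=False)["species"].nunique()


def build_community_table(
    records: pd.DataFrame,
    *,
    synonym_map: Mapping[str, str] | None = None,
    invalid_patterns: Sequence[str] = DEFAULT_INVALID_PATTERNS,
) -> CommunityTable:
    """Normalize, filter and aggregate raw (site, species, abundance) rows."""
    df = records.copy()
    df.columns = ["site_id", "species", "abundance"]
    n_input = len(df)
    df["site_id"] = df["site_id"].astype(str).str.strip()
    df["abundance"] = pd.to_numeric(df["abundance"], errors="coerce")
    bad_abund = df["abundance"].isna() | (df["abundance"] <= 0)
    n_dropped = int(bad_abund.sum())
    if n_dropped:
        logger.info("dropped %d rows with missing/non-positive abundance", n_dropped)
    df = df.loc[~bad_abund]
    df["species"] = [normalize_species_name(s, synonym_map) for s in df["species"]]
    valid = df["species"].map(lambda s: is_valid_binomial(s, invalid_patterns))
    invalid_names = sorted(set(df.loc[~valid, "species"]))
    if invalid_names:
        logger.info("flagged %d invalid (non-binomial) names", len(invalid_names))
    df = df.loc[valid]
    agg = (
        df.groupby(["site_id", "species"], sort=False, as_index=False)["abundance"]
        .sum()
        .sort_values(["site_id", "species"], kind="mergesort")
        .reset_index(drop=True)
    )
    return CommunityTable(
        df=agg,
        n_input_rows=n_input,
        n_dropped_nonpositive=n_dropped,
        invalid_names=invalid_names,
    )


_SITE_PAT = re.compile(r"(?i)site|plot|inventor|local")
_SPECIES_PAT = re.compile(r"(?i)spec|taxon|binom")
_ABUND_PAT = re.compile(r"(?i)abund|count|n_?ind|import|stems?")


def _identify_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Pick (site, species, abundance) columns by header name, else position."""
    cols = [str(c) for c in df.columns]
    site = next((c for c in cols if _SITE_PAT.search(c)), None)
    sp = next((c for c in cols if c != site and _SPECIES_PAT.search(c)), None)
    ab = next((c for c in cols if c not in (site, sp) and _ABUND_PAT.search(c)), None)
    if site and sp and ab:
        return df[[site, sp, ab]]
    if len(cols) < 3:
        raise FormatError(
            f"need 3 columns (site, species, abundance); got {cols}"
        )
    return df.iloc[:, :3]


def read_community_table(
    path: str | Path,
    dialect: str | None = None,
    *,
    synonym_map: Mapping[str, str] | None = None,
    invalid_patterns: Sequence[str] = DEFAULT_INVALID_PATTERNS,
) -> CommunityTable:
    """Read a three-column long table from CSV/TSV/XLSX.

    ``dialect`` is inferred from the file suffix when not given.  Columns are
    identified by header keywords (site/species/abundance) or, failing that,
    by position.  XLSX reads the first sheet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower()
        )
        if dialect is None:
            raise FormatError(f"cannot infer dialect from suffix {path.suffix!r}")
    if dialect == "csv":
        raw = pd.read_csv(path)
    elif dialect == "tsv":
        raw = pd.read_csv(path, sep="\t")
    elif dialect == "xlsx":
        raw = pd.read_excel(path, sheet_name=0)
    else:
        raise FormatError(f"unknown dialect {dialect!r} (expected csv, tsv or xlsx)")
    # headerless files: pandas promoted a data row to the header
    if len(raw.columns) >= 3:
        third = str(raw.columns[2])
        try:
            float(third)
            raw = pd.concat(
                [pd.DataFrame([list(raw.columns)], columns=raw.columns), raw],
                ignore_index=True,
            )
            raw.columns = ["site_id", "species", "abundance"] + [
                f"extra_{i}" for i in range(len(raw.columns) - 3)
            ]
        except ValueError:
            pass
    return build_community_table(
        _identify_columns(raw),
        synonym_map=synonym_map,
        invalid_patterns=invalid_patterns,
    )


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    """Write the canonical long table as CSV (round-trips losslessly)."""
    table.df.to_csv(path, index=False)


@dataclass
class SiteMetadata:
    """Per-site biome labels, coordinates and pre-extracted climate values.

    Climate variables arrive as a table (mean annual temperature ``mat`` in
    degrees C, ``map_mm`` in mm/yr, precipitation seasonality ``p_seasonality``
    as CV%, temperature seasonality ``t_seasonality`` as sd x 100, and
    ``dry_months``); missing values are allowed and flagged out of climate
    models downstream.
    """

    df: pd.DataFrame

    CLIMATE_VARS = ("mat", "map_mm", "p_seasonality", "t_seasonality", "dry_months")

    def __post_init__(self) -> None:
        missing = {"site_id", "biome"} - set(self.df.columns)
        if missing:
            raise FormatError(f"site metadata missing columns: {sorted(missing)}")
        if self.df["site_id"].duplicated().any():
            dups = self.df.loc[self.df["site_id"].duplicated(), "site_id"].tolist()
            raise ValueError(f"duplicate site_id in metadata: {dups}")

    def biome_of(self) -> pd.Series:
        return self.df.set_index("site_id")["biome"]

    def check_covers(self, table: CommunityTable) -> None:
        """Every site in the community table must have exactly one metadata row."""
        missing = sorted(set(table.sites) - set(self.df["site_id"]))
        if missing:
            raise ValueError(f"sites without metadata: {missing}")

    def climate(self, variables: Iterable[str] | None = None) -> pd.DataFrame:
        """Climate table indexed by site_id; rows with any NaN are kept (callers drop)."""
        variables = list(variables) if variables is not None else [
            v for v in self.CLIMATE_VARS if v in self.df.columns
        ]
        return self.df.set_index("site_id")[variables].apply(pd.to_numeric)


def read_site_metadata(
    path: str | Path, *, strict_biomes: bool = True, mat_times_10: bool = False
) -> SiteMetadata:
    """Read the site-metadata CSV.

    ``mat_times_10`` divides the temperature column by 10 for sources that
    follow the grid convention of storing degrees C x 10.
    """
    df = pd.read_csv(path)
    df["site_id"] = df["site_id"].astype(str)
    if strict_biomes:
        bad = sorted(set(df["biome"]) - set(BRAZILIAN_BIOMES))
        if bad:
            raise ValueError(
                f"unknown biome labels {bad}; expected {BRAZILIAN_BIOMES} "
                "(pass strict_biomes=False for custom labels)"
            )
    if mat_times_10 and "mat" in df.columns:
        df["mat"] = pd.to_numeric(df["mat"]) / 10.0
    return SiteMetadata(df=df)


@dataclass
class InventorySummary:
    """Per-site (N individuals, S species) summaries as published per source.

    These are the inputs to Fisher's alpha when the full abundance table is
    not available for a site.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"site_id", "n_individuals", "n_species"} - set(self.df.columns)
        if missing:
            raise FormatError(f"inventory summary missing columns: {sorted(missing)}")
        bad = self.df[
            (self.df["n_species"] < 1) | (self.df["n_species"] > self.df["n_individuals"])
        ]
        if len(bad):
            raise ValueError(
                f"invalid (S, N) pairs (need 1 <= S <= N) for sites: "
                f"{bad['site_id'].tolist()}"
            )


def read_inventory_summary(path: str | Path) -> InventorySummary:
    df = pd.read_csv(path)
    df["site_id"] = df["site_id"].astype(str)
    return InventorySummary(df=df)


def summary_from_table(table: CommunityTable) -> InventorySummary:
    """Derive (S, N) per site from a full abundance table."""
    n = table.site_totals()
    s = table.site_richness()
    df = pd.DataFrame(
        {"site_id": n.index, "n_individuals": n.values, "n_species": s.reindex(n.index).values}
    ).reset_index(drop=True)
    return InventorySummary(df=df)


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV map (e.g. synonym -> accepted, genus -> family)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("mapping file needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


@dataclass
class TaxonTallies:
    """Distinct species / genus / family counts, overall and per biome."""

    n_species: int
    n_genera: int
    n_families: int | None  # None when no genus->family map supplied
    per_biome: pd.DataFrame  # index biome, columns n_species / n_genera / n_families


def tally_taxa(
    table: CommunityTable,
    metadata: SiteMetadata,
    family_map: Mapping[str, str] | None = None,
) -> TaxonTallies:
    """Count distinct species, genera (first binomial token) and families.

    Families require a user-supplied genus->family map and are reported as
    ``None`` (unavailable) otherwise.
    """
    biome_of = metadata.biome_of()
    unlabeled = sorted(set(table.sites) - set(biome_of.index))
    if unlabeled:
        raise ValueError(f"sites without a biome label: {unlabeled}")

    def counts(species: Iterable[str]) -> tuple[int, int, int | None]:
        sp = set(species)
        genera = {s.split(" ")[0] for s in sp}
        fams = None
        if family_map is not None:
            fams = len({family_map[g] for g in genera if g in family_map})
        return len(sp), len(genera), fams

    n_sp, n_gen, n_fam = counts(table.df["species"])
    rows = {}
    df = table.df.assign(biome=table.df["site_id"].map(biome_of))
    for biome, grp in df.groupby("biome", sort=True):
        rows[biome] = counts(grp["species"])
    per_biome = pd.DataFrame(
        rows, index=["n_species", "n_genera", "n_families"]
    ).T
    return TaxonTallies(n_species=n_sp, n_genera=n_gen, n_families=n_fam, per_biome=per_biome)


def species_checklist(table: CommunityTable, metadata: SiteMetadata) -> pd.DataFrame:
    """Species x biome site-frequency checklist (S2-Table-like layout)."""
    biome_of = metadata.biome_of()
    df = table.df.assign(biome=table.df["site_id"].map(biome_of))
    freq = (
        df.groupby(["species", "biome"])["site_id"].nunique().unstack(fill_value=0)
    )
    freq["total_sites"] = freq.sum(axis=1)
    return freq.sort_index()
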