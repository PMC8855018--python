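"""Structural and functional community metrics per site.

Works on long- or wide-format site x taxon abundance tables for three kinds
of survey data: plant quadrat-presence counts (0-10 over ten 1-m2 quadrats),
butterfly transect counts, and orthopteran flush counts.  Records may be
resolved to species, to genus only ("Chorthippus sp."), or left unidentified;
the resolution flag drives how each record enters richness, evenness and
trait averaging.

Functional structure is summarised by community-weighted means (CWM) of
dispersal, specialization and (for plants) insect-pollination dependence,
with the specialization of plants measured by the co-occurrence index
theta_wb = gamma / mu(alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "richness",
    "total_abundance",
    "pielou_evenness",
    "community_weighted_mean",
    "theta_wb",
    "pollination_dependence",
    "propagate_genus_traits",
    "site_metrics",
    "SPECIES",
    "GENUS",
    "UNIDENTIFIED",
]

SPECIES = "species"
GENUS = "genus"
UNIDENTIFIED = "unidentified"
_RESOLUTIONS = (SPECIES, GENUS, UNIDENTIFIED)


@dataclass
class CommunityMatrix:
    """Site x taxon abundances with per-taxon resolution flags.

    ``abundance`` is a wide DataFrame (rows = sites, columns = taxa);
    ``resolution`` maps each taxon column to 'species', 'genus' or
    'unidentified'; ``genus_of`` maps each identified taxon to its genus
    (for the congeneric-collapse richness rule and genus-trait
    propagation).  Plant abundances are quadrat-presence counts and must
    not exceed the number of quadrats (10).
    """

    abundance: pd.DataFrame
    resolution: dict[str, str]
    genus_of: dict[str, str]
    n_quadrats: int | None = None  # set for plant (quadrat) data

    def __post_init__(self) -> None:
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")
        for t in self.abundance.columns:
            r = self.resolution.get(t, SPECIES)
            if r not in _RESOLUTIONS:
                raise ValueError(f"unknown resolution {r!r} for taxon {t!r}")
        if self.n_quadrats is not None:
            if (self.abundance.values > self.n_quadrats).any():
                raise ValueError(
                    f"plant abundances exceed the number of quadrats ({self.n_quadrats})"
                )

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, n_quadrats: int | None = None
    ) -> "CommunityMatrix":
        """Build from a long table with columns site, taxon, resolution,
        abundance and (optionally) genus."""
        required = {"site", "taxon", "resolution", "abundance"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long community table lacks columns: {sorted(missing)}")
        wide = (
            df.pivot_table(index="site", columns="taxon", values="abundance",
                           aggfunc="sum", fill_value=0)
        )
        res = dict(df.drop_duplicates("taxon").set_index("taxon")["resolution"])
        if "genus" in df.columns:
            genus = dict(df.drop_duplicates("taxon").set_index("taxon")["genus"].dropna())
        else:
            genus = {t: t.split()[0] for t in wide.columns if res.get(t) != UNIDENTIFIED}
        return cls(abundance=wide, resolution=res, genus_of=genus, n_quadrats=n_quadrats)

    def to_long(self) -> pd.DataFrame:
        long = self.abundance.stack().rename("abundance").reset_index()
        long.columns = ["site", "taxon", "abundance"]
        long = long[long["abundance"] > 0]
        long["resolution"] = long["taxon"].map(lambda t: self.resolution.get(t, SPECIES))
        long["genus"] = long["taxon"].map(self.genus_of)
        return long.reset_index(drop=True)


def _row(site_row: pd.Series | dict) -> pd.Series:
    s = pd.Series(site_row, dtype=float)
    return s[s > 0]


def richness(
    site_row: pd.Series | dict,
    resolution: dict[str, str] | None = None,
    genus_of: dict[str, str] | None = None,
) -> int:
    """Number of distinct taxa present at the site.

    Unidentified records never count.  A genus-level record counts as one
    taxon only when no congeneric species-level record is present at the
    site, so 'Chorthippus sp.' alongside 'Chorthippus biguttulus' adds
    nothing (it may be the same species).
    """
    present = _row(site_row)
    resolution = resolution or {}
    genus_of = genus_of or {}
    count = 0
    species_genera = {
        genus_of.get(t, t.split()[0] if " " in t else t)
        for t in present.index
        if resolution.get(t, SPECIES) == SPECIES
    }
    for t in present.index:
        r = resolution.get(t, SPECIES)
        if r == SPECIES:
            count += 1
        elif r == GENUS:
            g = genus_of.get(t, t.split()[0])
            if g not in species_genera:
                count += 1
    return count


def total_abundance(site_row: pd.Series | dict) -> float:
    """Sum of abundances over all records, including genus-level and
    unidentified ones (for plants: total quadrat occurrences)."""
    return float(_row(site_row).sum())


def pielou_evenness(
    site_row: pd.Series | dict,
    resolution: dict[str, str] | None = None,
) -> float:
    """Pielou's evenness J = H' / ln(S) with natural-log Shannon entropy.

    Shares are computed over identified taxa (species- and genus-level
    records carry identity; unidentified ones do not).  Undefined (NaN)
    when fewer than two taxa are present.
    """
    present = _row(site_row)
    resolution = resolution or {}
    present = present[
        [t for t in present.index if resolution.get(t, SPECIES) != UNIDENTIFIED]
    ]
    s = len(present)
    if s < 2:
        return float("nan")
    p = present.values / present.values.sum()
    h = -(p * np.log(p)).sum()
    return float(h / math.log(s))


def community_weighted_mean(
    site_row: pd.Series | dict,
    traits: pd.Series | dict,
) -> float:
    """Abundance-weighted mean trait value over trait-known taxa.

    Taxa with unknown (missing) trait values are removed before weighting:
    weights are abundance shares among the remaining taxa only.  NaN when
    no present taxon has a known trait.
    """
    present = _row(site_row)
    traits = pd.Series(traits, dtype=float)
    known = [t for t in present.index if t in traits.index and pd.notna(traits[t])]
    if not known:
        return float("nan")
    a = present[known].values
    return float((a * traits[known].values).sum() / a.sum())


def theta_wb(occurrence: pd.DataFrame, focal: str) -> float:
    """Species specialization index theta_wb = gamma / mu(alpha).

    ``occurrence`` is a plot x species presence table from an independent
    co-occurrence database.  gamma is the cumulative number of distinct
    species over all plots containing the focal species; mu(alpha) is the
    mean richness of those plots.  theta_wb >= 1; it decreases with
    specialization (generalists co-occur with many species across varied
    plots).
    """
    if focal not in occurrence.columns:
        raise KeyError(f"focal species {focal!r} not in the occurrence table")
    occ = occurrence.astype(bool)
    plots = occ.index[occ[focal]]
    if len(plots) == 0:
        raise ValueError(f"focal species {focal!r} occurs in no plot")
    # identical plot compositions count once: theta is a composition-based
    # index, so resampling the same community adds no information
    sub = occ.loc[plots].drop_duplicates()
    gamma = int(sub.any(axis=0).sum())
    mu_alpha = float(sub.sum(axis=1).mean())
    return gamma / mu_alpha


def theta_wb_all_plots(occurrence: pd.DataFrame, focal: str) -> float:
    """Variant of :func:`theta_wb` with mu(alpha) averaged over every plot
    of the reference database rather than only plots hosting the focal
    species."""
    if focal not in occurrence.columns:
        raise KeyError(f"focal species {focal!r} not in the occurrence table")
    occ = occurrence.astype(bool).drop_duplicates()
    plots = occ.index[occ[focal]]
    if len(plots) == 0:
        raise ValueError(f"focal species {focal!r} occurs in no plot")
    gamma = int(occ.loc[plots].any(axis=0).sum())
    mu_alpha = float(occ.sum(axis=1).mean())
    return gamma / mu_alpha


def pollination_dependence(vector_records: dict[str, list[str] | None]) -> float:
    """Percentage of trait databases listing insects as a pollen vector.

    ``vector_records`` maps database name -> list of pollen vectors for the
    species (None when the database has no information).  Returns
    100 * (# databases listing 'insects') / (# databases with information),
    or NaN when no database is informative.
    """
    informative = {k: v for k, v in vector_records.items() if v is not None}
    if not informative:
        return float("nan")
    hits = sum(1 for v in informative.values() if "insects" in [x.lower() for x in v])
    return 100.0 * hits / len(informative)


def propagate_genus_traits(
    traits: pd.DataFrame,
    genus_of: dict[str, str],
    genus_taxa: list[str],
) -> pd.DataFrame:
    """Assign traits to genus-level records by congeneric unanimity.

    A genus-level taxon gains a trait value iff every congeneric species
    with a known value shares the same value; otherwise the trait stays
    missing.  Returns a copy of ``traits`` with one row added (or filled)
    per genus-level taxon.
    """
    out = traits.copy()
    for gtaxon in genus_taxa:
        genus = genus_of.get(gtaxon, gtaxon.split()[0])
        members = [
            t for t in traits.index
            if genus_of.get(t, t.split()[0] if " " in t else t) == genus and t != gtaxon
        ]
        if gtaxon not in out.index:
            out.loc[gtaxon] = np.nan
        for col in traits.columns:
            vals = traits.loc[members, col].dropna().unique() if members else []
            if len(vals) == 1:
                out.loc[gtaxon, col] = vals[0]
    return out


def site_metrics(
    matrix: CommunityMatrix,
    traits: pd.DataFrame | None = None,
    trait_columns: tuple[str, ...] = ("dispersal", "specialization"),
) -> pd.DataFrame:
    """Per-site metric table: richness, abundance, evenness and CWMs.

    CWM columns are named ``cwm_<trait>``; unidentified records are
    excluded from CWM weighting (they carry no traits) but contribute to
    total abundance.
    """
    rows = []
    for site, row in matrix.abundance.iterrows():
        rec: dict[str, float] = {
            "site": site,
            "richness": richness(row, matrix.resolution, matrix.genus_of),
            "abundance": total_abundance(row),
            "evenness": pielou_evenness(row, matrix.resolution),
        }
        if traits is not None:
            identified = row[
                [t for t in row.index
                 if matrix.resolution.get(t, SPECIES) != UNIDENTIFIED]
            ]
            for col in trait_columns:
                if col in traits.columns:
                    rec[f"cwm_{col}"] = community_weighted_mean(identified, traits[col])
        rows.append(rec)
    return pd.DataFrame(rows).set_index("site")
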