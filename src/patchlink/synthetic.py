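"""Synthetic study-system generator with known ground truth.

Emulates a network of small fenced grassland sites (0.1-1 ha) spread
regularly through an agricultural matrix: a 2-m categorical land-use raster
with habitat / favourable / unfavourable / barrier classes, field polygons
carrying herbicide treatment-frequency indices, survey sites placed inside
habitat patches, and plant / butterfly / orthopteran communities whose
site-level metrics follow a known linear model

    mu = b0 + b_herb * z(TFI) + b_conn * z(dPC) + b_local * local + N(0, sigma)

so that every downstream stage — connectivity, community metrics, covariates
and the fixed three-predictor regressions — can be tested against embedded
truth.  A single seeded generator drives all randomness in a documented
order (landscape, fields, site attributes, then communities taxon by taxon),
so one seed reproduces the full study bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box

from .community import GENUS, SPECIES, UNIDENTIFIED, CommunityMatrix
from .connectivity import (
    ConnectivityResult,
    DispersalModel,
    build_patch_graph,
    node_importances,
    probability_of_connectivity,
    site_connectivity,
)
from .covariates import FieldPolygonSet, site_covariate_table
from .landscape import (
    CostSurface,
    CostTable,
    LandUseRaster,
    assign_costs,
    extract_patches,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "HABITAT",
    "CROP",
    "MARGIN",
    "FOREST",
    "insect_cost_table",
    "flora_cost_table",
    "generate_landscape",
    "draw_site_responses",
    "generate_communities",
    "generate_study",
]

# Land-use class codes
HABITAT = 1   # grassland site habitat (cost 1)
CROP = 2      # arable fields (unfavourable for insects, cost 100)
MARGIN = 3    # herbaceous margins/strips (favourable, cost 10)
FOREST = 4    # forest / tall buildings (barrier, cost 1000)


def insect_cost_table() -> CostTable:
    """Butterfly/orthopteran preset: 1 / 10 / 100 / 1000 tiers."""
    return CostTable(
        costs={HABITAT: 1, MARGIN: 10, CROP: 100, FOREST: 1000},
        labels={HABITAT: "grassland", MARGIN: "margin", CROP: "crop", FOREST: "forest"},
    )


def flora_cost_table() -> CostTable:
    """Flora preset: herbaceous classes are habitat (1), forests and tall
    buildings are barriers (1000), everything else costs 10."""
    return CostTable(
        costs={HABITAT: 1, MARGIN: 1, CROP: 10, FOREST: 1000},
        labels={HABITAT: "grassland", MARGIN: "margin", CROP: "crop", FOREST: "forest"},
    )


#: Per-response generative effects (b0, b_herb, b_conn, b_local, sigma),
#: sized to the study system: ~35 sites, herbicide effects negative on
#: plant/butterfly richness and abundance, connectivity effects positive on
#: abundance, noise at the scale implied by coefficient standard errors of
#: roughly 1-5 per scaled unit.
DEFAULT_EFFECTS: dict[str, dict[str, tuple[float, float, float, float, float]]] = {
    "flora": {
        "richness": (21.0, -2.08, 1.77, 6.30, 5.6),
        "abundance": (112.0, -15.04, 15.13, 33.72, 30.0),
        "evenness": (0.64, -0.01, 0.003, 0.01, 0.05),
    },
    "rhopalocera": {
        "richness": (6.0, -0.58, -0.08, 0.50, 2.6),
        "abundance": (29.0, -8.84, 9.27, 2.67, 17.8),
        "evenness": (0.61, 0.01, 0.01, -0.01, 0.06),
    },
    "orthoptera": {
        "richness": (5.0, 0.92, -0.38, -0.18, 1.7),
        "abundance": (20.0, -0.53, -3.10, 0.63, 11.5),
        "evenness": (0.55, 0.03, 0.05, -0.01, 0.08),
    },
}

#: Species-pool sizes observed in comparable grassland surveys.
POOL_SIZES = {"flora": 147, "rhopalocera": 32, "orthoptera": 17}

#: Fraction of records identified to genus only / left unidentified.
RESOLUTION_MIX = {
    "flora": (0.05, 0.0),
    "rhopalocera": (0.05, 0.01),
    "orthoptera": (0.12, 0.16),
}

#: Trait missingness (fraction of species without a value).
TRAIT_MISSING = {
    "flora": {"dispersal": 0.056, "specialization": 0.095, "pollination": 0.056},
    "rhopalocera": {"dispersal": 0.0, "specialization": 0.0},
    "orthoptera": {"dispersal": 0.0, "specialization": 0.15},
}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    nrow: int = 500
    ncol: int = 500
    resolution: float = 2.0  # m
    n_sites: int = 35
    site_area_ha: tuple[float, float] = (0.1, 1.0)
    n_forest_strips: int = 5
    forest_strip_width_m: float = 20.0
    n_margin_strips: int = 25
    margin_width_m: float = 6.0
    field_size_m: float = 120.0  # target field edge length
    tfi_range: tuple[float, float] = (0.0, 2.1)
    tfi_missing_fraction: float = 0.12
    p_clay: float = 0.375
    effects: dict = field(default_factory=lambda: DEFAULT_EFFECTS)
    pool_sizes: dict = field(default_factory=lambda: dict(POOL_SIZES))
    resolution_mix: dict = field(default_factory=lambda: dict(RESOLUTION_MIX))
    trait_missing: dict = field(default_factory=lambda: dict(TRAIT_MISSING))
    genus_size: int = 3  # species per genus in the synthetic pool
    evenness_floor: float = 0.4

    @property
    def extent_m(self) -> tuple[float, float]:
        return self.ncol * self.resolution, self.nrow * self.resolution


@dataclass
class SyntheticStudy:
    """Everything one run of the generator produces, plus ground truth."""

    config: SyntheticConfig
    raster: LandUseRaster
    fields: FieldPolygonSet
    sites: pd.DataFrame  # covariates incl. tfi_*, dpc_*, locals
    surfaces: dict[str, CostSurface]
    patches: dict[str, list]
    connectivity: dict[str, object]  # variable name -> ConnectivityResult
    communities: dict[str, CommunityMatrix]
    traits: dict[str, pd.DataFrame]
    site_truth: dict[str, pd.DataFrame]  # taxon -> drawn metric targets
    ground_truth: dict  # taxon -> response -> effect tuple


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def generate_landscape(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[LandUseRaster, pd.DataFrame, FieldPolygonSet]:
    """Raster + site locations + field polygons for one seed.

    Habitat patches are laid out on a jittered regular grid (the sites are
    "regularly distributed" through the matrix), each an axis-aligned block
    of 0.1-1 ha; forest strips cross the landscape as barriers and narrow
    herbaceous margins thread the crop matrix.  Fields tile the whole
    extent; a fraction of them carries no TFI information.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nrow, ncol, res = config.nrow, config.ncol, config.resolution
    grid = np.full((nrow, ncol), CROP, dtype=np.int64)

    # herbaceous margins threading the crop matrix
    mcells = max(1, int(round(config.margin_width_m / res)))
    for _ in range(config.n_margin_strips):
        if rng.random() < 0.5:
            r0 = int(rng.integers(0, nrow - mcells))
            c0 = int(rng.integers(0, ncol))
            length = int(rng.integers(ncol // 8, ncol // 2))
            grid[r0:r0 + mcells, c0:min(ncol, c0 + length)] = MARGIN
        else:
            c0 = int(rng.integers(0, ncol - mcells))
            r0 = int(rng.integers(0, nrow))
            length = int(rng.integers(nrow // 8, nrow // 2))
            grid[r0:min(nrow, r0 + length), c0:c0 + mcells] = MARGIN

    # forest strips (drawn after the margins, so barriers cut them)
    wcells = max(1, int(round(config.forest_strip_width_m / res)))
    for _ in range(config.n_forest_strips):
        if rng.random() < 0.5:
            r0 = int(rng.integers(0, nrow - wcells))
            grid[r0:r0 + wcells, :] = FOREST
        else:
            c0 = int(rng.integers(0, ncol - wcells))
            grid[:, c0:c0 + wcells] = FOREST

    # habitat patches on a jittered regular grid
    k = int(np.ceil(np.sqrt(config.n_sites)))
    cell_r = nrow // k
    cell_c = ncol // k
    slots = [(i, j) for i in range(k) for j in range(k)]
    order = rng.permutation(len(slots))
    placed = 0
    site_rows = []
    lo_ha, hi_ha = config.site_area_ha
    max_block = min(cell_r, cell_c) - 2
    for s in order:
        if placed >= config.n_sites:
            break
        i, j = slots[s]
        area_m2 = rng.uniform(lo_ha, hi_ha) * 1e4
        side = int(round(np.sqrt(area_m2) / res))
        side = max(4, min(side, max_block))
        jr = int(rng.integers(0, max(1, cell_r - side)))
        jc = int(rng.integers(0, max(1, cell_c - side)))
        r0 = i * cell_r + jr
        c0 = j * cell_c + jc
        r1, c1 = min(r0 + side, nrow), min(c0 + side, ncol)
        # keep patches disjoint (a 1-cell buffer prevents 8-adjacency merges)
        rb0, cb0 = max(0, r0 - 2), max(0, c0 - 2)
        if (grid[rb0:min(r1 + 2, nrow), cb0:min(c1 + 2, ncol)] == HABITAT).any():
            continue
        grid[r0:r1, c0:c1] = HABITAT
        rc = (r0 + r1 - 1) / 2.0
        cc = (c0 + c1 - 1) / 2.0
        site_rows.append({
            "site": f"S{placed:02d}",
            "x": (cc + 0.5) * res,
            "y": (nrow - rc - 0.5) * res,
        })
        placed += 1
    if placed < config.n_sites:
        raise ValueError(
            f"could only place {placed}/{config.n_sites} sites; "
            "raster too small or habitat demand too high"
        )
    sites = pd.DataFrame(site_rows).set_index("site")

    # fields tiling the extent plus a 300-m apron: agriculture continues
    # beyond the mapped window, so edge sites keep informative buffers
    fx, fy = config.extent_m
    fsize = config.field_size_m
    apron = 300.0
    nfx = max(1, int(round((fx + 2 * apron) / fsize)))
    nfy = max(1, int(round((fy + 2 * apron) / fsize)))
    wx, wy = (fx + 2 * apron) / nfx, (fy + 2 * apron) / nfy
    geoms, tfis = [], []
    for iy in range(nfy):
        for ix in range(nfx):
            geoms.append(box(-apron + ix * wx, -apron + iy * wy,
                             -apron + (ix + 1) * wx, -apron + (iy + 1) * wy))
            if rng.random() < config.tfi_missing_fraction:
                tfis.append(np.nan)
            else:
                tfis.append(rng.uniform(*config.tfi_range))
    fields = FieldPolygonSet(geometries=geoms, tfi=np.array(tfis))

    raster = LandUseRaster(grid=grid, resolution=res, origin=(0.0, 0.0))
    return raster, sites, fields


def _site_attributes(
    sites: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw local site attributes: soil, moisture, floral cover, vegetation."""
    n = len(sites)
    out = sites.copy()
    out["soil_type"] = np.where(rng.random(n) < config.p_clay, "clay", "sandy")
    out["moisture"] = rng.integers(1, 4, size=n)
    # floral cover: 4 visits around a site-level mean (study range ~1-31%)
    site_mean = np.clip(rng.normal(12.9, 8.8, size=n), 0.5, 60)
    for v in range(1, 5):
        out[f"visit_{v}"] = np.clip(rng.normal(site_mean, 3.0), 0, 100)
    # herbaceous structure: low ~12%, high ~59%, medium fills part of the rest
    low = np.clip(rng.normal(12.1, 16.6, size=n), 0, 70)
    high = np.clip(rng.normal(58.7, 26.9, size=n), 0, 95)
    scale = np.maximum(1.0, (low + high) / 100.0)
    low, high = low / scale, high / scale
    medium = np.clip(rng.uniform(0, 1, size=n) * (100 - low - high), 0, 100)
    out["cover_low"], out["cover_medium"], out["cover_high"] = low, medium, high
    return out


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def _zfill(x: np.ndarray) -> np.ndarray:
    """z-score over non-missing entries, missing -> 0 (the mean)."""
    x = np.asarray(x, dtype=float)
    obs = x[~np.isnan(x)]
    sd = obs.std(ddof=1)
    z = (x - obs.mean()) / (sd if sd > 0 else 1.0)
    return np.where(np.isnan(z), 0.0, z)


def draw_site_responses(
    config: SyntheticConfig,
    taxon: str,
    herb: np.ndarray,
    conn: np.ndarray,
    local: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Site-level metric targets from the embedded linear model.

    ``herb`` and ``conn`` are raw covariates (z-scored internally, missing
    treated as at the mean); ``local`` is already coded (0/1 for soil,
    z-scored otherwise).  Gaussian noise sigma per response.
    """
    zh, zc = _zfill(herb), _zfill(conn)
    n = len(zh)
    out = {}
    for response, (b0, bh, bc, bl, sigma) in config.effects[taxon].items():
        mu = b0 + bh * zh + bc * zc + bl * np.asarray(local, dtype=float)
        out[response] = mu + rng.normal(0.0, sigma, size=n)
    return pd.DataFrame(out)


def _species_pool(taxon: str, config: SyntheticConfig, rng: np.random.Generator
                  ) -> tuple[list[str], dict[str, str], pd.DataFrame]:
    """Names, genus map and trait table for one taxon's species pool."""
    n = config.pool_sizes[taxon]
    gsize = config.genus_size
    names, genus_of = [], {}
    for i in range(n):
        g = i // gsize
        name = f"{taxon[:2].capitalize()}genus{g:02d} sp{i % gsize}"
        names.append(name)
        genus_of[name] = f"{taxon[:2].capitalize()}genus{g:02d}"
    if taxon == "flora":
        traits = pd.DataFrame({
            "dispersal": np.clip(rng.lognormal(-0.7, 1.0, n), 0.1, 25.0),
            "specialization": np.clip(rng.normal(17.3, 3.5, n), 8.3, 24.3),
            "pollination": 100 * rng.beta(1.6, 1.25, n),
        }, index=names)
    elif taxon == "rhopalocera":
        traits = pd.DataFrame({
            "dispersal": rng.integers(1, 4, n).astype(float),
            "specialization": rng.integers(1, 5, n).astype(float),
        }, index=names)
    else:
        traits = pd.DataFrame({
            "dispersal": rng.integers(1, 4, n).astype(float),
            "specialization": rng.integers(0, 2, n).astype(float),
        }, index=names)
    for col, frac in config.trait_missing[taxon].items():
        if frac > 0 and col in traits.columns:
            mask = rng.random(n) < frac
            traits.loc[mask, col] = np.nan
    return names, genus_of, traits


def _realize_row(
    taxon: str,
    richness_t: float,
    abundance_t: float,
    evenness_t: float,
    pool: list[str],
    tilt: float,
    traits: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Integer abundances for one site hitting the metric targets.

    Species are sampled with rank-biased probabilities; ``tilt`` shifts the
    sampling towards high-dispersal species (positive) or away (negative),
    which is how covariate-driven CWM gradients arise.  Shares follow a
    geometric series whose ratio is tuned from the evenness target (ratio
    1 -> equal shares -> J = 1 exactly).
    """
    n_pool = len(pool)
    cap = 10 if taxon == "flora" else None
    s = int(np.clip(round(richness_t), 1, n_pool))
    total = max(s, int(round(abundance_t)))
    if cap is not None:
        total = min(total, s * cap)
    # selection weights: mild rank bias + trait tilt on dispersal rank
    ranks = np.arange(n_pool, dtype=float)
    w = np.exp(-ranks / (0.4 * n_pool))
    if tilt != 0 and "dispersal" in traits.columns:
        disp = traits["dispersal"].fillna(traits["dispersal"].median()).to_numpy()
        order = np.argsort(disp)
        trank = np.empty(n_pool)
        trank[order] = np.linspace(-1, 1, n_pool)
        w = w * np.exp(np.clip(tilt, -2, 2) * trank)
    w = w / w.sum()
    chosen = rng.choice(n_pool, size=s, replace=False, p=w)
    # geometric shares from the evenness target
    j = float(np.clip(evenness_t, config.evenness_floor, 1.0))
    ratio = 1.0 if j >= 1.0 else j ** 3  # monotone heuristic map J -> ratio
    shares = ratio ** np.arange(s)
    shares = shares / shares.sum()
    counts = np.maximum(1, np.round(shares * total)).astype(int)
    if cap is not None:
        counts = np.minimum(counts, cap)
    # adjust deterministically so the realized total matches the target
    # (subject to the per-species floor of 1 and the quadrat cap)
    guard = 0
    while counts.sum() != total and guard < 10 * total:
        guard += 1
        if counts.sum() < total:
            room = np.nonzero(counts < (cap or total))[0]
            if room.size == 0:
                break
            counts[room[np.argmin(counts[room])]] += 1
        else:
            room = np.nonzero(counts > 1)[0]
            if room.size == 0:
                break
            counts[room[np.argmax(counts[room])]] -= 1
    return {pool[c]: int(k) for c, k in zip(chosen, counts)}


def generate_communities(
    config: SyntheticConfig,
    sites: pd.DataFrame,
    drivers: dict[str, tuple[str, str, str]],
    rng: np.random.Generator,
) -> tuple[dict[str, CommunityMatrix], dict[str, pd.DataFrame],
           dict[str, pd.DataFrame]]:
    """Communities and traits for all taxon groups.

    ``drivers`` maps taxon -> (herbicide column, connectivity column, local
    column) in ``sites``.  Returns (communities, traits, site_truth) where
    site_truth holds the drawn metric targets per taxon.
    """
    communities, trait_tables, truths = {}, {}, {}
    for taxon in ("flora", "rhopalocera", "orthoptera"):
        herb_col, conn_col, local_col = drivers[taxon]
        if local_col == "soil_type":
            local = (sites[local_col] == "sandy").astype(float).to_numpy()
        else:
            local = _zfill(sites[local_col].to_numpy(dtype=float))
        targets = draw_site_responses(
            config, taxon,
            sites[herb_col].to_numpy(dtype=float),
            sites[conn_col].to_numpy(dtype=float),
            local, rng,
        )
        targets.index = sites.index
        truths[taxon] = targets
        pool, genus_of, traits = _species_pool(taxon, config, rng)
        zh = _zfill(sites[herb_col].to_numpy(dtype=float))
        zc = _zfill(sites[conn_col].to_numpy(dtype=float))
        tilts = 0.8 * zh - 0.8 * zc  # herbicide favours mobile colonists
        rows = {}
        g_frac, u_frac = config.resolution_mix[taxon]
        resolution: dict[str, str] = {}
        for s_i, site in enumerate(sites.index):
            row = _realize_row(
                taxon,
                targets.loc[site, "richness"],
                targets.loc[site, "abundance"],
                targets.loc[site, "evenness"],
                pool, float(tilts[s_i]), traits, config, rng,
            )
            # degrade some records to genus level / unidentified
            out_row: dict[str, float] = {}
            for name, count in row.items():
                u = rng.random()
                if u < u_frac:
                    key = f"{taxon}_unidentified"
                    resolution[key] = UNIDENTIFIED
                    out_row[key] = out_row.get(key, 0) + count
                elif u < u_frac + g_frac:
                    key = f"{genus_of[name]} sp."
                    resolution[key] = GENUS
                    out_row[key] = out_row.get(key, 0) + count
                else:
                    resolution[name] = SPECIES
                    out_row[name] = out_row.get(name, 0) + count
            rows[site] = out_row
        wide = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
        wide.index.name = "site"
        if taxon == "flora":
            wide = wide.clip(upper=10)
        genus_map = dict(genus_of)
        for key in wide.columns:
            if key.endswith(" sp."):
                genus_map[key] = key[:-4]
        communities[taxon] = CommunityMatrix(
            abundance=wide.sort_index(),
            resolution=resolution,
            genus_of=genus_map,
            n_quadrats=10 if taxon == "flora" else None,
        )
        trait_tables[taxon] = traits
    return communities, trait_tables, truths


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

#: Connectivity variables computed for the study, named after the taxon
#: preset and dispersal distance.
CONNECTIVITY_VARIABLES = {
    "dpc_flora_150": ("flora", 150.0),
    "dpc_flora_500": ("flora", 500.0),
    "dpc_insect_100": ("insect", 100.0),
    "dpc_insect_300": ("insect", 300.0),
}

DRIVERS = {
    "flora": ("tfi_300", "dpc_flora_500", "soil_type"),
    "rhopalocera": ("tfi_300", "dpc_insect_300", "floral_availability"),
    "orthoptera": ("tfi_100", "dpc_insect_300", "cover_low"),
}


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Run the full generator: landscape, connectivity, covariates,
    communities.  Deterministic for a given config (seed included)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    raster, sites, fields = generate_landscape(config, rng)
    sites = _site_attributes(sites, config, rng)

    surfaces = {
        "insect": assign_costs(raster, insect_cost_table()),
        "flora": assign_costs(raster, flora_cost_table()),
    }
    patches = {k: extract_patches(s) for k, s in surfaces.items()}

    connectivity: dict[str, object] = {}
    site_xy = sites[["x", "y"]].to_numpy()
    graphs = {}
    for var, (preset, dstar) in CONNECTIVITY_VARIABLES.items():
        surface = surfaces[preset]
        model = DispersalModel(dispersal_distance=dstar)
        if preset not in graphs:
            graphs[preset] = build_patch_graph(surface, patches[preset])
        graph = graphs[preset]
        pc = probability_of_connectivity(graph, model)
        dpc = node_importances(graph, model)
        ranking = sorted(dpc, key=lambda pid: (-dpc[pid], pid))
        result = ConnectivityResult(pc=pc, dpc=dpc, ranking=ranking, model=model)
        connectivity[var] = result
        sites[var] = site_connectivity(
            site_xy, surface, patches[preset], dpc, snap_tolerance_cells=2
        )

    sites = site_covariate_table(sites, fields)
    sites = sites.rename(columns={"tfi_100": "tfi_100", "tfi_300": "tfi_300"})

    communities, traits, truths = generate_communities(config, sites, DRIVERS, rng)

    return SyntheticStudy(
        config=config,
        raster=raster,
        fields=fields,
        sites=sites,
        surfaces=surfaces,
        patches=patches,
        connectivity=connectivity,
        communities=communities,
        traits=traits,
        site_truth=truths,
        ground_truth={t: dict(config.effects[t]) for t in config.effects},
    )
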