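"""Orchestration: connectivity -> community metrics -> covariates -> models.

Runs the full analysis either on files (raster, cost table, sites, fields,
communities, traits) or on a synthetic study bundle, and produces the four
standard outputs: a descriptive table of explanatory variables, coefficient
tables per taxon x response, the cross-metric correlation matrix, and the
connectivity report — plus a run log capturing seed, versions and every
decision taken (dropped sites, NA propagation, screen exclusions).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import CommunityMatrix, site_metrics
from .connectivity import ConnectivityResult
from .covariates import read_fields_geojson
from .inference import (
    CorrelationReport,
    DiversityLMResults,
    ModelSpec,
    collinearity_screen,
    fit_gaussian_lm,
    pearson_matrix,
)
from .landscape import read_ascii_grid, read_cost_table, read_tiff
from .synthetic import DRIVERS, SyntheticConfig, SyntheticStudy, generate_study

logger = logging.getLogger("patchlink")

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "descriptive_table",
    "taxon_site_metrics",
    "fit_all_models",
    "correlation_report",
    "run_pipeline",
    "run_synthetic",
    "write_outputs",
]

#: Responses modelled per taxon (Table-3-like rows).
RESPONSES = {
    "flora": ["richness", "abundance", "evenness",
              "cwm_dispersal", "cwm_specialization", "cwm_pollination"],
    "rhopalocera": ["richness", "abundance", "evenness",
                    "cwm_dispersal", "cwm_specialization"],
    "orthoptera": ["richness", "abundance", "evenness",
                   "cwm_dispersal", "cwm_specialization"],
}


@dataclass
class RunConfig:
    """Paths and options for a file-based run."""

    raster: str | None = None
    costs: str | None = None
    sites: str | None = None
    fields: str | None = None
    communities: dict[str, str] = field(default_factory=dict)
    traits: dict[str, str] = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0
    buffer_radii: tuple[float, ...] = (100.0, 300.0)
    screen_cutoff: float = 0.3
    verbose: bool = False


@dataclass
class ResultsBundle:
    """All tables one run produces."""

    descriptive: pd.DataFrame
    models: pd.DataFrame  # long coefficient table
    fits: dict[tuple[str, str], DiversityLMResults]
    correlations: CorrelationReport
    connectivity: dict[str, ConnectivityResult]
    metrics: dict[str, pd.DataFrame]
    sites: pd.DataFrame
    log: dict


def descriptive_table(
    sites: pd.DataFrame, variables: list[str]
) -> pd.DataFrame:
    """Mean, SD, min, max per explanatory variable (descriptive summary)."""
    rows = []
    for v in variables:
        if v not in sites.columns:
            continue
        col = pd.to_numeric(sites[v], errors="coerce")
        rows.append({
            "variable": v,
            "mean": col.mean(),
            "sd": col.std(ddof=1),
            "min": col.min(),
            "max": col.max(),
            "n": int(col.notna().sum()),
        })
    return pd.DataFrame(rows).set_index("variable")


def taxon_site_metrics(
    communities: dict[str, CommunityMatrix],
    traits: dict[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Per-taxon site metric tables (richness, abundance, evenness, CWMs)."""
    out = {}
    for taxon, matrix in communities.items():
        cols = ("dispersal", "specialization", "pollination") \
            if taxon == "flora" else ("dispersal", "specialization")
        out[taxon] = site_metrics(matrix, traits.get(taxon), trait_columns=cols)
    return out


def _model_specs(sites: pd.DataFrame) -> dict[str, ModelSpec]:
    """The fixed three-predictor structure per taxon.

    Flora: 300-m herbicide TFI + flora 500-m dPC + soil type; the flora
    pollination response swaps in the butterfly 300-m dPC (butterflies stand
    in for the pollinator community).  Butterflies: 300-m TFI + butterfly
    300-m dPC + floral availability.  Orthoptera: 100-m TFI + 300-m dPC +
    low herbaceous cover.
    """
    return {
        "flora": ModelSpec("", "tfi_300", "dpc_flora_500", "soil_type",
                           categorical_local=True, reference_level="clay"),
        "flora_pollination": ModelSpec("", "tfi_300", "dpc_insect_300",
                                       "soil_type", categorical_local=True,
                                       reference_level="clay"),
        "rhopalocera": ModelSpec("", "tfi_300", "dpc_insect_300",
                                 "floral_availability"),
        "orthoptera": ModelSpec("", "tfi_100", "dpc_insect_300", "cover_low"),
    }


def fit_all_models(
    sites: pd.DataFrame,
    metrics: dict[str, pd.DataFrame],
    log: dict | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], DiversityLMResults]]:
    """Fit every taxon x response model; returns the long coefficient table
    and the fitted results objects."""
    from dataclasses import replace

    specs = _model_specs(sites)
    rows = []
    fits: dict[tuple[str, str], DiversityLMResults] = {}
    for taxon, responses in RESPONSES.items():
        table = metrics[taxon].join(sites, how="left")
        for response in responses:
            if response not in table.columns:
                continue
            base = specs["flora_pollination"] \
                if (taxon == "flora" and response == "cwm_pollination") \
                else specs[taxon]
            spec = replace(base, response=response)
            try:
                res = fit_gaussian_lm(table, spec)
            except ValueError as exc:
                if log is not None:
                    log.setdefault("skipped_models", []).append(
                        {"taxon": taxon, "response": response, "reason": str(exc)}
                    )
                continue
            fits[(taxon, response)] = res
            for term in res.params.index:
                rows.append({
                    "taxon": taxon,
                    "response": response,
                    "term": term,
                    "beta": res.params[term],
                    "se": res.bse[term],
                    "p": res.pvalues[term],
                    "n": res.n,
                })
    return pd.DataFrame(rows), fits


_METRIC_SHORT = {"richness": "Sr", "abundance": "Ab", "evenness": "E",
                 "cwm_specialization": "CWMs", "cwm_dispersal": "CWMd",
                 "cwm_pollination": "CWMdp"}


def correlation_report(metrics: dict[str, pd.DataFrame]) -> CorrelationReport:
    """Pearson correlations between all community diversity metrics,
    pairwise-complete, flagged at the 0.01 level (Table-4 shape)."""
    blocks = []
    for taxon, df in metrics.items():
        sub = df[[c for c in df.columns if c in _METRIC_SHORT]].copy()
        sub.columns = [f"{taxon}_{_METRIC_SHORT[c]}" for c in sub.columns]
        blocks.append(sub)
    combined = pd.concat(blocks, axis=1)
    return pearson_matrix(combined, alpha=0.01)


def run_synthetic(config: SyntheticConfig | None = None,
                  screen_cutoff: float = 0.3) -> ResultsBundle:
    """Full pipeline on a generated study."""
    config = config or SyntheticConfig()
    study = generate_study(config)
    return analyse_study(study, screen_cutoff=screen_cutoff)


def analyse_study(study: SyntheticStudy, screen_cutoff: float = 0.3
                  ) -> ResultsBundle:
    """Descriptives, screening, models and correlations for a study bundle."""
    sites = study.sites
    log: dict = {
        "patchlink_version": __version__,
        "python": platform.python_version(),
        "seed": study.config.seed,
        "n_sites": len(sites),
    }
    explanatory = ["tfi_100", "tfi_300", "dpc_flora_150", "dpc_flora_500",
                   "dpc_insect_100", "dpc_insect_300", "floral_availability",
                   "cover_low", "cover_medium", "cover_high", "moisture"]
    desc = descriptive_table(sites, explanatory)

    for col in ("tfi_100", "tfi_300"):
        na_sites = sites.index[sites[col].isna()].tolist()
        if na_sites:
            log.setdefault("tfi_missing", {})[col] = na_sites

    try:
        selection, screen_log = collinearity_screen(
            sites,
            {"herbicide": ["tfi_100", "tfi_300"],
             "connectivity": ["dpc_flora_150", "dpc_flora_500",
                              "dpc_insect_100", "dpc_insect_300"],
             "local": ["floral_availability", "cover_low", "cover_high"]},
            cutoff=screen_cutoff,
        )
        log["screen_selection"] = selection
        log["screen_exclusions"] = screen_log.to_dict("records")
    except ValueError as exc:
        log["screen_selection"] = None
        log["screen_error"] = str(exc)

    metrics = taxon_site_metrics(study.communities, study.traits)
    models, fits = fit_all_models(sites, metrics, log=log)
    corr = correlation_report(metrics)
    return ResultsBundle(
        descriptive=desc,
        models=models,
        fits=fits,
        correlations=corr,
        connectivity=study.connectivity,
        metrics=metrics,
        sites=sites,
        log=log,
    )


# ---------------------------------------------------------------------------
# File-based run
# ---------------------------------------------------------------------------

def read_inputs(config: RunConfig) -> dict:
    """Read and validate all file inputs for a run."""
    bundle: dict = {}
    if config.raster:
        p = Path(config.raster)
        if p.suffix.lower() in {".tif", ".tiff"}:
            bundle["raster"] = read_tiff(p)
        else:
            bundle["raster"] = read_ascii_grid(p)
    if config.costs:
        bundle["costs"] = read_cost_table(config.costs)
    if config.sites:
        sites = pd.read_csv(config.sites)
        if "site" not in sites.columns:
            raise ValueError(f"{config.sites}: missing 'site' column")
        bundle["sites"] = sites.set_index("site")
    if config.fields:
        bundle["fields"] = read_fields_geojson(config.fields)
    communities = {}
    for taxon, path in config.communities.items():
        df = pd.read_csv(path)
        communities[taxon] = CommunityMatrix.from_long(
            df, n_quadrats=10 if taxon == "flora" else None
        )
        if "sites" in bundle:
            unknown = set(communities[taxon].abundance.index) - set(bundle["sites"].index)
            if unknown:
                raise ValueError(
                    f"{path}: unknown site id(s): {sorted(unknown)}"
                )
    bundle["communities"] = communities
    bundle["traits"] = {
        taxon: pd.read_csv(path, index_col=0)
        for taxon, path in config.traits.items()
    }
    return bundle


def run_pipeline(config: RunConfig,
                 dispersal_distances: tuple[float, ...] = (100.0, 300.0),
                 ) -> ResultsBundle:
    """File-based end-to-end run (synthetic when no raster is given).

    With file inputs the stages are: cost surface and patches from the
    raster + cost table, planar graph and dPC per dispersal distance
    (columns ``dpc_<d>``), buffer TFI covariates (columns ``tfi_<r>``),
    community metrics, then the fixed three-predictor models wherever the
    site table carries the needed columns.  Any stage failure aborts with
    the stage name and the offending input.
    """
    if config.raster is None:
        bundle = run_synthetic(SyntheticConfig(seed=config.seed),
                               screen_cutoff=config.screen_cutoff)
        write_outputs(bundle, config.out_dir)
        return bundle

    from .connectivity import DispersalModel, build_patch_graph, \
        node_importances, probability_of_connectivity, site_connectivity
    from .covariates import site_covariate_table
    from .landscape import assign_costs, extract_patches

    log: dict = {"patchlink_version": __version__,
                 "python": platform.python_version(), "seed": config.seed}

    def _stage(name: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    bundle_in = _stage("read_inputs", read_inputs, config)
    surface = _stage("assign_costs", assign_costs,
                     bundle_in["raster"], bundle_in["costs"])
    patches = _stage("extract_patches", extract_patches, surface)
    graph = _stage("build_graph", build_patch_graph, surface, patches)
    sites = bundle_in["sites"]
    site_xy = sites[["x", "y"]].to_numpy(dtype=float)
    connectivity: dict[str, ConnectivityResult] = {}
    for dstar in dispersal_distances:
        model = DispersalModel(dispersal_distance=float(dstar))
        pc = probability_of_connectivity(graph, model)
        dpc = node_importances(graph, model)
        ranking = sorted(dpc, key=lambda pid: (-dpc[pid], pid))
        connectivity[f"dpc_{int(dstar)}"] = ConnectivityResult(
            pc=pc, dpc=dpc, ranking=ranking, model=model)
        sites[f"dpc_{int(dstar)}"] = site_connectivity(
            site_xy, surface, patches, dpc, snap_tolerance_cells=2)
    if "fields" in bundle_in:
        sites = _stage("covariates", site_covariate_table,
                       sites, bundle_in["fields"], config.buffer_radii)
    metrics = _stage("community_metrics", taxon_site_metrics,
                     bundle_in["communities"], bundle_in["traits"])
    desc = descriptive_table(
        sites, [c for c in sites.columns
                if c.startswith(("tfi_", "dpc_", "cover_", "visit_"))
                or c in ("floral_availability", "moisture")])
    models, fits = fit_all_models(sites, metrics, log=log) \
        if _has_model_columns(sites) else (pd.DataFrame(), {})
    corr = correlation_report(metrics) if metrics else None
    bundle = ResultsBundle(descriptive=desc, models=models, fits=fits,
                           correlations=corr, connectivity=connectivity,
                           metrics=metrics, sites=sites, log=log)
    write_outputs(bundle, config.out_dir)
    return bundle


def _has_model_columns(sites: pd.DataFrame) -> bool:
    needed = {"tfi_300", "tfi_100", "dpc_flora_500", "dpc_insect_300"}
    return needed.issubset(sites.columns)


def write_outputs(bundle: ResultsBundle, out_dir: str | Path) -> None:
    """Write every results table as CSV plus the JSON run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.descriptive.to_csv(out / "descriptive_variables.csv")
    bundle.models.to_csv(out / "model_coefficients.csv", index=False)
    if bundle.correlations is not None:
        bundle.correlations.r.to_csv(out / "correlations_r.csv")
        bundle.correlations.n.to_csv(out / "correlations_n.csv")
        bundle.correlations.p.to_csv(out / "correlations_p.csv")
    bundle.sites.to_csv(out / "site_covariates.csv")
    for taxon, df in bundle.metrics.items():
        df.to_csv(out / f"metrics_{taxon}.csv")
    conn_rows = []
    for var, res in bundle.connectivity.items():
        for pid in res.ranking:
            conn_rows.append({"variable": var, "patch": pid,
                              "dpc": res.dpc[pid], "pc": res.pc})
    pd.DataFrame(conn_rows).to_csv(out / "connectivity_report.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(bundle.log, fh, indent=2, default=str)
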