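"""Site-level explanatory variables: herbicide exposure and local habitat.

Herbicide pressure is summarised by the treatment frequency index (TFI, a
standardised count of full doses applied per field per season), averaged
over the agricultural area inside 100-m and 300-m circular buffers around
each site.  Sites where less than half of the buffer area carries TFI
information get a missing value — never an imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape, mapping
from shapely.geometry.base import BaseGeometry

__all__ = [
    "FieldPolygonSet",
    "tfi_buffer_mean",
    "floral_availability",
    "validate_cover_classes",
    "site_covariate_table",
    "read_fields_geojson",
    "write_fields_geojson",
    "BUFFER_RADII_M",
]

#: Buffer radii used in paper mode (m): wide enough to describe the
#: surrounding landscape, narrow enough to avoid overlap between sites.
BUFFER_RADII_M = (100.0, 300.0)


@dataclass
class FieldPolygonSet:
    """Agricultural field polygons with herbicide TFI values.

    ``tfi`` may contain NaN for fields without information; those polygons
    count as non-informative area in buffer averaging.
    """

    geometries: list[BaseGeometry]
    tfi: np.ndarray

    def __post_init__(self) -> None:
        self.tfi = np.asarray(self.tfi, dtype=float)
        if len(self.geometries) != len(self.tfi):
            raise ValueError("one TFI value per polygon required")
        if np.nanmin(self.tfi, initial=0.0) < 0:
            raise ValueError("TFI values must be non-negative")
        for i, g in enumerate(self.geometries):
            if g.is_empty or g.area <= 0:
                raise ValueError(f"degenerate field polygon at index {i}")

    def __len__(self) -> int:
        return len(self.geometries)


def tfi_buffer_mean(
    site_xy: tuple[float, float],
    fields: FieldPolygonSet,
    radius: float,
    min_informative_fraction: float = 0.5,
    exclude: BaseGeometry | None = None,
) -> float:
    """Area-weighted mean herbicide TFI inside a circular buffer.

    The buffer is a circle of ``radius`` m centred at the site centroid.
    Each field contributes its TFI weighted by the area of its intersection
    with the buffer.  If the informative intersected area covers less than
    ``min_informative_fraction`` of the buffer (default: half the
    surrounding land), the value is missing (NaN).  ``exclude`` (e.g. the
    site's own untreated footprint) is removed from the informative area
    but not from the buffer area.
    """
    if radius <= 0:
        raise ValueError("buffer radius must be positive")
    buffer = Point(*site_xy).buffer(radius, quad_segs=64)
    if exclude is not None:
        informative_zone = buffer.difference(exclude)
    else:
        informative_zone = buffer
    total = 0.0
    weight = 0.0
    for geom, t in zip(fields.geometries, fields.tfi):
        if np.isnan(t):
            continue
        inter = informative_zone.intersection(geom)
        if inter.is_empty:
            continue
        total += t * inter.area
        weight += inter.area
    if weight < min_informative_fraction * buffer.area:
        return float("nan")
    return total / weight


def floral_availability(visit_covers: list[float] | np.ndarray) -> float:
    """Mean flowering-plant cover (%) over the recorded site visits.

    The protocol plans four visits; the mean is taken over however many
    were recorded.  NaN with zero recorded visits.
    """
    covers = np.asarray([c for c in np.atleast_1d(visit_covers) if not np.isnan(c)],
                        dtype=float)
    if covers.size == 0:
        return float("nan")
    if ((covers < 0) | (covers > 100)).any():
        raise ValueError("cover percentages must lie in [0, 100]")
    return float(covers.mean())


def validate_cover_classes(low: float, medium: float, high: float) -> dict:
    """Validate the three herbaceous-vegetation cover classes.

    Classes are percent cover of low (<20 cm), medium (20-40 cm) and high
    (>40 cm) herbaceous vegetation.  Each must lie in [0, 100]; rows whose
    classes sum beyond 100 are passed through but flagged.
    """
    vals = {"cover_low": low, "cover_medium": medium, "cover_high": high}
    for name, v in vals.items():
        if not 0 <= v <= 100:
            raise ValueError(f"{name} out of [0, 100]: {v}")
    vals["cover_sum_exceeds_100"] = bool(low + medium + high > 100)
    return vals


def site_covariate_table(
    sites: pd.DataFrame,
    fields: FieldPolygonSet,
    radii: tuple[float, ...] = BUFFER_RADII_M,
    site_footprints: list[BaseGeometry] | None = None,
) -> pd.DataFrame:
    """Assemble the per-site covariate table.

    ``sites`` needs columns x, y and may carry soil_type, moisture,
    floral availability visit columns (visit_1..visit_4) and cover classes;
    TFI_<radius> columns are computed here.
    """
    out = sites.copy()
    for r in radii:
        vals = []
        for i, row in sites.iterrows():
            ex = None
            if site_footprints is not None:
                ex = site_footprints[list(sites.index).index(i)]
            vals.append(tfi_buffer_mean((row["x"], row["y"]), fields, r, exclude=ex))
        out[f"tfi_{int(r)}"] = vals
    visit_cols = [c for c in sites.columns if c.startswith("visit_")]
    if visit_cols:
        out["floral_availability"] = [
            floral_availability(row[visit_cols].to_numpy(dtype=float))
            for _, row in sites.iterrows()
        ]
    return out


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def read_fields_geojson(path: str | Path) -> FieldPolygonSet:
    with open(path) as fh:
        gj = json.load(fh)
    geoms, tfis = [], []
    for i, feat in enumerate(gj.get("features", [])):
        try:
            geoms.append(shape(feat["geometry"]))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: feature {i}: bad geometry: {exc}") from exc
        props = feat.get("properties", {}) or {}
        t = props.get("tfi")
        tfis.append(float("nan") if t is None else float(t))
    return FieldPolygonSet(geometries=geoms, tfi=np.array(tfis))


def write_fields_geojson(fields: FieldPolygonSet, path: str | Path) -> None:
    feats = []
    for geom, t in zip(fields.geometries, fields.tfi):
        feats.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"tfi": None if np.isnan(t) else float(t)},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
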