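"""Resistance surfaces and habitat patches from categorical land-use rasters.

A landscape is represented as a 2-D grid of integer land-use class codes at a
fixed metric resolution (2 m by default, fine enough to resolve linear
features such as hedgerows and roads).  Each class carries a movement cost
(resistance per metre traversed); cells whose cost equals 1 are habitat.
Habitat patches are connected components of the habitat mask and carry the
areas that enter the probability-of-connectivity index.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "LandUseRaster",
    "CostTable",
    "CostSurface",
    "Patch",
    "assign_costs",
    "pool_mosaic",
    "extract_patches",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_tiff",
    "write_tiff",
    "read_cost_table",
    "write_cost_table",
    "write_patch_table",
    "FLORA_COST_TIERS",
    "INSECT_COST_TIERS",
]

#: Paper-mode cost tiers: habitat, favourable, unfavourable, barrier.
INSECT_COST_TIERS = (1.0, 10.0, 100.0, 1000.0)

#: Flora preset: herbaceous = habitat (1), forests and buildings taller than
#: 15 m = barriers (1000), everything else (crops, shrubs, roads...) = 10.
FLORA_COST_TIERS = (1.0, 10.0, 1000.0)


@dataclass
class LandUseRaster:
    """Categorical land-use grid.

    Parameters
    ----------
    grid : ndarray of int, shape (nrow, ncol)
        Land-use class codes, row-major with row 0 at the grid's top edge.
    resolution : float
        Cell edge length in metres (> 0).
    origin : tuple of float
        Planar (x, y) coordinates of the lower-left corner.
    nodata : int
        Reserved code for cells with no land-use information.
    """

    grid: np.ndarray
    resolution: float = 2.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("raster grid must be 2-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("raster grid must hold integer class codes")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def classes(self) -> np.ndarray:
        """Distinct non-nodata codes present in the grid."""
        vals = np.unique(self.grid)
        return vals[vals != self.nodata]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Planar coordinates of a cell centre (cell-centre convention)."""
        nrow = self.grid.shape[0]
        x = self.origin[0] + (col + 0.5) * self.resolution
        y = self.origin[1] + (nrow - row - 0.5) * self.resolution
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid (row, col) containing planar point (x, y)."""
        nrow = self.grid.shape[0]
        col = int((x - self.origin[0]) / self.resolution)
        row = nrow - 1 - int((y - self.origin[1]) / self.resolution)
        return row, col


@dataclass
class CostTable:
    """Mapping from land-use class code to movement resistance.

    Costs are unitless resistances per metre traversed.  In paper mode every
    cost is one of the tiers 1 / 10 / 100 / 1000 (habitat, favourable,
    unfavourable, barrier); arbitrary positive costs are allowed in general
    mode.  Habitat is the set of classes with cost exactly 1.
    """

    costs: dict[int, float]
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.costs:
            raise ValueError("cost table is empty")
        for code, c in self.costs.items():
            if not c > 0:
                raise ValueError(f"cost for class {code} must be positive, got {c}")
        if not self.habitat_classes():
            raise ValueError("cost table defines no habitat class (cost == 1)")

    def habitat_classes(self) -> set[int]:
        return {code for code, c in self.costs.items() if c == 1}

    def is_paper_mode(self) -> bool:
        return all(c in INSECT_COST_TIERS for c in self.costs.values())


@dataclass
class CostSurface:
    """Per-cell resistance grid with habitat mask.

    ``habitat`` is exactly the set of cells with cost 1; ``passable`` marks
    cells that take part in movement at all (nodata cells do not).
    """

    cost: np.ndarray
    resolution: float
    habitat: np.ndarray
    passable: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cost.shape

    @property
    def landscape_area(self) -> float:
        """Total area A of the study zone in m² (all cells, incl. nodata)."""
        return float(self.cost.size) * self.resolution**2


@dataclass
class Patch:
    """One habitat patch: a connected component of the habitat mask."""

    id: int
    cells: np.ndarray  # (n, 2) array of (row, col) indices
    area: float  # m²
    centroid: tuple[float, float]  # planar (x, y)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def assign_costs(raster: LandUseRaster, costs: CostTable) -> CostSurface:
    """Allocate a movement cost to every cell by land-use class lookup.

    Every non-nodata code in the raster must have an entry in ``costs``;
    an unmapped code raises ``KeyError`` naming the offending code.  Nodata
    cells are impassable: they get an infinite cost and are excluded from
    the habitat mask and the movement graph.
    """
    present = set(raster.classes().tolist())
    unmapped = sorted(present - set(costs.costs))
    if unmapped:
        raise KeyError(
            f"no cost assigned for land-use class(es): {unmapped}"
        )
    cost = np.full(raster.shape, np.inf, dtype=float)
    for code, c in costs.costs.items():
        cost[raster.grid == code] = c
    passable = raster.grid != raster.nodata
    cost[~passable] = np.inf
    habitat = (cost == 1.0) & passable
    return CostSurface(
        cost=cost,
        resolution=raster.resolution,
        habitat=habitat,
        passable=passable,
        origin=raster.origin,
    )


def pool_mosaic(
    costs: CostTable, mosaic_classes: set[int], pooled_code: int | None = None
) -> CostTable:
    """Pool a set of mosaic habitat classes into a single class.

    Small habitat mosaics are merged into one class whose cost is the
    arithmetic mean of the composite classes' costs.  Returns a new table in
    which every class in ``mosaic_classes`` maps to ``pooled_code`` (default:
    the smallest pooled code) with the averaged cost; other classes are
    unchanged.  Class coverage is preserved: cells keep a mapping, none are
    dropped.
    """
    if not mosaic_classes:
        raise ValueError("mosaic_classes must be non-empty")
    missing = sorted(set(mosaic_classes) - set(costs.costs))
    if missing:
        raise KeyError(f"mosaic class(es) not in cost table: {missing}")
    mean_cost = float(np.mean([costs.costs[c] for c in mosaic_classes]))
    if pooled_code is None:
        pooled_code = min(mosaic_classes)
    new_costs = {
        code: (mean_cost if code in mosaic_classes else c)
        for code, c in costs.costs.items()
    }
    # every mosaic member keeps an entry so existing rasters stay mapped
    new_labels = dict(costs.labels)
    new_labels[pooled_code] = new_labels.get(pooled_code, f"mosaic_{pooled_code}")
    return CostTable(costs=new_costs, labels=new_labels)


_STRUCTURE_8 = np.ones((3, 3), dtype=bool)
_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


def extract_patches(
    surface: CostSurface,
    min_cells: int = 1,
    connectivity: int = 8,
) -> list[Patch]:
    """Extract habitat patches as connected components of the habitat mask.

    Components are found under 8-neighbourhood by default (diagonally
    touching habitat cells belong to one patch); components smaller than
    ``min_cells`` are discarded.  Patch ids are assigned in row-major order
    of each component's first cell, so they are stable and deterministic.
    Areas are cell count × resolution².
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    labels, n = ndimage.label(surface.habitat, structure=structure)
    patches: list[Patch] = []
    if n == 0:
        return patches
    res = surface.resolution
    nrow = surface.shape[0]
    objects = ndimage.find_objects(labels)
    # ndimage.label scans row-major, so label order == row-major first-cell order
    pid = 0
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        local = labels[sl] == lab
        if local.sum() < min_cells:
            continue
        rows, cols = np.nonzero(local)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        cells = np.column_stack([rows, cols])
        cx = surface.origin[0] + (cols.mean() + 0.5) * res
        cy = surface.origin[1] + (nrow - rows.mean() - 0.5) * res
        patches.append(
            Patch(
                id=pid,
                cells=cells,
                area=float(len(rows)) * res**2,
                centroid=(float(cx), float(cy)),
            )
        )
        pid += 1
    return patches


def patch_label_grid(surface: CostSurface, patches: list[Patch]) -> np.ndarray:
    """Grid of patch ids (−1 outside every patch)."""
    labels = np.full(surface.shape, -1, dtype=int)
    for p in patches:
        labels[p.cells[:, 0], p.cells[:, 1]] = p.id
    return labels


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid, TIFF, cost-table CSV, patch table CSV
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path, resolution: float | None = None) -> LandUseRaster:
    """Read an ESRI ASCII grid (.asc) as a land-use raster."""
    path = Path(path)
    header: dict[str, float] = {}
    known = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        key, _, val = line.partition(" ")
        if key.strip().lower() in known:
            header[key.strip().lower()] = float(val)
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:], dtype=int)
    grid = np.atleast_2d(grid)
    if "ncols" in header and grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return LandUseRaster(
        grid=grid,
        resolution=resolution or header.get("cellsize", 2.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=int(header.get("nodata_value", -9999)),
    )


def write_ascii_grid(raster: LandUseRaster, path: str | Path) -> None:
    """Write a land-use raster as an ESRI ASCII grid."""
    path = Path(path)
    nrow, ncol = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {raster.origin[0]}\n")
        fh.write(f"yllcorner {raster.origin[1]}\n")
        fh.write(f"cellsize {raster.resolution}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.grid, fmt="%d")


def read_tiff(
    path: str | Path,
    resolution: float = 2.0,
    origin: tuple[float, float] = (0.0, 0.0),
    nodata: int = -9999,
) -> LandUseRaster:
    """Read a single-band TIFF of integer class codes."""
    import tifffile

    grid = np.asarray(tifffile.imread(str(path)))
    if grid.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    return LandUseRaster(
        grid=grid.astype(np.int64), resolution=resolution, origin=origin, nodata=nodata
    )


def write_tiff(raster: LandUseRaster, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), raster.grid.astype(np.int32))


def read_cost_table(path: str | Path) -> CostTable:
    """Read a cost table CSV with columns class_code, label, cost, is_habitat."""
    costs: dict[int, float] = {}
    labels: dict[int, str] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                code = int(row["class_code"])
                cost = float(row["cost"])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row {i}: {exc}") from exc
            costs[code] = cost
            labels[code] = row.get("label", str(code))
            declared = str(row.get("is_habitat", "")).strip().lower()
            if declared in {"1", "true", "yes"} and cost != 1:
                raise ValueError(
                    f"{path}: row {i}: class {code} flagged habitat but cost {cost} != 1"
                )
    return CostTable(costs=costs, labels=labels)


def write_cost_table(table: CostTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class_code", "label", "cost", "is_habitat"])
        for code in sorted(table.costs):
            cost = table.costs[code]
            w.writerow([code, table.labels.get(code, code), cost, int(cost == 1)])


def write_patch_table(patches: list[Patch], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "area_m2", "n_cells", "centroid_x", "centroid_y"])
        for p in patches:
            w.writerow([p.id, p.area, p.n_cells, p.centroid[0], p.centroid[1]])
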