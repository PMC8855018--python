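"""Least-cost patch networks and the probability of connectivity (PC, dPC).

The landscape is abstracted as a graph whose nodes are habitat patches
(weighted by area) and whose edges join spatially neighbouring patches
(adjacent Voronoi cells), carrying least-cost distances measured on the
resistance surface.  The graph is planar by construction and non-thresholded:
no edge is pruned by distance.

Dispersal follows a negative-exponential kernel p_ij = exp(-k * d_ij), with k
calibrated so that the probability of covering the taxon's dispersal distance
d* equals p* (0.05 by default).  The probability of connectivity is

    PC = sum_i sum_j a_i * a_j * p_ij / A**2

— the chance that two organisms dropped at random in the study zone land in
mutually reachable habitat.  Each patch's importance is the relative drop in
PC when it is removed: dPC = 100 * (PC - PC') / PC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra, shortest_path

from .landscape import CostSurface, Patch, patch_label_grid

__all__ = [
    "DispersalModel",
    "PatchGraph",
    "ConnectivityResult",
    "calibrate_decay",
    "build_planar_graph",
    "least_cost_edge_distances",
    "least_cost_distance_matrix",
    "effective_distances",
    "build_patch_graph",
    "probability_of_connectivity",
    "delta_pc",
    "node_importances",
    "connectivity_analysis",
    "site_connectivity",
    "FLORA_DISPERSAL_M",
    "RHOPALOCERA_DISPERSAL_M",
    "ORTHOPTERA_DISPERSAL_M",
]

#: Dispersal-distance presets (m): poorly / moderately mobile species.
#: Highly mobile species are deliberately unsupported at this landscape scale.
FLORA_DISPERSAL_M = (150.0, 500.0)
RHOPALOCERA_DISPERSAL_M = (100.0, 300.0)
ORTHOPTERA_DISPERSAL_M = (100.0, 300.0)


def calibrate_decay(d_star: float, p_star: float = 0.05) -> float:
    """Decay rate k (per metre) such that exp(-k * d_star) == p_star.

    ``d_star`` is the taxon's dispersal distance in metres, ``p_star`` the
    probability of a dispersal event covering that distance.
    """
    if d_star <= 0:
        raise ValueError(f"dispersal distance must be positive, got {d_star}")
    if not 0 < p_star < 1:
        raise ValueError(f"calibration probability must be in (0, 1), got {p_star}")
    return -math.log(p_star) / d_star


@dataclass
class DispersalModel:
    """Negative-exponential dispersal kernel for one taxon group."""

    dispersal_distance: float  # d*, metres
    p_star: float = 0.05

    @property
    def k(self) -> float:
        """Decay rate per metre: -ln(p*) / d*."""
        return calibrate_decay(self.dispersal_distance, self.p_star)

    def probability(self, distance: float | np.ndarray) -> float | np.ndarray:
        """p = exp(-k d); unreachable (infinite) distances give p = 0."""
        with np.errstate(over="ignore"):
            return np.where(np.isinf(distance), 0.0, np.exp(-self.k * np.asarray(distance)))


@dataclass
class PatchGraph:
    """Planar, non-thresholded patch network with effective distances."""

    patch_ids: list[int]
    areas: np.ndarray  # m², aligned with patch_ids
    edges: dict[tuple[int, int], float]  # (i, j) with i < j -> least-cost m
    d: np.ndarray  # effective distance matrix over the planar edges
    landscape_area: float  # A, m²
    unreachable_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.patch_ids)


@dataclass
class ConnectivityResult:
    """PC plus per-patch importance (dPC, %) and the descending ranking."""

    pc: float
    dpc: dict[int, float]
    ranking: list[int]  # patch ids, most important first
    model: DispersalModel


# ---------------------------------------------------------------------------
# Cell-level least-cost machinery
# ---------------------------------------------------------------------------

def _cell_graph(surface: CostSurface) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse 8-neighbour cell graph with half-in/half-out step weights.

    Moving between adjacent cell centres costs (w_a + w_b)/2 * step length,
    with the step length = resolution (orthogonal) or resolution * sqrt(2)
    (diagonal).  Habitat cells have w = 0: movement within habitat is free,
    so a patch behaves as a single zero-distance node.  Impassable (nodata)
    cells are excluded from the graph entirely.

    Returns the CSR adjacency and an index grid mapping (row, col) to node
    index (-1 for impassable cells).
    """
    passable = surface.passable
    nrow, ncol = surface.shape
    idx = np.full((nrow, ncol), -1, dtype=np.int64)
    idx[passable] = np.arange(passable.sum())
    w = np.where(surface.habitat, 0.0, surface.cost)
    res = surface.resolution

    rows_i, rows_j, data = [], [], []
    # E, S: orthogonal; SE, SW: diagonal (undirected graph, each pair once)
    offsets = [((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), math.sqrt(2)), ((1, -1), math.sqrt(2))]
    for (dr, dc), mult in offsets:
        r0 = slice(max(0, -dr), nrow - max(0, dr))
        c0 = slice(max(0, -dc), ncol - max(0, dc))
        r1 = slice(max(0, dr), nrow - max(0, -dr))
        c1 = slice(max(0, dc), ncol - max(0, -dc))
        a = idx[r0, c0]
        b = idx[r1, c1]
        ok = (a >= 0) & (b >= 0)
        wa = w[r0, c0][ok]
        wb = w[r1, c1][ok]
        rows_i.append(a[ok])
        rows_j.append(b[ok])
        data.append((wa + wb) * 0.5 * res * mult)
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    d = np.concatenate(data)
    n = int(passable.sum())
    g = sparse.csr_matrix((np.concatenate([d, d]), (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n))
    return g, idx


def _patch_cell_distances(
    surface: CostSurface, patches: list[Patch]
) -> tuple[np.ndarray, np.ndarray]:
    """Least-cost distance from every patch to every passable cell.

    Because intra-habitat steps cost zero, a single source cell per patch
    yields the distance from the whole patch.  Returns (dist, idx) where
    dist has shape (n_patches, n_passable_cells).
    """
    g, idx = _cell_graph(surface)
    sources = []
    for p in patches:
        r, c = p.cells[0]
        node = idx[r, c]
        if node < 0:
            raise ValueError(f"patch {p.id} lies on impassable cells")
        sources.append(node)
    dist = dijkstra(g, directed=False, indices=sources)
    return dist, idx


def least_cost_distance_matrix(
    surface: CostSurface, patches: list[Patch]
) -> np.ndarray:
    """Direct raster least-cost distances between every pair of patches.

    This is the complete-graph (non-planar) distance matrix; the planar
    pipeline uses :func:`least_cost_edge_distances` over Voronoi-adjacent
    pairs instead.  Unreachable pairs get +inf.
    """
    dist, idx = _patch_cell_distances(surface, patches)
    n = len(patches)
    d = np.zeros((n, n))
    for jq, q in enumerate(patches):
        nodes = idx[q.cells[:, 0], q.cells[:, 1]]
        for ip in range(n):
            if ip == jq:
                continue
            d[ip, jq] = dist[ip, nodes].min()
    return np.minimum(d, d.T)  # symmetrise (equal up to float noise)


def build_planar_graph(
    surface: CostSurface, patches: list[Patch]
) -> dict[tuple[int, int], float] | set[tuple[int, int]]:
    """Planar edge set: pairs of patches with adjacent Voronoi cells.

    Every cell of the grid is assigned to its nearest patch (Euclidean
    distance to the nearest habitat cell of a patch); two patches are joined
    when their assignment regions share a 4-adjacent cell border.  Region
    adjacency of a planar partition yields a planar graph; corner-touching
    regions are not joined.
    """
    if not patches:
        raise ValueError("at least one patch required")
    if len(patches) == 1:
        return set()
    labels = patch_label_grid(surface, patches)
    # nearest patch cell for every grid cell
    _, (ri, ci) = ndimage.distance_transform_edt(labels < 0, return_indices=True)
    assign = labels[ri, ci]
    edges: set[tuple[int, int]] = set()
    a = assign[:, :-1]
    b = assign[:, 1:]
    for x, y in zip(a[a != b], b[a != b]):
        edges.add((min(x, y), max(x, y)))
    a = assign[:-1, :]
    b = assign[1:, :]
    for x, y in zip(a[a != b], b[a != b]):
        edges.add((min(x, y), max(x, y)))
    return edges


def least_cost_edge_distances(
    surface: CostSurface,
    patches: list[Patch],
    edges: set[tuple[int, int]],
) -> dict[tuple[int, int], float]:
    """Least-cost distance on the resistance surface for each graph edge.

    The distance is the minimum over cell paths of sum(cell cost * metric
    length traversed in the cell), diagonal steps weighted sqrt(2); habitat
    contributes zero, so distances are measured patch edge to patch edge.
    Unreachable pairs (separated by impassable nodata) get +inf.
    """
    if not edges:
        return {}
    dist, idx = _patch_cell_distances(surface, patches)
    pos = {p.id: i for i, p in enumerate(patches)}
    by_patch_nodes = {p.id: idx[p.cells[:, 0], p.cells[:, 1]] for p in patches}
    out: dict[tuple[int, int], float] = {}
    for (i, j) in sorted(edges):
        row = dist[pos[i]]
        out[(i, j)] = float(row[by_patch_nodes[j]].min())
    return out


def effective_distances(
    patch_ids: list[int], edges: dict[tuple[int, int], float]
) -> np.ndarray:
    """All-pairs shortest-path distances over the planar edge set.

    Because p = exp(-k d) multiplies along a route, the maximum-probability
    path is the minimum accumulated-distance path: effective distance is the
    graph shortest path over the edge distances.  Disconnected pairs get
    +inf (p_ij = 0).
    """
    n = len(patch_ids)
    pos = {pid: i for i, pid in enumerate(patch_ids)}
    g = np.full((n, n), np.inf)
    np.fill_diagonal(g, 0.0)
    for (i, j), dij in edges.items():
        if i in pos and j in pos:
            g[pos[i], pos[j]] = min(g[pos[i], pos[j]], dij)
            g[pos[j], pos[i]] = g[pos[i], pos[j]]
    if n <= 1 or not edges:
        return g
    finite = np.where(np.isinf(g), 0.0, g)
    mask = ~np.isinf(g)
    gg = sparse.csr_matrix((finite[mask], np.nonzero(mask)), shape=(n, n))
    d = shortest_path(gg, method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def build_patch_graph(
    surface: CostSurface, patches: list[Patch]
) -> PatchGraph:
    """Assemble the planar patch network from a cost surface."""
    edge_set = build_planar_graph(surface, patches)
    edges = least_cost_edge_distances(surface, patches, edge_set)
    ids = [p.id for p in patches]
    d = effective_distances(ids, edges)
    unreachable = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if np.isinf(d[i, j])
    ]
    return PatchGraph(
        patch_ids=ids,
        areas=np.array([p.area for p in patches], dtype=float),
        edges=edges,
        d=d,
        landscape_area=surface.landscape_area,
        unreachable_pairs=unreachable,
    )


# ---------------------------------------------------------------------------
# PC / dPC
# ---------------------------------------------------------------------------

def probability_of_connectivity(graph: PatchGraph, model: DispersalModel) -> float:
    """PC = sum_ij a_i a_j exp(-k d_ij) / A**2, i = j terms included."""
    A = graph.landscape_area
    if A <= 0:
        raise ValueError("landscape area must be positive")
    if graph.areas.sum() > A * (1 + 1e-9):
        raise ValueError("total patch area exceeds landscape area")
    p = model.probability(graph.d)
    a = graph.areas
    return float(a @ p @ a) / A**2


def _pc_without(graph: PatchGraph, model: DispersalModel, patch_id: int) -> float:
    """PC' after removing one patch (node, edges, area); A unchanged."""
    keep = [pid for pid in graph.patch_ids if pid != patch_id]
    edges = {
        e: d for e, d in graph.edges.items() if patch_id not in e
    }
    d = effective_distances(keep, edges)
    pos = {pid: i for i, pid in enumerate(graph.patch_ids)}
    areas = np.array([graph.areas[pos[pid]] for pid in keep])
    sub = PatchGraph(
        patch_ids=keep, areas=areas, edges=edges, d=d,
        landscape_area=graph.landscape_area,
    )
    return probability_of_connectivity(sub, model)


def delta_pc(graph: PatchGraph, model: DispersalModel, patch_id: int) -> float:
    """dPC = 100 (PC - PC') / PC for the removal of one patch.

    Effective distances are recomputed over the remaining planar edges, so a
    stepping-stone patch loses more than its own area share.
    """
    if patch_id not in graph.patch_ids:
        raise KeyError(f"unknown patch id {patch_id}")
    pc = probability_of_connectivity(graph, model)
    if pc <= 0:
        raise ValueError("PC is zero; dPC undefined")
    pc_prime = _pc_without(graph, model, patch_id)
    return 100.0 * (pc - pc_prime) / pc


def node_importances(graph: PatchGraph, model: DispersalModel) -> dict[int, float]:
    """dPC for every patch."""
    return {pid: delta_pc(graph, model, pid) for pid in graph.patch_ids}


def connectivity_analysis(
    surface: CostSurface, patches: list[Patch], model: DispersalModel
) -> tuple[PatchGraph, ConnectivityResult]:
    """Full connectivity evaluation: graph, PC, per-patch dPC, ranking."""
    graph = build_patch_graph(surface, patches)
    pc = probability_of_connectivity(graph, model)
    dpc = node_importances(graph, model)
    ranking = sorted(dpc, key=lambda pid: (-dpc[pid], pid))
    return graph, ConnectivityResult(pc=pc, dpc=dpc, ranking=ranking, model=model)


# ---------------------------------------------------------------------------
# Site assignment
# ---------------------------------------------------------------------------

def site_connectivity(
    sites: np.ndarray,
    surface: CostSurface,
    patches: list[Patch],
    dpc: dict[int, float],
    snap_tolerance_cells: int = 0,
) -> np.ndarray:
    """Per-site connectivity: the dPC of the patch containing each site.

    ``sites`` is an (n, 2) array of planar (x, y) points.  A site outside
    every patch is snapped to the nearest patch if the nearest habitat cell
    is within ``snap_tolerance_cells`` cells; otherwise its value is NaN
    (missing, propagated downstream).
    """
    sites = np.asarray(sites, dtype=float)
    labels = patch_label_grid(surface, patches)
    dist, (ri, ci) = ndimage.distance_transform_edt(labels < 0, return_indices=True)
    nrow, ncol = surface.shape
    res = surface.resolution
    out = np.full(len(sites), np.nan)
    for s, (x, y) in enumerate(sites):
        col = int((x - surface.origin[0]) / res)
        row = nrow - 1 - int((y - surface.origin[1]) / res)
        if not (0 <= row < nrow and 0 <= col < ncol):
            continue
        lab = labels[row, col]
        if lab < 0 and dist[row, col] <= snap_tolerance_cells:
            lab = labels[ri[row, col], ci[row, col]]
        if lab >= 0:
            out[s] = dpc.get(lab, np.nan)
    return out
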