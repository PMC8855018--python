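"""Least-cost distances, planar graphs, PC and dPC against brute-force oracles."""

import math
import itertools

import networkx as nx
import numpy as np
import pytest

from patchlink.connectivity import (
    DispersalModel,
    PatchGraph,
    build_patch_graph,
    build_planar_graph,
    calibrate_decay,
    connectivity_analysis,
    delta_pc,
    effective_distances,
    least_cost_distance_matrix,
    least_cost_edge_distances,
    node_importances,
    probability_of_connectivity,
    site_connectivity,
)
from patchlink.landscape import extract_patches

from conftest import make_surface


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def cell_graph_oracle(surface) -> nx.Graph:
    """8-neighbour cell graph built independently with explicit loops."""
    g = nx.Graph()
    nrow, ncol = surface.shape
    w = np.where(surface.habitat, 0.0, surface.cost)
    for r in range(nrow):
        for c in range(ncol):
            if not surface.passable[r, c]:
                continue
            for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrow and 0 <= c2 < ncol and surface.passable[r2, c2]:
                    length = surface.resolution * (math.sqrt(2) if dr and dc else 1.0)
                    g.add_edge((r, c), (r2, c2),
                               weight=(w[r, c] + w[r2, c2]) / 2 * length)
    return g


def enumerate_min_path(graph: nx.Graph, source, target) -> float:
    """Minimum path weight by exhaustive simple-path enumeration.

    One cell per patch suffices: intra-patch steps have weight zero, so the
    enumeration can route through the rest of the patch for free.
    """
    best = math.inf
    for path in nx.all_simple_paths(graph, source, target):
        wsum = sum(graph[u][v]["weight"] for u, v in zip(path, path[1:]))
        best = min(best, wsum)
    return best


def fw_cell_oracle(graph: nx.Graph, source, target) -> float:
    """Floyd-Warshall on the independently built cell graph."""
    nodes = list(graph.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, data in graph.edges(data=True):
        d[pos[u], pos[v]] = d[pos[v], pos[u]] = data["weight"]
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return float(d[pos[source], pos[target]])


def pc_oracle(areas, d, A, k) -> float:
    """Explicit double sum, i = j included, unreachable pairs contribute 0."""
    total = 0.0
    n = len(areas)
    for i in range(n):
        for j in range(n):
            p = 0.0 if math.isinf(d[i][j]) else math.exp(-k * d[i][j])
            total += areas[i] * areas[j] * p
    return total / A**2


def floyd_warshall_oracle(n, edges) -> np.ndarray:
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (i, j), w in edges.items():
        d[i, j] = d[j, i] = min(d[i, j], w)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


# ---------------------------------------------------------------------------
# Decay calibration
# ---------------------------------------------------------------------------

class TestCalibrateDecay:
    @pytest.mark.parametrize("d_star,expected", [
        (300.0, 0.009986),  # -ln(0.05)/300
        (500.0, 0.005991),
    ])
    def test_closed_form(self, d_star, expected):
        assert calibrate_decay(d_star, 0.05) == pytest.approx(expected, abs=5e-7)

    @pytest.mark.parametrize("d_star,p_star", [(100, 0.05), (300, 0.5), (42, 0.01)])
    def test_round_trip(self, d_star, p_star):
        k = calibrate_decay(d_star, p_star)
        assert math.exp(-k * d_star) == pytest.approx(p_star, rel=1e-12)

    @pytest.mark.parametrize("d_star,p_star", [(0, 0.05), (-5, 0.05), (100, 0.0),
                                               (100, 1.0), (100, 1.5)])
    def test_invalid_inputs(self, d_star, p_star):
        with pytest.raises(ValueError):
            calibrate_decay(d_star, p_star)


# ---------------------------------------------------------------------------
# Least-cost distances on the raster
# ---------------------------------------------------------------------------

class TestLeastCostDistances:
    def test_corridor_hand_count(self, corridor_surface):
        patches = extract_patches(corridor_surface)
        assert len(patches) == 2
        d = least_cost_distance_matrix(corridor_surface, patches)
        # 10 corridor cells x 2 m x cost 10
        assert d[0, 1] == pytest.approx(200.0)

    def test_matches_exhaustive_enumeration_on_small_grids(self):
        checked = 0
        rng = np.random.default_rng(11)
        while checked < 5:
            g = rng.choice([2, 3, 4], size=(3, 3)).astype(np.int64)
            g[0, 0] = 1
            g[2, 2] = 1
            g[1, 1] = rng.choice([2, 3, 4])  # keep the corners apart
            s = make_surface(g)
            patches = extract_patches(s)
            if len(patches) != 2:
                continue
            checked += 1
            d = least_cost_distance_matrix(s, patches)
            oracle = cell_graph_oracle(s)
            want = enumerate_min_path(oracle, tuple(patches[0].cells[0]),
                                      tuple(patches[1].cells[0]))
            assert d[0, 1] == pytest.approx(want, rel=1e-9)

    def test_wall_forces_detour_matches_floyd_warshall(self):
        g = np.full((5, 5), 2, dtype=np.int64)
        g[0, 0] = 1
        g[0, 4] = 1
        g[0:4, 2] = 4  # cost-1000 wall with a gap at the bottom
        s = make_surface(g)
        patches = extract_patches(s)
        d = least_cost_distance_matrix(s, patches)
        oracle = cell_graph_oracle(s)
        want = fw_cell_oracle(oracle, (0, 0), (0, 4))
        assert d[0, 1] == pytest.approx(want, rel=1e-9)
        direct = (10 + 1000) / 2 * 2 * 2 + (1000 + 1000) / 2 * 2
        assert d[0, 1] < direct  # the detour through the gap is cheaper

    def test_unreachable_pair_is_infinite(self):
        g = np.full((5, 5), 1, dtype=np.int64)
        g[:, 2] = -9999  # nodata ring splits the grid
        s = make_surface(g)
        patches = extract_patches(s)
        assert len(patches) == 2
        d = least_cost_distance_matrix(s, patches)
        assert np.isinf(d[0, 1])
        graph = build_patch_graph(s, patches)
        assert (patches[0].id, patches[1].id) in graph.unreachable_pairs


# ---------------------------------------------------------------------------
# Planar graph construction
# ---------------------------------------------------------------------------

def _surface_with_blocks(blocks, shape=(40, 40)):
    g = np.full(shape, 2, dtype=np.int64)
    for r0, c0 in blocks:
        g[r0:r0 + 3, c0:c0 + 3] = 1
    return make_surface(g)


class TestPlanarGraph:
    def test_single_patch_no_edges(self):
        s = _surface_with_blocks([(5, 5)])
        patches = extract_patches(s)
        assert build_planar_graph(s, patches) == set()

    def test_three_collinear_patches_skip_long_edge(self):
        s = _surface_with_blocks([(18, 4), (18, 18), (18, 32)])
        patches = extract_patches(s)
        edges = build_planar_graph(s, patches)
        assert edges == {(0, 1), (1, 2)}

    def test_square_corners_never_complete(self):
        s = _surface_with_blocks([(6, 6), (6, 30), (30, 6), (30, 30)])
        patches = extract_patches(s)
        edges = build_planar_graph(s, patches)
        assert len(edges) in (4, 5)
        assert not ({(0, 3), (1, 2)} <= edges)  # both diagonals never co-exist


# ---------------------------------------------------------------------------
# Effective distances over the patch graph
# ---------------------------------------------------------------------------

class TestEffectiveDistances:
    def test_chain_additivity(self):
        d = effective_distances([0, 1, 2], {(0, 1): 100.0, (1, 2): 200.0})
        assert d[0, 2] == pytest.approx(300.0)

    def test_triangle_shortcut(self):
        d = effective_distances([0, 1, 2],
                                {(0, 1): 100.0, (1, 2): 100.0, (0, 2): 250.0})
        assert d[0, 2] == pytest.approx(200.0)

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            ids = list(range(n))
            edges = {}
            for i, j in itertools.combinations(ids, 2):
                if rng.random() < 0.5:
                    edges[(i, j)] = float(rng.uniform(10, 500))
            d = effective_distances(ids, edges)
            want = floyd_warshall_oracle(n, edges)
            assert np.allclose(d, want, rtol=1e-12), (edges, d, want)


# ---------------------------------------------------------------------------
# PC and dPC
# ---------------------------------------------------------------------------

def toy_graph(areas, edges, A):
    ids = list(range(len(areas)))
    d = effective_distances(ids, edges)
    return PatchGraph(patch_ids=ids, areas=np.array(areas, dtype=float),
                      edges=edges, d=d, landscape_area=A)


class TestPC:
    def test_single_patch_spanning_landscape(self):
        g = toy_graph([1e4], {}, 1e4)
        m = DispersalModel(300.0)
        assert probability_of_connectivity(g, m) == pytest.approx(1.0)

    def test_infinite_decay_leaves_self_terms(self):
        areas = [100.0, 200.0, 300.0]
        g = toy_graph(areas, {(0, 1): 100.0, (1, 2): 100.0}, 1e4)
        m = DispersalModel(1e-9)  # k enormous: p_ij -> 0 for i != j
        want = sum(a * a for a in areas) / 1e4**2
        assert probability_of_connectivity(g, m) == pytest.approx(want, rel=1e-6)

    def test_three_patch_chain_matches_double_sum(self):
        areas = [100.0, 200.0, 300.0]
        edges = {(0, 1): 100.0, (1, 2): 100.0}
        g = toy_graph(areas, edges, 1e4)
        k = math.log(20) / 300.0
        m = DispersalModel(300.0, p_star=0.05)
        assert m.k == pytest.approx(k, rel=1e-12)
        want = pc_oracle(areas, g.d, 1e4, k)
        assert probability_of_connectivity(g, m) == pytest.approx(want, rel=1e-12)

    def test_monotone_in_k_and_bounded(self):
        rng = np.random.default_rng(5)
        areas = rng.uniform(50, 500, 5)
        edges = {(i, j): float(rng.uniform(50, 400))
                 for i in range(5) for j in range(i + 1, 5) if rng.random() < 0.6}
        g = toy_graph(list(areas), edges, 5e3)
        pcs = [probability_of_connectivity(g, DispersalModel(d)) for d in
               (1000.0, 300.0, 100.0, 30.0)]  # decreasing d* = increasing k
        assert all(0 <= pc <= 1 for pc in pcs)
        assert all(a >= b - 1e-15 for a, b in zip(pcs, pcs[1:]))

    def test_area_growth_increases_pc(self):
        edges = {(0, 1): 100.0}
        g1 = toy_graph([100.0, 100.0], edges, 1e4)
        g2 = toy_graph([150.0, 100.0], edges, 1e4)
        m = DispersalModel(300.0)
        assert probability_of_connectivity(g2, m) > probability_of_connectivity(g1, m)

    def test_merging_zero_distance_patches_preserves_pc(self):
        m = DispersalModel(300.0)
        split = toy_graph([100.0, 200.0, 300.0],
                          {(0, 1): 0.0, (0, 2): 150.0, (1, 2): 150.0}, 1e4)
        merged = toy_graph([300.0, 300.0], {(0, 1): 150.0}, 1e4)
        assert probability_of_connectivity(split, m) == pytest.approx(
            probability_of_connectivity(merged, m), rel=1e-12)


class TestDeltaPC:
    def test_single_patch_removal_gives_100(self):
        g = toy_graph([5e3], {}, 1e4)
        assert delta_pc(g, DispersalModel(300.0), 0) == pytest.approx(100.0)

    def test_symmetric_patches_equal_dpc(self):
        g = toy_graph([200.0, 200.0, 500.0],
                      {(0, 2): 100.0, (1, 2): 100.0}, 1e4)
        dpc = node_importances(g, DispersalModel(300.0))
        assert dpc[0] == pytest.approx(dpc[1], rel=1e-12)

    def test_chain_toy_matches_removal_oracle(self):
        areas = [100.0, 200.0, 300.0]
        edges = {(0, 1): 100.0, (1, 2): 100.0}
        g = toy_graph(areas, edges, 1e4)
        m = DispersalModel(300.0)
        k = m.k
        pc = pc_oracle(areas, g.d, 1e4, k)
        for drop in range(3):
            keep = [i for i in range(3) if i != drop]
            sub_edges = {e: w for e, w in edges.items() if drop not in e}
            remap = {pid: i for i, pid in enumerate(keep)}
            d_sub = floyd_warshall_oracle(
                2, {(remap[i], remap[j]): w for (i, j), w in sub_edges.items()})
            want = 100 * (pc - pc_oracle([areas[i] for i in keep], d_sub, 1e4, k)) / pc
            assert delta_pc(g, m, drop) == pytest.approx(want, rel=1e-12)

    def test_dpc_nonnegative_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(2, 7))
            areas = list(rng.uniform(20, 300, n))
            edges = {(i, j): float(rng.uniform(20, 400))
                     for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.7}
            g = toy_graph(areas, edges, 1e4)
            dpc = node_importances(g, DispersalModel(200.0))
            assert all(v >= -1e-9 for v in dpc.values())


class TestSiteConnectivity:
    def test_containment_and_sharing(self):
        s = _surface_with_blocks([(5, 5), (5, 30)], shape=(40, 40))
        patches = extract_patches(s)
        dpc = {0: 7.5, 1: 2.5}
        res = s.resolution
        # two points inside patch 0, one inside patch 1 (row 6 -> y = (40-6.5)*2)
        pts = np.array([
            [6.5 * res, (40 - 6.5) * res],
            [5.5 * res, (40 - 7.0) * res],
            [31.0 * res, (40 - 6.0) * res],
        ])
        vals = site_connectivity(pts, s, patches, dpc)
        assert vals[0] == vals[1] == 7.5
        assert vals[2] == 2.5

    def test_snap_tolerance(self):
        s = _surface_with_blocks([(5, 5)], shape=(20, 20))
        patches = extract_patches(s)
        res = s.resolution
        outside = np.array([[9.5 * res, (20 - 6.0) * res]])  # 1 cell right of patch
        no_snap = site_connectivity(outside, s, patches, {0: 4.0},
                                    snap_tolerance_cells=0)
        snapped = site_connectivity(outside, s, patches, {0: 4.0},
                                    snap_tolerance_cells=2)
        assert np.isnan(no_snap[0])
        assert snapped[0] == 4.0


class TestEndToEnd:
    def test_connectivity_analysis_ranking_sorted(self):
        s = _surface_with_blocks([(5, 5), (5, 30), (30, 18)], shape=(40, 40))
        patches = extract_patches(s)
        graph, result = connectivity_analysis(s, patches, DispersalModel(300.0))
        vals = [result.dpc[pid] for pid in result.ranking]
        assert vals == sorted(vals, reverse=True)
        assert 0 <= result.pc <= 1
        assert graph.n == 3
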