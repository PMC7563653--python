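"""Spatial graph structures against brute-force oracles and closed forms."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

import nucleoqh as nq
from nucleoqh.spatial import decay_threshold


def square_lattice(n: int, spacing: float) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def brute_force_mst_length(pts: np.ndarray) -> float:
    """Minimum total length over all spanning trees (exhaustive, N <= 7)."""
    n = len(pts)
    edges = list(itertools.combinations(range(n), 2))
    lengths = {e: float(np.linalg.norm(pts[e[0]] - pts[e[1]])) for e in edges}
    best = np.inf
    for tree in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for u, v in tree:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            best = min(best, sum(lengths[e] for e in tree))
    return best


def test_square_lattice_closed_form():
    pts = square_lattice(4, spacing=8.0)  # px; mpp=1 -> um
    g = nq.build_graphs(pts, mpp=1.0)
    # 4 interior cells, each a square of area s^2
    assert len(g.voronoi_areas) == 4
    assert np.allclose(g.voronoi_areas, 64.0)
    assert np.allclose(g.voronoi_perimeters, 32.0)
    # MST: 15 edges of length s
    assert len(g.mst_lengths) == 15
    assert np.allclose(g.mst_lengths, 8.0)
    # Delaunay edges lie on lattice axes or diagonals
    assert np.all(
        np.isclose(g.delaunay_sides, 8.0) | np.isclose(g.delaunay_sides, 8.0 * np.sqrt(2))
    )
    feats = nq.graph_features(g)
    assert len(feats) == 51
    assert feats["graph:voronoi_area:sd"] == 0.0
    assert feats["graph:voronoi_perimeter:minmax"] == 1.0
    assert feats["graph:voronoi_area:disorder"] == 0.0
    assert feats["graph:mst_edge:disorder"] == 0.0


@pytest.mark.parametrize("n,seed", [(5, 1), (6, 2), (7, 3)])
def test_mst_matches_brute_force(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 50, (n, 2))
    g = nq.build_graphs(pts, mpp=1.0)
    assert len(g.mst_lengths) == n - 1
    assert g.mst_lengths.sum() == pytest.approx(brute_force_mst_length(pts), rel=1e-9)


def test_right_triangle_mst():
    pts = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0], [100.0, 100.0]])
    g = nq.build_graphs(pts, mpp=1.0)
    # among the three triangle vertices, the MST keeps edges 3 and 4, not 5
    tri_edges = sorted(
        l for (u, v), l in zip(g.mst_edges, g.mst_lengths) if u < 3 and v < 3
    )
    assert tri_edges == pytest.approx([3.0, 4.0])


def test_voronoi_delaunay_duality_and_mst_subset():
    rng = np.random.default_rng(8)
    pts = rng.uniform(0, 100, (40, 2))
    g = nq.build_graphs(pts, mpp=1.0)
    # every MST edge is a Delaunay edge
    from scipy.spatial import Delaunay

    tri = Delaunay(pts)
    dedges = set()
    for s in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            dedges.add((min(s[a], s[b]), max(s[a], s[b])))
    for u, v in g.mst_edges:
        assert (min(u, v), max(u, v)) in dedges
    # Delaunay triangle count consistent with Euler's relation for the
    # triangulation of the convex hull: n - 1 - h + t where simplices
    # triangulate the hull interior
    assert len(g.delaunay_areas) == len(tri.simplices)


def test_rigid_motion_invariance_of_graph_features():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 100, (60, 2))
    theta = np.radians(29.0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + np.array([13.0, -7.0])
    f1 = nq.graph_features(nq.build_graphs(pts, mpp=0.5))
    f2 = nq.graph_features(nq.build_graphs(moved, mpp=0.5))
    for k in f1:
        assert f2[k] == pytest.approx(f1[k], rel=1e-6, abs=1e-9), k


def test_micron_unit_handling():
    """Neighbor-count radii are in microns: doubling mpp at fixed pixel
    coordinates is the same as halving the radius."""
    rng = np.random.default_rng(6)
    pts = rng.uniform(0, 200, (80, 2))
    f_fine = nq.graph_features(nq.build_graphs(pts, mpp=0.25))
    f_coarse = nq.graph_features(nq.build_graphs(pts, mpp=0.5))
    assert f_coarse["graph:nn_count_r20:mean"] == pytest.approx(
        f_fine["graph:nn_count_r10:mean"]
    )
    assert f_coarse["graph:knn_dist_3:mean"] == pytest.approx(
        2.0 * f_fine["graph:knn_dist_3:mean"], rel=1e-9
    )


def test_build_graphs_preconditions():
    with pytest.raises(ValueError):
        nq.build_graphs(np.array([[0.0, 0], [1, 1], [2, 2]]), mpp=1.0)
    collinear = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
    with pytest.raises(ValueError):
        nq.build_graphs(collinear, mpp=1.0)


def test_jitter_increases_voronoi_area_sd():
    lo, hi = [], []
    for seed in range(10):
        _, g1 = nq.generate_nucleus_field(
            nq.SyntheticConfig(n_nuclei=60, field_size=(300, 300), jitter_sigma=0.5, seed=seed)
        )
        _, g2 = nq.generate_nucleus_field(
            nq.SyntheticConfig(n_nuclei=60, field_size=(300, 300), jitter_sigma=1.0, seed=seed)
        )
        lo.append(np.std(nq.build_graphs(g1.centroids, g1.mpp).voronoi_areas, ddof=1))
        hi.append(np.std(nq.build_graphs(g2.centroids, g2.mpp).voronoi_areas, ddof=1))
    assert np.mean(hi) > np.mean(lo)


# --- cell cluster graph ---------------------------------------------------


def test_chain_collapses_to_single_node():
    pts = np.column_stack([np.arange(5) * 4.0, np.zeros(5)])  # 4 um apart < eps
    g = nq.build_cluster_graph(pts, mpp=1.0, eps=6.0)
    assert len(g.node_positions) == 1
    assert len(g.edges) == 0
    assert g.member_counts[0] == 5


def test_three_close_clusters_form_triangle():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.0]])
    g = nq.build_cluster_graph(pts, mpp=1.0, eps=2.0, threshold=decay_threshold(12.0))
    assert len(g.node_positions) == 3
    assert len(g.edges) == 3
    feats = nq.cluster_graph_features(g)
    assert feats["cluster:transitivity"] == 1.0
    assert feats["cluster:avg_clustering_coeff"] == 1.0
    assert feats["cluster:n_components"] == 1.0
    assert feats["cluster:diameter"] == 1.0
    assert feats["cluster:spectral_radius"] == pytest.approx(2.0)


def test_path_graph_features():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
    g = nq.build_cluster_graph(pts, mpp=1.0, eps=2.0, threshold=decay_threshold(11.0))
    assert len(g.edges) == 2  # 0-1 and 1-2; 0-2 at 20 um exceeds the cutoff
    feats = nq.cluster_graph_features(g)
    assert feats["cluster:avg_clustering_coeff"] == 0.0
    assert feats["cluster:endpoint_fraction"] == pytest.approx(2.0 / 3.0)
    assert feats["cluster:diameter"] == 2.0
    assert len(feats) == 26


def test_cluster_edges_match_brute_force():
    rng = np.random.default_rng(20)
    pts = rng.uniform(0, 150, (20, 2))
    eps, alpha, cutoff = 12.0, 0.5, 40.0
    thr = decay_threshold(cutoff, alpha)
    g = nq.build_cluster_graph(pts, mpp=1.0, eps=eps, alpha=alpha, threshold=thr)
    # independent oracle: scipy single-linkage clustering + all-pairs rule
    labels = fcluster(linkage(pdist(pts), method="single"), t=eps, criterion="distance")
    centers = {}
    for lab in np.unique(labels):
        centers[lab] = pts[labels == lab].mean(axis=0)
    order = sorted(centers, key=lambda lab: int(np.min(np.nonzero(labels == lab)[0])))
    centers_arr = np.array([centers[lab] for lab in order])
    assert np.allclose(np.sort(centers_arr, axis=0), np.sort(g.node_positions, axis=0))
    expected = set()
    pos_index = {tuple(np.round(v, 9)): i for i, v in enumerate(g.node_positions)}
    for i in range(len(centers_arr)):
        for j in range(i + 1, len(centers_arr)):
            d = np.linalg.norm(centers_arr[i] - centers_arr[j])
            if d > 0 and d ** (-alpha) >= thr:
                u = pos_index[tuple(np.round(centers_arr[i], 9))]
                v = pos_index[tuple(np.round(centers_arr[j], 9))]
                expected.add((min(u, v), max(u, v)))
    got = {(min(u, v), max(u, v)) for u, v in g.edges}
    assert got == expected


def test_empty_cluster_graph_warns_all_zero():
    g = nq.ClusterGraph(
        node_positions=np.empty((0, 2)),
        member_counts=np.empty(0, dtype=int),
        edges=np.empty((0, 2), dtype=int),
        edge_lengths=np.empty(0),
    )
    with pytest.warns(UserWarning):
        feats = nq.cluster_graph_features(g)
    assert all(v == 0.0 for v in feats.values())
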