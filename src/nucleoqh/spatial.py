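"""Spatial-architecture features from nuclear centroids.

Two feature blocks are computed here:

* 51 graph features from the Voronoi tessellation, Delaunay triangulation,
  minimum spanning tree and k-nearest-neighbor structure of the centroid
  cloud (area/perimeter/edge-length statistics plus local-density measures);
* 26 cell-cluster-graph features, where nuclei are first merged into
  clusters by single-linkage at a distance ``eps`` and cluster centroids
  become nodes of a graph whose edges follow a deterministic distance-decay
  rule d^(-alpha) >= threshold.

All distances are in microns (pixel coordinates times ``mpp``).  The
"disorder" statistic used throughout is 1 - 1/(1 + SD/mean), a bounded
coefficient-of-variation transform: 0 for a perfectly regular arrangement,
approaching 1 with increasing relative spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree as _sparse_mst
from scipy.spatial import ConvexHull, Delaunay, Voronoi, cKDTree
from scipy.spatial.distance import pdist, squareform

from .manifest import CLUSTER_MEASURES, KNN_KS, NEIGHBOR_RADII_UM

#: disc radius (um) used for the per-nucleus local-density measure
LOCAL_DENSITY_RADIUS_UM = 50.0

#: cell-cluster-graph defaults: single-linkage merge radius and decay rule.
#: eps must stay below typical nearest-neighbor spacing (~10 um in packed
#: tumor fields) or single linkage collapses the field into one node.
CCG_EPS_UM = 6.0
CCG_ALPHA = 0.5
CCG_CUTOFF_UM = 12.0  # edge iff inter-cluster distance <= cutoff


def decay_threshold(cutoff_um: float, alpha: float = CCG_ALPHA) -> float:
    """Threshold on d^(-alpha) equivalent to a hard distance cutoff."""
    return cutoff_um ** (-alpha)


@dataclass
class SpatialGraphs:
    """Voronoi/Delaunay/MST/kNN structures built over one centroid cloud."""

    centroids_um: np.ndarray
    voronoi_areas: np.ndarray  # interior cells only
    voronoi_perimeters: np.ndarray
    voronoi_chords: np.ndarray  # centroid-to-vertex segment lengths, interior cells
    interior_mask: np.ndarray  # per-centroid: has an interior (finite, in-hull) cell
    delaunay_sides: np.ndarray
    delaunay_areas: np.ndarray
    mst_edges: np.ndarray  # (n-1, 2) vertex index pairs
    mst_lengths: np.ndarray
    knn_dists: dict[int, np.ndarray] = field(default_factory=dict)
    neighbor_counts: dict[int, np.ndarray] = field(default_factory=dict)
    local_density: np.ndarray = field(default_factory=lambda: np.empty(0))


def _poly_area_perimeter(verts: np.ndarray) -> tuple[float, float]:
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs((x * yn - xn * y).sum())
    perim = float(np.hypot(xn - x, yn - y).sum())
    return area, perim


def build_graphs(centroids: np.ndarray, mpp: float) -> SpatialGraphs:
    """Build all four spatial structures over nuclear centroids.

    ``centroids`` is (n, 2) in pixel coordinates; internal geometry is in
    microns.  Requires >= 4 non-collinear points.  Voronoi cells that are
    unbounded or reach outside the convex hull of the centroids are flagged
    non-interior and excluded from Voronoi statistics.
    """
    pts = np.asarray(centroids, dtype=float) * float(mpp)
    if len(pts) < 4:
        raise ValueError("build_graphs requires >= 4 centroids")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("centroids are collinear")

    vor = Voronoi(pts)
    hull = ConvexHull(pts)
    # point-in-hull via the hull's facet inequalities A x + b <= 0
    eqs = hull.equations
    tol = 1e-9 * max(1.0, float(np.abs(pts).max()))

    def in_hull(v: np.ndarray) -> bool:
        return bool(np.all(eqs[:, :2] @ v + eqs[:, 2] <= tol))

    areas, perims, chords = [], [], []
    interior = np.zeros(len(pts), dtype=bool)
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if len(region) == 0 or -1 in region:
            continue
        verts = vor.vertices[region]
        if not all(in_hull(v) for v in verts):
            continue
        interior[i] = True
        a, p = _poly_area_perimeter(verts)
        areas.append(a)
        perims.append(p)
        cell_centroid = verts.mean(axis=0)
        chords.extend(np.linalg.norm(verts - cell_centroid, axis=1))

    tri = Delaunay(pts)
    sides, tareas = [], []
    seen_edges = set()
    for simplex in tri.simplices:
        v = pts[simplex]
        for a, b in ((0, 1), (1, 2), (0, 2)):
            e = (min(simplex[a], simplex[b]), max(simplex[a], simplex[b]))
            if e not in seen_edges:
                seen_edges.add(e)
                sides.append(float(np.linalg.norm(v[a] - v[b])))
        tareas.append(
            0.5
            * abs(
                (v[1, 0] - v[0, 0]) * (v[2, 1] - v[0, 1])
                - (v[2, 0] - v[0, 0]) * (v[1, 1] - v[0, 1])
            )
        )

    dmat = squareform(pdist(pts))
    mst = _sparse_mst(dmat).tocoo()
    mst_edges = np.column_stack([mst.row, mst.col])
    mst_lengths = mst.data.copy()

    tree = cKDTree(pts)
    kmax = max(KNN_KS)
    dists, _ = tree.query(pts, k=kmax + 1)  # first neighbor is self
    knn = {k: dists[:, k].copy() for k in KNN_KS}
    counts = {}
    for r in NEIGHBOR_RADII_UM:
        counts[r] = np.array([len(tree.query_ball_point(p, r)) - 1 for p in pts])
    n_r = np.array(
        [len(tree.query_ball_point(p, LOCAL_DENSITY_RADIUS_UM)) - 1 for p in pts]
    )
    density = n_r / (np.pi * LOCAL_DENSITY_RADIUS_UM**2)

    return SpatialGraphs(
        centroids_um=pts,
        voronoi_areas=np.array(areas),
        voronoi_perimeters=np.array(perims),
        voronoi_chords=np.array(chords),
        interior_mask=interior,
        delaunay_sides=np.array(sides),
        delaunay_areas=np.array(tareas),
        mst_edges=mst_edges,
        mst_lengths=mst_lengths,
        knn_dists=knn,
        neighbor_counts=counts,
        local_density=density,
    )


def _disorder(x: np.ndarray) -> float:
    m = float(np.mean(x))
    if m == 0:
        return 0.0
    s = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return 1.0 - 1.0 / (1.0 + s / m)


def _minmax(x: np.ndarray) -> float:
    mx = float(np.max(x))
    if mx == 0:
        return 1.0
    return float(np.min(x) / mx)


def _four_stats(prefix: str, x: np.ndarray, out: dict[str, float]) -> None:
    out[f"{prefix}:mean"] = float(np.mean(x))
    out[f"{prefix}:sd"] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    out[f"{prefix}:minmax"] = _minmax(x)
    out[f"{prefix}:disorder"] = _disorder(x)


def _three_stats(prefix: str, x: np.ndarray, out: dict[str, float]) -> None:
    out[f"{prefix}:mean"] = float(np.mean(x))
    out[f"{prefix}:sd"] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    out[f"{prefix}:disorder"] = _disorder(x)


def graph_features(graphs: SpatialGraphs) -> dict[str, float]:
    """The 51-value graph feature block, keyed by manifest names."""
    if len(graphs.voronoi_areas) < 2:
        raise ValueError("graph_features requires >= 2 interior Voronoi cells")
    out: dict[str, float] = {}
    _four_stats("graph:voronoi_area", graphs.voronoi_areas, out)
    _four_stats("graph:voronoi_perimeter", graphs.voronoi_perimeters, out)
    _four_stats("graph:voronoi_chord", graphs.voronoi_chords, out)
    _four_stats("graph:delaunay_side", graphs.delaunay_sides, out)
    _four_stats("graph:delaunay_area", graphs.delaunay_areas, out)
    _four_stats("graph:mst_edge", graphs.mst_lengths, out)
    for k in KNN_KS:
        _three_stats(f"graph:knn_dist_{k}", graphs.knn_dists[k], out)
    for r in NEIGHBOR_RADII_UM:
        _three_stats(f"graph:nn_count_r{r}", graphs.neighbor_counts[r].astype(float), out)
    _three_stats("graph:local_density", graphs.local_density, out)
    return out


@dataclass
class ClusterGraph:
    """Graph whose nodes are single-linkage clusters of nuclei."""

    node_positions: np.ndarray  # (m, 2) cluster centroids, um
    member_counts: np.ndarray  # nuclei per node
    edges: np.ndarray  # (e, 2) node index pairs, i < j
    edge_lengths: np.ndarray

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.node_positions)))
        for (u, v), w in zip(self.edges, self.edge_lengths):
            g.add_edge(int(u), int(v), length=float(w))
        return g


def build_cluster_graph(
    centroids: np.ndarray,
    mpp: float,
    eps: float = CCG_EPS_UM,
    alpha: float = CCG_ALPHA,
    threshold: float | None = None,
) -> ClusterGraph:
    """Build the cell cluster graph.

    Nuclei are merged by single linkage at distance ``eps`` (microns):
    clusters are the connected components of the graph joining centroid
    pairs closer than ``eps``.  Each cluster's centroid is a node; an edge
    (u, v) is present iff d(u, v)^(-alpha) >= threshold, i.e. iff the
    inter-node distance is below the equivalent cutoff.  The decay rule is
    deterministic.
    """
    pts = np.asarray(centroids, dtype=float) * float(mpp)
    if len(pts) < 1:
        raise ValueError("build_cluster_graph requires >= 1 centroid")
    if threshold is None:
        threshold = decay_threshold(CCG_CUTOFF_UM, alpha)
    # single linkage at eps == connected components of the eps-ball graph
    tree = cKDTree(pts)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    g.add_edges_from(map(tuple, pairs))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])  # deterministic node order
    nodes = np.array([pts[c].mean(axis=0) for c in comps])
    sizes = np.array([len(c) for c in comps])
    edges, lengths = [], []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            d = float(np.linalg.norm(nodes[i] - nodes[j]))
            if d > 0 and d ** (-alpha) >= threshold:
                edges.append((i, j))
                lengths.append(d)
    return ClusterGraph(
        node_positions=nodes,
        member_counts=sizes,
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        edge_lengths=np.array(lengths),
    )


def cluster_graph_features(graph: ClusterGraph) -> dict[str, float]:
    """The 26-value cell-cluster-graph block, keyed by manifest names.

    Path-based measures (eccentricity, diameter, radius, average path
    length) are computed on the giant component.  An empty graph yields an
    all-zero block with a warning.
    """
    out = {f"cluster:{m}": 0.0 for m in CLUSTER_MEASURES}
    n = len(graph.node_positions)
    if n == 0:
        warnings.warn("empty cluster graph: all-zero feature block")
        return out
    g = graph.to_networkx()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    out["cluster:node_count"] = float(n)
    out["cluster:edge_count"] = float(g.number_of_edges())
    out["cluster:degree_mean"] = float(degrees.mean())
    out["cluster:degree_sd"] = float(degrees.std(ddof=1)) if n > 1 else 0.0
    el = graph.edge_lengths
    if len(el):
        out["cluster:edge_length_mean"] = float(el.mean())
        out["cluster:edge_length_sd"] = float(el.std(ddof=1)) if len(el) > 1 else 0.0
        out["cluster:edge_length_minmax"] = _minmax(el)
        out["cluster:edge_length_disorder"] = _disorder(el)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(comps[0])
    if giant.number_of_nodes() > 1:
        ecc = nx.eccentricity(giant)
        ev = np.array(list(ecc.values()), dtype=float)
        out["cluster:eccentricity_mean"] = float(ev.mean())
        out["cluster:eccentricity_sd"] = float(ev.std(ddof=1)) if len(ev) > 1 else 0.0
        out["cluster:eccentricity_p90"] = float(np.percentile(ev, 90))
        out["cluster:diameter"] = float(ev.max())
        radius = float(ev.min())
        out["cluster:radius"] = radius
        out["cluster:avg_path_length"] = float(nx.average_shortest_path_length(giant))
        out["cluster:central_point_count"] = float(sum(1 for e in ecc.values() if e == radius))
    else:
        # a one-node giant component: its sole node is central by convention
        out["cluster:central_point_count"] = 1.0
    out["cluster:avg_clustering_coeff"] = float(nx.average_clustering(g)) if n > 0 else 0.0
    out["cluster:transitivity"] = float(nx.transitivity(g))
    out["cluster:n_components"] = float(len(comps))
    out["cluster:giant_component_ratio"] = float(len(comps[0])) / n
    out["cluster:isolated_fraction"] = float(np.mean(degrees == 0))
    out["cluster:endpoint_fraction"] = float(np.mean(degrees == 1))
    sizes = graph.member_counts.astype(float)
    out["cluster:cluster_size_mean"] = float(sizes.mean())
    out["cluster:cluster_size_sd"] = float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0
    out["cluster:cluster_size_minmax"] = _minmax(sizes)
    if g.number_of_edges() > 0:
        a = nx.to_numpy_array(g)
        evals = np.sort(np.linalg.eigvalsh(a))
        out["cluster:spectral_radius"] = float(evals[-1])
        out["cluster:second_eigenvalue"] = float(evals[-2]) if n > 1 else 0.0
    return out
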