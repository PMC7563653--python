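"""Canonical feature manifest.

The manifest is the single source of truth for the order, names and family
tags of the 216 nuclear morphometry features (51 graph, 100 shape,
39 orientation-disorder, 26 cell-cluster-graph).  Every module resolves
features by name; only the CSV boundary relies on column order, and that
order is this manifest's order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MANIFEST_VERSION = "1.0"

FAMILY_SIZES = {"graph": 51, "shape": 100, "disorder": 39, "cluster": 26}

#: the four aggregate statistics used for graph-structure measures
_GRAPH_STATS = ("mean", "sd", "minmax", "disorder")
#: the four aggregate statistics used for per-nucleus shape measures
_SHAPE_STATS = ("mean", "median", "sd", "minmax")
#: the three aggregate statistics used for per-subgraph disorder measures
_DISORDER_STATS = ("mean", "sd", "range")

#: the 25 canonical per-nucleus shape measures, in order
SHAPE_MEASURES = (
    "area",
    "perimeter",
    "radial_dist_max",
    "radial_dist_mean",
    "radial_dist_sd",
    "minmax_radius_ratio",
    "smoothness",
    "fractal_dimension",
    "hu_moment_1",
    "hu_moment_2",
    "hu_moment_3",
    "hu_moment_4",
    "hu_moment_5",
    "hu_moment_6",
    "hu_moment_7",
    "fourier_descriptor_1",
    "fourier_descriptor_2",
    "fourier_descriptor_3",
    "fourier_descriptor_4",
    "fourier_descriptor_5",
    "fourier_descriptor_6",
    "fourier_descriptor_7",
    "fourier_descriptor_8",
    "fourier_descriptor_9",
    "fourier_descriptor_10",
)

#: the 13 second-order co-occurrence measures, in order
DISORDER_MEASURES = (
    "contrast_energy",
    "contrast_inverse_moment",
    "contrast_average",
    "contrast_variance",
    "contrast_entropy",
    "intensity_average",
    "intensity_variance",
    "intensity_entropy",
    "entropy",
    "energy",
    "correlation",
    "info_measure_corr_1",
    "info_measure_corr_2",
)

KNN_KS = (3, 5, 7)
NEIGHBOR_RADII_UM = (10, 20, 30, 40, 50)

#: the 26 cell-cluster-graph measures, in order
CLUSTER_MEASURES = (
    "node_count",
    "edge_count",
    "degree_mean",
    "degree_sd",
    "edge_length_mean",
    "edge_length_sd",
    "edge_length_minmax",
    "edge_length_disorder",
    "eccentricity_mean",
    "eccentricity_sd",
    "eccentricity_p90",
    "diameter",
    "radius",
    "avg_path_length",
    "avg_clustering_coeff",
    "transitivity",
    "n_components",
    "giant_component_ratio",
    "isolated_fraction",
    "endpoint_fraction",
    "central_point_count",
    "cluster_size_mean",
    "cluster_size_sd",
    "cluster_size_minmax",
    "spectral_radius",
    "second_eigenvalue",
)


@dataclass(frozen=True)
class FeatureRecord:
    name: str
    family: str  # graph | shape | disorder | cluster
    units: str
    definition: str


def _graph_records() -> list[FeatureRecord]:
    recs = []
    for measure, units in (
        ("voronoi_area", "um^2"),
        ("voronoi_perimeter", "um"),
        ("voronoi_chord", "um"),
    ):
        for stat in _GRAPH_STATS:
            recs.append(
                FeatureRecord(
                    f"graph:{measure}:{stat}", "graph", units if stat in ("mean", "sd") else "1",
                    f"{stat} over interior Voronoi cells of {measure}",
                )
            )
    for measure, units in (("delaunay_side", "um"), ("delaunay_area", "um^2")):
        for stat in _GRAPH_STATS:
            recs.append(
                FeatureRecord(
                    f"graph:{measure}:{stat}", "graph", units if stat in ("mean", "sd") else "1",
                    f"{stat} over Delaunay triangles of {measure}",
                )
            )
    for stat in _GRAPH_STATS:
        recs.append(
            FeatureRecord(
                f"graph:mst_edge:{stat}", "graph", "um" if stat in ("mean", "sd") else "1",
                f"{stat} of minimum-spanning-tree edge lengths",
            )
        )
    for k in KNN_KS:
        for stat in ("mean", "sd", "disorder"):
            recs.append(
                FeatureRecord(
                    f"graph:knn_dist_{k}:{stat}", "graph", "um" if stat != "disorder" else "1",
                    f"{stat} of per-nucleus distance to {k}-th nearest centroid",
                )
            )
    for r in NEIGHBOR_RADII_UM:
        for stat in ("mean", "sd", "disorder"):
            recs.append(
                FeatureRecord(
                    f"graph:nn_count_r{r}:{stat}", "graph", "count" if stat != "disorder" else "1",
                    f"{stat} of per-nucleus centroid count within {r} um",
                )
            )
    for stat in ("mean", "sd", "disorder"):
        recs.append(
            FeatureRecord(
                f"graph:local_density:{stat}", "graph", "1/um^2" if stat != "disorder" else "1",
                f"{stat} of per-nucleus local centroid density",
            )
        )
    return recs


_SHAPE_UNITS = {
    "area": "um^2",
    "perimeter": "um",
    "radial_dist_max": "um",
    "radial_dist_mean": "um",
    "radial_dist_sd": "um",
}


def _shape_records() -> list[FeatureRecord]:
    recs = []
    for measure in SHAPE_MEASURES:
        for stat in _SHAPE_STATS:
            units = _SHAPE_UNITS.get(measure, "1") if stat in ("mean", "median", "sd") else "1"
            recs.append(
                FeatureRecord(
                    f"shape:{measure}:{stat}", "shape", units,
                    f"{stat} over nuclei of per-nucleus {measure}",
                )
            )
    return recs


def _disorder_records() -> list[FeatureRecord]:
    return [
        FeatureRecord(
            f"disorder:{measure}:{stat}", "disorder", "1",
            f"{stat} over local subgraphs of orientation co-occurrence {measure}",
        )
        for measure in DISORDER_MEASURES
        for stat in _DISORDER_STATS
    ]


def _cluster_records() -> list[FeatureRecord]:
    return [
        FeatureRecord(
            f"cluster:{measure}", "cluster", "1",
            f"cell-cluster-graph {measure}",
        )
        for measure in CLUSTER_MEASURES
    ]


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered, versioned list of the 216 canonical feature records."""

    version: str = MANIFEST_VERSION
    records: tuple[FeatureRecord, ...] = field(default_factory=tuple)

    @classmethod
    def canonical(cls) -> "FeatureManifest":
        recs = _graph_records() + _shape_records() + _disorder_records() + _cluster_records()
        m = cls(version=MANIFEST_VERSION, records=tuple(recs))
        m._validate()
        return m

    def _validate(self) -> None:
        counts: dict[str, int] = {}
        names = set()
        for r in self.records:
            counts[r.family] = counts.get(r.family, 0) + 1
            if r.name in names:
                raise ValueError(f"duplicate feature name: {r.name}")
            names.add(r.name)
        if counts != FAMILY_SIZES:
            raise ValueError(f"family counts {counts} != {FAMILY_SIZES}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def families(self) -> list[str]:
        return [r.family for r in self.records]

    def family_names(self, family: str) -> list[str]:
        return [r.name for r in self.records if r.family == family]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.records)


_CANONICAL: FeatureManifest | None = None


def canonical_manifest() -> FeatureManifest:
    """Return the (cached) canonical 216-feature manifest."""
    global _CANONICAL
    if _CANONICAL is None:
        _CANONICAL = FeatureManifest.canonical()
    return _CANONICAL
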