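[
"cluster:avg_path_length",
"cluster:degree_sd",
"cluster:edge_length_disorder",
"cluster:edge_length_mean",
"cluster:edge_length_sd",
"disorder:contrast_average:mean",
"disorder:contrast_energy:mean",
"disorder:contrast_entropy:mean",
"disorder:contrast_entropy:range",
"disorder:contrast_entropy:sd",
"disorder:contrast_inverse_moment:mean",
"disorder:contrast_variance:mean",
"disorder:correlation:mean",
"disorder:energy:mean",
"disorder:entropy:mean",
"disorder:intensity_variance:mean",
"graph:delaunay_area:disorder",
"graph:delaunay_area:mean",
"graph:delaunay_area:sd",
"graph:delaunay_side:mean",
"graph:knn_dist_3:disorder",
"graph:knn_dist_3:sd",
"graph:knn_dist_5:disorder",
"graph:knn_dist_5:mean",
"graph:knn_dist_5:sd",
"graph:knn_dist_7:disorder",
"graph:knn_dist_7:mean",
"graph:knn_dist_7:sd",
"graph:local_density:mean",
"graph:local_density:sd",
"graph:mst_edge:mean",
"graph:nn_count_r10:disorder",
"graph:nn_count_r10:mean",
"graph:nn_count_r20:mean",
"graph:nn_count_r30:mean",
"graph:nn_count_r30:sd",
"graph:nn_count_r40:mean",
"graph:nn_count_r40:sd",
"graph:nn_count_r50:mean",
"graph:nn_count_r50:sd",
"graph:voronoi_area:disorder",
"graph:voronoi_area:mean",
"graph:voronoi_area:minmax",
"graph:voronoi_area:sd",
"graph:voronoi_chord:disorder",
"graph:voronoi_chord:mean",
"graph:voronoi_chord:minmax",
"graph:voronoi_chord:sd",
"graph:voronoi_perimeter:disorder",
"graph:voronoi_perimeter:mean",
"graph:voronoi_perimeter:minmax",
"graph:voronoi_perimeter:sd",
"shape:fourier_descriptor_3:minmax",
"shape:fourier_descriptor_3:sd",
"shape:fourier_descriptor_7:sd",
"shape:fourier_descriptor_9:sd",
"shape:fractal_dimension:minmax",
"shape:fractal_dimension:sd",
"shape:hu_moment_1:minmax",
"shape:hu_moment_1:sd",
"shape:hu_moment_2:minmax",
"shape:hu_moment_2:sd",
"shape:minmax_radius_ratio:minmax",
"shape:minmax_radius_ratio:sd",
"shape:radial_dist_sd:minmax",
"shape:radial_dist_sd:sd",
"shape:smoothness:sd"
]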