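"""Assembly of the full 216-feature vector from a nucleus set.

``extract_all`` concatenates the four family blocks — 51 graph, 100 shape,
39 orientation-disorder, 26 cell-cluster-graph — in canonical manifest
order.  ``NucleusFeatureExtractor`` wraps the same computation as a
scikit-learn transformer over lists of nucleus sets, so feature extraction
composes with sklearn pipelines.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import disorder as _disorder
from . import shape as _shape
from . import spatial as _spatial
from .manifest import FeatureManifest, canonical_manifest
from .segmentation import NucleusSet

MIN_NUCLEI = 10


def extract_all(
    nuclei: NucleusSet,
    manifest: FeatureManifest | None = None,
    min_nuclei: int = MIN_NUCLEI,
) -> dict[str, float]:
    """Compute all 216 features of one nucleus set, keyed by manifest name.

    Requires at least ``min_nuclei`` nuclei; the limiting family
    precondition is named in the error otherwise.  Degenerate sub-features
    (e.g. empty cluster-graph blocks) are filled per the documented
    family rules, with a warning from the family module.
    """
    if manifest is None:
        manifest = canonical_manifest()
    n = len(nuclei.contours)
    if n < min_nuclei:
        raise ValueError(
            f"{n} nuclei < required {min_nuclei}: graph and disorder feature "
            "preconditions (>= 4 non-collinear centroids, >= 2 non-singleton "
            "subgraphs) are not reliably met"
        )
    graphs = _spatial.build_graphs(nuclei.centroids, nuclei.mpp)
    values = _spatial.graph_features(graphs)
    measures = [_shape.measure_nucleus(c, nuclei.mpp) for c in nuclei.contours]
    values.update(_shape.aggregate_shape(measures))
    ofield = _disorder.orientation_field(nuclei.contours, nuclei.centroids, nuclei.mpp)
    values.update(_disorder.disorder_features(ofield))
    ccg = _spatial.build_cluster_graph(nuclei.centroids, nuclei.mpp)
    values.update(_spatial.cluster_graph_features(ccg))
    missing = [name for name in manifest.names if name not in values]
    if missing:
        raise RuntimeError(f"feature blocks incomplete: missing {missing[:5]}...")
    return {name: values[name] for name in manifest.names}


class NucleusFeatureExtractor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: nucleus sets -> (n_samples, 216) matrix.

    Stateless apart from the manifest; ``fit`` validates parameters and
    records ``feature_names_out_``.
    """

    def __init__(self, min_nuclei: int = MIN_NUCLEI):
        self.min_nuclei = min_nuclei

    def fit(self, X: Iterable[NucleusSet], y=None):
        if self.min_nuclei < 4:
            raise ValueError("min_nuclei must be >= 4")
        self.manifest_ = canonical_manifest()
        self.feature_names_out_ = np.array(self.manifest_.names, dtype=object)
        return self

    def transform(self, X: Iterable[NucleusSet]) -> np.ndarray:
        if not hasattr(self, "manifest_"):
            self.fit(X)
        rows = [
            [extract_all(ns, self.manifest_, self.min_nuclei)[n] for n in self.manifest_.names]
            for ns in X
        ]
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return self.feature_names_out_

    def transform_frame(self, X: Iterable[NucleusSet]) -> pd.DataFrame:
        """Transform to a DataFrame with manifest-named columns."""
        return pd.DataFrame(self.transform(X), columns=list(self.manifest_.names))


def extract_cohort(patients, min_nuclei: int = MIN_NUCLEI) -> pd.DataFrame:
    """Feature table for a synthetic cohort: patient_id, label, 216 columns.

    ``patients`` is an iterable of objects with ``patient_id``, ``label``
    and ``ground_truth`` attributes (see :mod:`nucleoqh.synthetic`); ground
    truth contours bypass segmentation, so feature behaviour can be studied
    independent of segmentation fidelity.
    """
    manifest = canonical_manifest()
    records = []
    for p in patients:
        gt = p.ground_truth
        ns = NucleusSet(contours=gt.contours, centroids=gt.centroids, mpp=gt.mpp)
        row = {"patient_id": p.patient_id, "label": p.label}
        row.update(extract_all(ns, manifest, min_nuclei))
        records.append(row)
    return pd.DataFrame.from_records(records)
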