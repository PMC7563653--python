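"""File formats: cohort CSV, nucleus-set / ground-truth JSON, run config.

Cohort tables are CSV with columns ``patient_id, label`` followed by the
216 manifest-ordered feature columns; the manifest version is embedded as
a ``# manifest_version:`` comment on the first line.  Nucleus sets and
ground truth are JSON (contours as coordinate lists).  The run
configuration is a flat YAML mapping validated against known keys and
hashed so outputs can be traced to their parameters.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .manifest import MANIFEST_VERSION, canonical_manifest
from .segmentation import NucleusSet
from .synthetic import GroundTruth

VALID_LABELS = ("progressor", "non-progressor")


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort feature table (lossless to 12 significant digits)."""
    path = Path(path)
    manifest = canonical_manifest()
    cols = ["patient_id", "label"] + manifest.names
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing[:4]}...")
    with open(path, "w") as fh:
        fh.write(f"# manifest_version: {manifest.version}\n")
        table[cols].to_csv(fh, index=False, float_format="%.12g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort feature CSV.

    Errors name the offending row/column on label or column-count
    mismatches; a manifest version mismatch warns and maps columns by
    name where possible.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    version = None
    skip = 0
    if first.startswith("# manifest_version:"):
        version = first.split(":", 1)[1].strip()
        skip = 1
    table = pd.read_csv(path, skiprows=skip)
    manifest = canonical_manifest()
    if version is not None and version != manifest.version:
        warnings.warn(
            f"manifest version mismatch (file {version}, library {manifest.version}); "
            "mapping feature columns by name"
        )
    feature_cols = [c for c in table.columns if c not in ("patient_id", "label")]
    if set(feature_cols) != set(manifest.names):
        if len(feature_cols) != len(manifest):
            raise ValueError(
                f"feature count mismatch: expected {len(manifest)}, got {len(feature_cols)}"
            )
        unknown = sorted(set(feature_cols) - set(manifest.names))
        raise ValueError(f"unknown feature columns: {unknown[:4]}...")
    bad = ~table["label"].isin(VALID_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unknown label {table['label'].iloc[row]!r} in row {row} "
            f"(patient {table['patient_id'].iloc[row]!r})"
        )
    if table[feature_cols].isna().any().any():
        raise ValueError("cohort table contains missing feature values")
    return table[["patient_id", "label"] + manifest.names]


def write_nucleus_set(nuclei: NucleusSet, path: str | Path) -> None:
    payload = {
        "mpp": nuclei.mpp,
        "contours": [c.tolist() for c in nuclei.contours],
        "centroids": np.asarray(nuclei.centroids).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_nucleus_set(path: str | Path) -> NucleusSet:
    payload = json.loads(Path(path).read_text())
    return NucleusSet(
        contours=[np.asarray(c, dtype=float) for c in payload["contours"]],
        centroids=np.asarray(payload["centroids"], dtype=float).reshape(-1, 2),
        mpp=float(payload["mpp"]),
    )


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "mpp": gt.mpp,
        "label": gt.label,
        "contours": [c.tolist() for c in gt.contours],
        "centroids": gt.centroids.tolist(),
        "orientations_deg": gt.orientations_deg.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        contours=[np.asarray(c, dtype=float) for c in payload["contours"]],
        centroids=np.asarray(payload["centroids"], dtype=float).reshape(-1, 2),
        orientations_deg=np.asarray(payload["orientations_deg"], dtype=float),
        mpp=float(payload["mpp"]),
        label=payload.get("label"),
    )


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults."""

    mpp: float = 0.25
    # segmentation
    scales_um: tuple[float, ...] = (2.0, 4.0, 6.0)
    n_orientations: int = 6
    min_area_um2: float = 8.0
    # orientation-disorder subgraphs
    disorder_alpha: float = 0.5
    disorder_cutoff_um: float = 50.0
    disorder_bins: int = 18
    # cell cluster graph
    ccg_eps_um: float = 6.0
    ccg_alpha: float = 0.5
    ccg_cutoff_um: float = 12.0
    # selection
    n_iter: int = 30
    retention_auc: float = 0.65
    retention_scope: str = "record"
    # modeling
    cv_folds: int = 3
    cv_iterations: int = 100
    rf_trees: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scales_um" in data:
            data["scales_um"] = tuple(data["scales_um"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales_um"] = list(d["scales_um"])
        return d

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
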