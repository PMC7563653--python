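"""Shared fixtures: synthetic fields and cohorts reused across test modules.

Expensive artifacts (rendered fields, extracted cohort tables) are
session-scoped so the suite pays for each only once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import nucleoqh as nq

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def regular_polygon(radius: float, n: int = 256, center=(0.0, 0.0)) -> np.ndarray:
    """Circle approximated by a regular n-gon (pixel coordinates)."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(phi), center[1] + radius * np.sin(phi)]
    )


def ellipse_polygon(a: float, b: float, theta_deg: float = 0.0, n: int = 256, center=(0.0, 0.0)) -> np.ndarray:
    """Ellipse contour with semi-axes a, b, major axis at theta_deg."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    t = np.radians(theta_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return pts @ rot.T + np.asarray(center)


def as_nucleus_set(gt: nq.GroundTruth) -> nq.NucleusSet:
    return nq.NucleusSet(contours=gt.contours, centroids=gt.centroids, mpp=gt.mpp)


@pytest.fixture(scope="session")
def default_field() -> nq.GroundTruth:
    """The default 200-nucleus synthetic field (ground truth only)."""
    _, gt = nq.generate_nucleus_field(nq.SyntheticConfig(seed=42))
    return gt


@pytest.fixture(scope="session")
def default_features(default_field) -> dict[str, float]:
    return nq.extract_all(as_nucleus_set(default_field))


@pytest.fixture(scope="session")
def rendered_field():
    """Rendered 50-nucleus field with ground truth, for segmentation tests."""
    cfg = nq.SyntheticConfig(n_nuclei=50, field_size=(512, 512), seed=7, render=True)
    img, gt = nq.generate_nucleus_field(cfg)
    return img, gt, cfg


@pytest.fixture(scope="session")
def training_cohort():
    """60-patient (30 + 30) synthetic training cohort feature table, seed 0."""
    return nq.extract_cohort(nq.generate_cohort(30, seed=0))
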