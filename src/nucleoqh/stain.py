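"""H&E stain estimation and normalization in optical density space.

Stain vectors are estimated per image by the SVD/plane-projection approach:
tissue pixels are projected onto the plane spanned by the two leading
singular vectors of their optical densities, and the extreme-angle
directions within that plane are taken as the hematoxylin and eosin
vectors.  An image is normalized by unmixing it against its own stain
matrix, rescaling each stain's concentration so its 99th-percentile
("maximum") value matches the template's, and recomposing with the
template stain matrix.  Background (near-white) pixels carry almost no
optical density and are left near-white by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_OD_BG_THRESHOLD = 0.15  # pixels below this total OD are background
_ANGLE_PERCENTILES = (1.0, 99.0)
_MAX_OD_PERCENTILE = 99.0


class DegenerateStainError(RuntimeError):
    """Raised internally when a stain basis cannot be estimated."""


@dataclass(frozen=True)
class StainTemplate:
    """Reference stain basis: unit OD directions and per-stain OD scale."""

    stain_matrix: np.ndarray  # (3, 2): columns = hematoxylin, eosin OD directions
    max_od: np.ndarray  # (2,): 99th-percentile OD concentration per stain

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit norm")
        if np.any(self.max_od < 0):
            raise ValueError("max_od must be non-negative")


#: a standard H&E reference basis (hematoxylin, eosin OD directions)
DEFAULT_TEMPLATE = StainTemplate(
    stain_matrix=np.array(
        [[0.6443, 0.0928], [0.7167, 0.9541], [0.2668, 0.2831]]
    )
    / np.linalg.norm(
        np.array([[0.6443, 0.0928], [0.7167, 0.9541], [0.2668, 0.2831]]), axis=0
    ),
    max_od=np.array([1.0, 1.0]),
)


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """8-bit RGB to optical density, pixelwise (Beer-Lambert)."""
    arr = np.asarray(image, dtype=float)
    return -np.log10(np.clip(arr + 1.0, 1.0, 256.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Optical density back to 8-bit RGB."""
    return np.clip(np.round(256.0 * 10.0 ** (-od) - 1.0), 0, 255).astype(np.uint8)


def estimate_stains(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (stain_matrix (3,2), max_od (2,)) from an H&E RGB image.

    Raises :class:`DegenerateStainError` for blank or single-stain images
    whose OD cloud does not span a plane.
    """
    od = rgb_to_od(image).reshape(-1, 3)
    tissue = od[od.sum(axis=1) > _OD_BG_THRESHOLD]
    if len(tissue) < 64:
        raise DegenerateStainError("too few tissue pixels for stain estimation")
    cov = np.cov(tissue.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] < 1e-8 * max(evals[-1], 1e-12):
        raise DegenerateStainError("optical densities do not span a stain plane")
    basis = evecs[:, [2, 1]]  # leading plane
    # make the projection basis orientation deterministic
    for k in range(2):
        if basis[:, k].sum() < 0:
            basis[:, k] = -basis[:, k]
    proj = tissue @ basis
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, _ANGLE_PERCENTILES)
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    for v in (v1, v2):
        if v.sum() < 0:
            v *= -1
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    # hematoxylin absorbs more red light than eosin: larger R-channel OD
    if v1[0] >= v2[0]:
        stains = np.column_stack([v1, v2])
    else:
        stains = np.column_stack([v2, v1])
    conc, *_ = np.linalg.lstsq(stains, tissue.T, rcond=None)
    conc = np.clip(conc, 0.0, None)
    max_od = np.percentile(conc, _MAX_OD_PERCENTILE, axis=1)
    return stains, max_od


def normalize_stain(image: np.ndarray, template: StainTemplate = DEFAULT_TEMPLATE) -> np.ndarray:
    """Map an H&E image onto the template stain basis.

    The image is unmixed against its own estimated stain matrix; each
    stain's concentration field is scaled so its 99th-percentile matches
    the template's ``max_od``, then recomposed with the template's stain
    directions.  If the image yields a degenerate stain estimate (blank or
    single-stain input) it is returned unchanged with a warning.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image")
    try:
        stains, max_od = estimate_stains(arr)
    except DegenerateStainError as exc:
        warnings.warn(f"degenerate stain estimate ({exc}); image returned unchanged")
        return arr.copy()
    od = rgb_to_od(arr).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(stains, od.T, rcond=None)
    conc = np.clip(conc, 0.0, None)
    scale = np.where(max_od > 1e-8, template.max_od / np.maximum(max_od, 1e-8), 1.0)
    od_out = (template.stain_matrix @ (conc * scale[:, None])).T
    return od_to_rgb(od_out.reshape(arr.shape))


def hematoxylin_channel(image: np.ndarray, template: StainTemplate = DEFAULT_TEMPLATE) -> np.ndarray:
    """Hematoxylin concentration map of an (ideally normalized) image."""
    od = rgb_to_od(np.asarray(image)).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(template.stain_matrix, od.T, rcond=None)
    h = np.clip(conc[0], 0.0, None)
    return h.reshape(image.shape[:2])
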