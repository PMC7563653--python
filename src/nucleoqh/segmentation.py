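"""Nucleus detection and marker-controlled watershed segmentation.

Detection convolves the hematoxylin concentration map with a bank of
directional Gaussian second-derivative (blob/ridge) kernels — three scales
spanning the prostate-nucleus size range by six orientations — and takes
the maximum response over the bank.  Local maxima of the response inside
the region of interest, non-maximum-suppressed at the smallest filter
scale and thresholded by Otsu's rule, become nucleus seeds.

Segmentation runs a marker-controlled watershed on the gradient of the
hematoxylin channel, with the seeds as internal markers and confident
background as the external marker.  Surviving regions (above a minimum
area, not touching the image border) are turned into boundary polygons and
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve as _fftconvolve
from skimage.feature import peak_local_max
from skimage.filters import sobel, threshold_otsu
from skimage.measure import find_contours
from skimage.segmentation import watershed

from .shape import polygon_area_centroid
from .stain import StainTemplate, DEFAULT_TEMPLATE, hematoxylin_channel

DEFAULT_SCALES_UM = (2.0, 4.0, 6.0)  # equivalent nucleus radii covered
N_ORIENTATIONS = 6
MIN_AREA_UM2 = 8.0


@dataclass
class NucleusSet:
    """Segmented (or ground-truth) nuclei of one region of interest."""

    contours: list[np.ndarray]  # closed pixel-coordinate polygons
    centroids: np.ndarray  # (n, 2) pixel coordinates
    mpp: float
    roi_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.contours)


def _directional_log_kernel(sigma: float, elongation: float, theta: float) -> np.ndarray:
    """Negated second derivative of an anisotropic Gaussian along its short axis.

    Responds maximally to dark..bright ridge/blob structure of width
    ~2*sigma oriented at ``theta``.
    """
    half = int(np.ceil(3.0 * sigma * max(1.0, elongation)))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    c, s = np.cos(theta), np.sin(theta)
    u = c * x + s * y  # along the long axis
    v = -s * x + c * y  # across
    su = sigma * elongation
    g = np.exp(-(u**2) / (2 * su**2) - (v**2) / (2 * sigma**2))
    kern = -((v**2) / sigma**4 - 1.0 / sigma**2) * g  # positive at blob center
    kern -= kern.mean()
    norm = np.sqrt((kern**2).sum())
    return kern / norm


def filter_bank_response(
    h_channel: np.ndarray,
    mpp: float,
    scales_um: tuple[float, ...] = DEFAULT_SCALES_UM,
    n_orientations: int = N_ORIENTATIONS,
) -> np.ndarray:
    """Maximum response over the directional Gaussian-derivative bank."""
    response = np.full(h_channel.shape, -np.inf)
    for scale_um in scales_um:
        sigma_px = max(1.0, (scale_um / mpp) / 2.0)
        for k in range(n_orientations):
            theta = np.pi * k / n_orientations
            kern = _directional_log_kernel(sigma_px, 1.6, theta)
            resp = _fftconvolve(h_channel, kern, mode="same")
            response = np.maximum(response, resp)
    return response


def detect_nuclei(
    image: np.ndarray,
    roi_mask: np.ndarray | None = None,
    mpp: float = 0.25,
    scales_um: tuple[float, ...] = DEFAULT_SCALES_UM,
    n_orientations: int = N_ORIENTATIONS,
    template: StainTemplate = DEFAULT_TEMPLATE,
) -> np.ndarray:
    """Seed points (one per detected nucleus) as an (n, 2) x/y pixel array.

    Seeds are non-maximum-suppressed local maxima of the bank response,
    thresholded by Otsu's rule on the in-ROI response; seeds outside the
    ROI are discarded.  An empty ROI yields an empty array.
    """
    if roi_mask is None:
        roi_mask = np.ones(image.shape[:2], dtype=bool)
    roi_mask = roi_mask.astype(bool)
    if not roi_mask.any():
        return np.empty((0, 2))
    h = hematoxylin_channel(image, template)
    response = filter_bank_response(h, mpp, scales_um, n_orientations)
    vals = response[roi_mask]
    if float(vals.max() - vals.min()) <= 1e-12:
        return np.empty((0, 2))
    thr = threshold_otsu(vals)
    min_dist = max(2, int(round(min(scales_um) / mpp / 2.0)))
    peaks = peak_local_max(
        response, min_distance=min_dist, threshold_abs=thr, labels=roi_mask
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    return peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)


def segment_nuclei(
    image: np.ndarray,
    seeds: np.ndarray,
    roi_mask: np.ndarray | None = None,
    mpp: float = 0.25,
    min_area_um2: float = MIN_AREA_UM2,
    template: StainTemplate = DEFAULT_TEMPLATE,
) -> NucleusSet:
    """Marker-controlled watershed segmentation from detection seeds.

    The relief is the Sobel gradient of the hematoxylin channel; seeds are
    internal markers and confident background (hematoxylin below Otsu's
    threshold, away from seeds) is the external marker.  Regions smaller
    than ``min_area_um2`` or touching the image border are dropped.  Each
    surviving region contributes its boundary polygon and the polygon
    centroid.
    """
    if roi_mask is None:
        roi_mask = np.ones(image.shape[:2], dtype=bool)
    roi_mask = roi_mask.astype(bool)
    if len(seeds) == 0:
        return NucleusSet(contours=[], centroids=np.empty((0, 2)), mpp=mpp, roi_mask=roi_mask)
    h = hematoxylin_channel(image, template)
    relief = sobel(h)
    markers = np.zeros(h.shape, dtype=np.int32)
    for i, (x, y) in enumerate(np.asarray(seeds), start=1):
        markers[int(round(y)), int(round(x))] = i
    bg_thr = threshold_otsu(h[roi_mask]) if roi_mask.any() else threshold_otsu(h)
    background = h < bg_thr
    # keep background marker clear of the seeds
    near_seed = ndi.binary_dilation(markers > 0, iterations=3)
    background &= ~near_seed
    labels = watershed(relief, markers=markers + np.where(background, len(seeds) + 1, 0))
    labels[labels == len(seeds) + 1] = 0
    contours: list[np.ndarray] = []
    centroids: list[np.ndarray] = []
    min_area_px = min_area_um2 / (mpp * mpp)
    for lab in range(1, len(seeds) + 1):
        mask = labels == lab
        if mask.sum() < min_area_px:
            continue
        rows, cols = np.nonzero(mask)
        if (
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == mask.shape[0] - 1
            or cols.max() == mask.shape[1] - 1
        ):
            continue
        found = find_contours(mask.astype(float), 0.5)
        if not found:
            continue
        boundary = max(found, key=len)[:, ::-1]  # (row, col) -> (x, y)
        if len(boundary) < 8:
            continue
        try:
            _, centroid = polygon_area_centroid(boundary)
        except ValueError:
            continue
        if not roi_mask[int(round(centroid[1])), int(round(centroid[0]))]:
            continue
        contours.append(boundary)
        centroids.append(centroid)
    return NucleusSet(
        contours=contours,
        centroids=np.array(centroids).reshape(-1, 2),
        mpp=mpp,
        roi_mask=roi_mask,
    )


def segment_image(
    image: np.ndarray,
    roi_mask: np.ndarray | None = None,
    mpp: float = 0.25,
    template: StainTemplate = DEFAULT_TEMPLATE,
) -> NucleusSet:
    """Full segmentation pipeline: normalize, detect, watershed."""
    from .stain import normalize_stain

    norm = normalize_stain(image, template)
    seeds = detect_nuclei(norm, roi_mask, mpp=mpp, template=template)
    return segment_nuclei(norm, seeds, roi_mask, mpp=mpp, template=template)
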