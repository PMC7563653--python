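"""Per-nucleus shape measures and their cohort-level aggregation.

Each nucleus contour is resampled to 128 equal-arclength points and 25
measures are computed on the resampled polygon: area, perimeter, three
radial-distance statistics, min/max radius ratio, boundary smoothness,
box-counting fractal dimension, the seven Hu invariant moments and ten
normalized Fourier descriptors.  Aggregating each measure over the nuclei of
a region with mean, median, sample SD and min/max ratio yields the
100-feature shape block.

Hu moments are computed from exact polygon moment integrals (Green's
theorem over a triangle fan) rather than from a rasterization, so the
rotation/translation invariance of the moments holds to floating-point
accuracy on the resampled contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .manifest import SHAPE_MEASURES

N_RESAMPLE = 128  # equal-arclength contour points used for every measure


class DegenerateContourError(ValueError):
    """Raised for zero-area or otherwise invalid nucleus contours."""


@dataclass(frozen=True)
class ShapeMeasures:
    """The 25 canonical per-nucleus measures, keyed as in the manifest."""

    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def resample_contour(contour: np.ndarray, n: int = N_RESAMPLE) -> np.ndarray:
    """Resample a closed polygon to ``n`` equal-arclength vertices.

    The input is an (m, 2) array of vertices; the closing edge from the last
    vertex back to the first is implied.  The first output vertex coincides
    with the first input vertex, making resampling commute exactly with
    rigid motions of the input.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateContourError("contour must be an (m>=3, 2) vertex array")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise DegenerateContourError("zero-perimeter contour")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


def polygon_area_centroid(poly: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed shoelace area and area centroid of a closed polygon."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if a == 0:
        raise DegenerateContourError("zero-area contour")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return a, np.array([cx, cy])


def polygon_moments(poly: np.ndarray, order: int = 3) -> np.ndarray:
    """Exact raw geometric moments m_pq = iint x^p y^q dA over a polygon.

    Integrates over the signed triangle fan (origin, v_i, v_{i+1}) using the
    closed form for monomials on the unit simplex:
    integral u^a v^b du dv = a! b! / (a + b + 2)!.
    Returns an (order+1, order+1) array indexed [p, q]; entries with
    p + q > order are zero.  Sign follows vertex orientation.
    """
    v1 = np.asarray(poly, dtype=float)
    v2 = np.roll(v1, -1, axis=0)
    jac = v1[:, 0] * v2[:, 1] - v2[:, 0] * v1[:, 1]  # per-triangle 2*area
    m = np.zeros((order + 1, order + 1))
    fact = [math.factorial(i) for i in range(2 * order + 3)]
    for p in range(order + 1):
        for q in range(order + 1 - p):
            acc = np.zeros(len(v1))
            for k in range(p + 1):
                for l in range(q + 1):
                    a = k + l
                    b = (p - k) + (q - l)
                    simplex = fact[a] * fact[b] / fact[a + b + 2]
                    acc += (
                        math.comb(p, k)
                        * math.comb(q, l)
                        * v1[:, 0] ** k
                        * v2[:, 0] ** (p - k)
                        * v1[:, 1] ** l
                        * v2[:, 1] ** (q - l)
                        * simplex
                    )
            m[p, q] = float((jac * acc).sum())
    return m


def hu_moments(poly: np.ndarray) -> np.ndarray:
    """Seven Hu invariant moments of the polygon interior (exact integrals)."""
    m = polygon_moments(poly, order=3)
    m00 = m[0, 0]
    if m00 == 0:
        raise DegenerateContourError("zero-area contour")
    if m00 < 0:  # orientation only flips the sign of every integral
        m = -m
        m00 = -m00
    cx, cy = m[1, 0] / m00, m[0, 1] / m00
    # central moments via binomial shift
    mu = np.zeros((4, 4))
    for p in range(4):
        for q in range(4 - p):
            s = 0.0
            for k in range(p + 1):
                for l in range(q + 1):
                    s += (
                        math.comb(p, k)
                        * math.comb(q, l)
                        * (-cx) ** (p - k)
                        * (-cy) ** (q - l)
                        * m[k, l]
                    )
            mu[p, q] = s
    eta = np.zeros((4, 4))
    for p in range(4):
        for q in range(4 - p):
            if p + q >= 2:
                eta[p, q] = mu[p, q] / m00 ** (1 + (p + q) / 2.0)
    n20, n02, n11 = eta[2, 0], eta[0, 2], eta[1, 1]
    n30, n03, n21, n12 = eta[3, 0], eta[0, 3], eta[2, 1], eta[1, 2]
    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2) + (
        3 * n21 - n03
    ) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (n30 + n12) * (
        n21 + n03
    )
    h7 = (3 * n21 - n03) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2) - (
        n30 - 3 * n12
    ) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def fourier_descriptors(poly: np.ndarray, n_desc: int = 10) -> np.ndarray:
    """Normalized harmonic magnitudes |Z_k| / |Z_1| for k = 1..n_desc.

    The resampled contour is treated as a complex sequence; the DC term
    removes translation and dividing by the first harmonic removes scale,
    so the descriptors are similarity-invariant.  Descriptor 1 is 1 by
    construction.
    """
    z = poly[:, 0] + 1j * poly[:, 1]
    coeff = np.fft.fft(z) / len(z)
    mags = np.abs(coeff)
    if mags[1] == 0:
        raise DegenerateContourError("degenerate contour: vanishing first harmonic")
    return mags[1 : n_desc + 1] / mags[1]


def _box_counts(points: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    lo = points.min(axis=0)
    span = float((points.max(axis=0) - lo).max())
    if span <= 0:
        raise DegenerateContourError("degenerate contour extent")
    unit = (points - lo) / span
    counts = []
    for s in sizes:
        # symmetric shapes put points exactly on cell boundaries; snap to a
        # 1e-6 grid first so the floor is stable against pose round-off
        q = np.round(unit / s, 6) + 1e-9
        cells = np.floor(q).astype(np.int64)
        keys = cells[:, 0] * (int(1.0 / s) + 2) + cells[:, 1]  # 1-D cell key
        counts.append(len(np.unique(keys)))
    return np.array(counts)


def fractal_dimension(poly: np.ndarray) -> float:
    """Box-counting dimension of the contour curve.

    The polyline is densely sampled, brought into a canonical frame
    (centroid at the origin, principal axis of the dense points along x)
    so the estimate does not depend on the pose of the input, normalized
    to a unit box, and covered with grids of size 2^-k; the dimension is
    the least-squares slope of log(count) vs log(1/size).  The principal
    axis leaves a 180-degree ambiguity, resolved by taking the per-scale
    minimum count over the two flips.  Deterministic; ~1 for smooth
    contours.
    """
    dense = resample_contour(poly, 2048)
    centered = dense - dense.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    c, s = axis[0], axis[1]
    canon = centered @ np.array([[c, -s], [s, c]])
    sizes = 2.0 ** -np.arange(2, 7)  # 1/4 .. 1/64
    counts = np.minimum(_box_counts(canon, sizes), _box_counts(-canon, sizes))
    slope = np.polyfit(np.log(1.0 / sizes), np.log(counts), 1)[0]
    return float(slope)


def measure_nucleus(contour: np.ndarray, mpp: float) -> ShapeMeasures:
    """Compute the 25 canonical shape measures for one nucleus contour.

    ``contour`` is a simple closed polygon in pixel coordinates with at
    least 8 vertices; ``mpp`` converts pixel lengths to microns.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 8:
        raise DegenerateContourError("contour needs >= 8 vertices")
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    poly = resample_contour(pts) * mpp  # all measures in micron units
    area, centroid = polygon_area_centroid(poly)
    area = abs(area)
    closed = np.vstack([poly, poly[:1]])
    perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    r = np.linalg.norm(poly - centroid, axis=1)
    r_max = float(r.max())
    r_mean = float(r.mean())
    r_sd = float(r.std(ddof=1))
    minmax_radius = float(r.min() / r.max())
    # local roughness of the radial profile, normalized by mean radius so the
    # measure is scale-free
    rough = np.abs(r - 0.5 * (np.roll(r, 1) + np.roll(r, -1)))
    smooth = float(rough.mean() / r_mean)
    vals = {
        "area": area,
        "perimeter": perimeter,
        "radial_dist_max": r_max,
        "radial_dist_mean": r_mean,
        "radial_dist_sd": r_sd,
        "minmax_radius_ratio": minmax_radius,
        "smoothness": smooth,
        "fractal_dimension": fractal_dimension(poly),
    }
    for i, h in enumerate(hu_moments(poly), start=1):
        vals[f"hu_moment_{i}"] = float(h)
    for i, f in enumerate(fourier_descriptors(poly), start=1):
        vals[f"fourier_descriptor_{i}"] = float(f)
    return ShapeMeasures(values=vals)


def _minmax_ratio(x: np.ndarray) -> float:
    """min/max ratio with the degenerate all-zero case defined as 1."""
    mx = float(np.max(np.abs(x)))
    if mx == 0:
        return 1.0
    return float(np.min(x) / np.max(x))


def aggregate_shape(measures: list[ShapeMeasures]) -> dict[str, float]:
    """Aggregate per-nucleus measures into the 100-value shape block.

    For each of the 25 measures: mean, median, sample SD and min/max ratio
    over nuclei, in manifest order.  Requires at least 2 nuclei (SD).
    """
    if len(measures) < 2:
        raise ValueError("aggregate_shape requires >= 2 nuclei (SD undefined)")
    out: dict[str, float] = {}
    for name in SHAPE_MEASURES:
        x = np.array([m[name] for m in measures], dtype=float)
        out[f"shape:{name}:mean"] = float(x.mean())
        out[f"shape:{name}:median"] = float(np.median(x))
        out[f"shape:{name}:sd"] = float(x.std(ddof=1))
        out[f"shape:{name}:minmax"] = _minmax_ratio(x)
    return out
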