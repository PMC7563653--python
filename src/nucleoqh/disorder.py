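"""Nuclear orientation-disorder features.

Each nucleus gets an axial orientation in [0, 180) degrees from the first
principal component of its boundary points.  Local subgraphs of the
centroid cloud are formed by a deterministic distance-decay rule
(d^(-alpha) >= threshold, equivalent to a hard cutoff radius).  Within each
subgraph the orientations are quantized into B equal bins and a symmetric,
normalized co-occurrence matrix is accumulated over all within-subgraph
pairs; 13 second-order statistics (contrast, intensity and entropy/energy
families plus correlation measures) are computed per subgraph and
aggregated across subgraphs by mean, SD and range, giving the 39-feature
disorder block.

Entropies are in bits.  Contrast-family statistics depend only on bin
differences, i.e. on the quantized relative orientation of nucleus pairs,
which makes them insensitive to a global rotation of the field (up to
bin-edge effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .manifest import DISORDER_MEASURES

N_BINS = 18  # 10-degree axial orientation bins over [0, 180)
DECAY_ALPHA = 0.5
DECAY_CUTOFF_UM = 50.0
_CIRCLE_ECC_RATIO = 1.05  # eigenvalue ratio below which orientation is degenerate


def decay_threshold(cutoff_um: float = DECAY_CUTOFF_UM, alpha: float = DECAY_ALPHA) -> float:
    """Threshold on d^(-alpha) equivalent to a hard cutoff distance."""
    return cutoff_um ** (-alpha)


@dataclass
class OrientationField:
    """Per-nucleus axial orientations plus local subgraph membership."""

    angles_deg: np.ndarray  # in [0, 180)
    degenerate: np.ndarray  # circular contours flagged, angle set to 0
    subgraphs: list[np.ndarray]  # per-nucleus: indices of self + neighbors


def nucleus_orientation(contour: np.ndarray) -> tuple[float, bool]:
    """Axial orientation of a nucleus from its boundary points.

    Returns (angle in degrees within [0, 180), degenerate flag).  The angle
    is that of the dominant eigenvector of the boundary-point covariance;
    near-circular contours (eigenvalue ratio < 1.05) get angle 0 with the
    degeneracy flag set.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 8:
        raise ValueError("contour needs >= 8 points for orientation")
    c = pts - pts.mean(axis=0)
    cov = np.cov(c.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or evals[1] / max(evals[0], 1e-300) < _CIRCLE_ECC_RATIO:
        return 0.0, True
    v = evecs[:, 1]
    ang = np.degrees(np.arctan2(v[1], v[0])) % 180.0
    return float(ang), False


def axial_difference(a_deg: float | np.ndarray, b_deg: float | np.ndarray) -> np.ndarray:
    """Smallest angle between two axial orientations, in [0, 90]."""
    d = np.abs(np.asarray(a_deg) - np.asarray(b_deg)) % 180.0
    return np.minimum(d, 180.0 - d)


def build_subgraphs(
    centroids: np.ndarray,
    mpp: float,
    alpha: float = DECAY_ALPHA,
    threshold: float | None = None,
) -> list[np.ndarray]:
    """Local subgraph membership by the deterministic decay rule.

    j belongs to i's subgraph iff d(i, j)^(-alpha) >= threshold; the
    subgraph of i is i plus its neighbors.  Isolated nuclei yield singleton
    subgraphs.
    """
    pts = np.asarray(centroids, dtype=float) * float(mpp)
    if len(pts) < 2:
        raise ValueError("build_subgraphs requires >= 2 centroids")
    if threshold is None:
        threshold = decay_threshold()
    cutoff = threshold ** (-1.0 / alpha)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, cutoff)
    return [np.array(sorted(nb), dtype=int) for nb in neighbors]


def cooccurrence_matrix(angles_deg: np.ndarray, members: np.ndarray, bins: int = N_BINS) -> np.ndarray | None:
    """Symmetric normalized orientation co-occurrence matrix of one subgraph.

    Every unordered pair of distinct member nuclei contributes to cells
    (bin_a, bin_b) and (bin_b, bin_a) with equal weight; the matrix sums to
    one.  Returns None for singleton subgraphs (no pairs).
    """
    m = len(members)
    if m < 2:
        return None
    b = np.floor(angles_deg[members] / (180.0 / bins)).astype(int)
    b = np.clip(b, 0, bins - 1)
    mat = np.zeros((bins, bins))
    iu, ju = np.triu_indices(m, k=1)
    np.add.at(mat, (b[iu], b[ju]), 1.0)
    np.add.at(mat, (b[ju], b[iu]), 1.0)
    return mat / mat.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def cooccurrence_statistics(p: np.ndarray) -> dict[str, float]:
    """The 13 second-order statistics of one normalized co-occurrence matrix.

    Contrast-family measures use the distribution of axial bin distances
    min(|i - j|, B - |i - j|) — orientation is axial, so the first and last
    bins are adjacent; intensity-family measures use the distribution of
    bin sums i + j.  Correlation is 0 by convention when either marginal is
    degenerate.
    """
    b = p.shape[0]
    idx = np.arange(b, dtype=float)
    i_grid, j_grid = np.meshgrid(idx, idx, indexing="ij")
    # axial bin distance: bins 0 and B-1 are 1 bin apart, not B-1
    raw = np.abs(i_grid - j_grid).astype(int)
    diff = np.minimum(raw, b - raw)
    summ = (i_grid + j_grid).astype(int)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel(), minlength=b)
    p_sum = np.bincount(summ.ravel(), weights=p.ravel(), minlength=2 * b - 1)
    k_diff = np.arange(len(p_diff), dtype=float)
    k_sum = np.arange(len(p_sum), dtype=float)

    contrast_avg = float((k_diff * p_diff).sum())
    intensity_avg = float((k_sum * p_sum).sum())
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx, my = float((idx * px).sum()), float((idx * py).sum())
    sx = float(np.sqrt(((idx - mx) ** 2 * px).sum()))
    sy = float(np.sqrt(((idx - my) ** 2 * py).sum()))
    if sx > 0 and sy > 0:
        corr = float(((i_grid - mx) * (j_grid - my) * p).sum() / (sx * sy))
    else:
        corr = 0.0
    hxy = _entropy_bits(p.ravel())
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    outer = np.outer(px, py)
    mask = (p > 0) & (outer > 0)
    hxy1 = float(-(p[mask] * np.log2(outer[mask])).sum())
    mask2 = outer > 0
    hxy2 = float(-(outer[mask2] * np.log2(outer[mask2])).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    arg = max(0.0, 1.0 - np.exp(-2.0 * np.log(2.0) * (hxy2 - hxy)))
    imc2 = float(np.sqrt(arg))
    return {
        "contrast_energy": float((diff.astype(float) ** 2 * p).sum()),
        "contrast_inverse_moment": float((p / (1.0 + diff.astype(float) ** 2)).sum()),
        "contrast_average": contrast_avg,
        "contrast_variance": float(((k_diff - contrast_avg) ** 2 * p_diff).sum()),
        "contrast_entropy": _entropy_bits(p_diff),
        "intensity_average": intensity_avg,
        "intensity_variance": float(((k_sum - intensity_avg) ** 2 * p_sum).sum()),
        "intensity_entropy": _entropy_bits(p_sum),
        "entropy": hxy,
        "energy": float((p**2).sum()),
        "correlation": corr,
        "info_measure_corr_1": float(imc1),
        "info_measure_corr_2": imc2,
    }


def orientation_field(
    contours: list[np.ndarray],
    centroids: np.ndarray,
    mpp: float,
    alpha: float = DECAY_ALPHA,
    threshold: float | None = None,
) -> OrientationField:
    """Per-nucleus orientations plus decay-rule subgraph membership."""
    angles = np.empty(len(contours))
    degen = np.zeros(len(contours), dtype=bool)
    for i, c in enumerate(contours):
        angles[i], degen[i] = nucleus_orientation(c)
    subs = build_subgraphs(centroids, mpp, alpha=alpha, threshold=threshold)
    return OrientationField(angles_deg=angles, degenerate=degen, subgraphs=subs)


def disorder_features(field: OrientationField, bins: int = N_BINS) -> dict[str, float]:
    """The 39-value disorder block: 13 statistics x {mean, SD, range}.

    Statistics are computed per non-singleton subgraph and aggregated
    across subgraphs.  Raises if every subgraph is a singleton.
    """
    per_stat: dict[str, list[float]] = {m: [] for m in DISORDER_MEASURES}
    n_used = 0
    for members in field.subgraphs:
        mat = cooccurrence_matrix(field.angles_deg, members, bins=bins)
        if mat is None:
            continue
        n_used += 1
        for k, v in cooccurrence_statistics(mat).items():
            per_stat[k].append(v)
    if n_used == 0:
        raise ValueError("no co-occurring pairs: all subgraphs are singletons")
    out: dict[str, float] = {}
    for name in DISORDER_MEASURES:
        x = np.array(per_stat[name])
        out[f"disorder:{name}:mean"] = float(x.mean())
        out[f"disorder:{name}:sd"] = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        out[f"disorder:{name}:range"] = float(x.max() - x.min())
    return out
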