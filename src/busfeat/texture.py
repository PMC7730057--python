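"""GLCM texture features of the tumor ROI.

The ROI (tumor plus surrounding tissue) is quantized to G gray levels
and co-occurrence matrices are accumulated at 10 distances (1..10 px)
and 4 orientations (0, 45, 90, 135 degrees), giving 40 GLCMs.  Each
symmetric, normalized GLCM yields 20 statistics from the
Haralick/Soh/Clausi families, for 800 texture features per image.

Orientation convention (row, col) displacement for distance d:

====  ============
 0      (0, +d)
 45     (-d, +d)
 90     (-d, 0)
 135    (-d, -d)
====  ============

GLCMs are symmetrized (transpose added) and normalized to probabilities.
Statistic formulas use 1-based gray-level indices i, j in 1..G, the
convention of the Matlab-lineage feature codes common in this
literature; entropy-family statistics use the natural logarithm with the
0*log(0) = 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deep_features import FeatureSet, l2_normalize

__all__ = [
    "GlcmParams",
    "Glcm",
    "quantize",
    "compute_glcm",
    "glcm_statistics",
    "texture_feature_set",
    "STATISTIC_NAMES",
]

STATISTIC_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "sum_of_squares",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GlcmParams:
    """Co-occurrence parameters: pixel distances, orientations, gray levels."""

    distances: tuple[int, ...] = tuple(range(1, 11))
    angles: tuple[int, ...] = (0, 45, 90, 135)
    gray_levels: int = 32
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        if any(a not in _OFFSETS for a in self.angles):
            raise ValueError(f"angles must be in {sorted(_OFFSETS)}")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")


@dataclass
class Glcm:
    matrix: np.ndarray
    distance: int
    angle: int
    params: GlcmParams


def quantize(pixels: np.ndarray, gray_levels: int) -> np.ndarray:
    """Linear min-max rescale of the ROI, floored into ``gray_levels`` bins.

    A constant image maps to bin 0.
    """
    if gray_levels < 2:
        raise ValueError("gray_levels must be >= 2")
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.intp)
    q = np.floor((pixels - lo) / (hi - lo) * gray_levels).astype(np.intp)
    return np.minimum(q, gray_levels - 1)


def compute_glcm(
    quantized: np.ndarray,
    distance: int,
    angle: int,
    gray_levels: int | None = None,
    symmetric: bool = True,
    normalized: bool = True,
) -> Glcm:
    """Accumulate the co-occurrence matrix at one displacement.

    Pairs are counted at the (row, col) offset of the orientation table
    above, the transpose is added when ``symmetric``, and the counts are
    normalized to probabilities when ``normalized``.
    """
    q = np.asarray(quantized)
    if gray_levels is None:
        gray_levels = int(q.max()) + 1
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(
            f"image {q.shape} too small for distance {distance} at {angle} degrees"
        )
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = q[r0, c0].ravel()
    b = q[r1, c1].ravel()
    counts = np.zeros((gray_levels, gray_levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    if normalized:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    params = GlcmParams(
        distances=(distance,), angles=(angle,), gray_levels=gray_levels,
        symmetric=symmetric, normalized=normalized,
    )
    return Glcm(matrix=counts, distance=distance, angle=angle, params=params)


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def glcm_statistics(glcm: Glcm | np.ndarray) -> dict[str, float]:
    """The 20 texture statistics of a normalized GLCM, in fixed order.

    Gray-level indices are 1-based.  ``sum_of_squares`` (variance) uses
    the GLCM row mean mu_x as its center (the matrix is symmetric, so
    mu_x = mu_y); ``sum_variance`` is the variance of the diagonal-sum
    distribution about ``sum_average``.
    """
    p = np.asarray(glcm.matrix if isinstance(glcm, Glcm) else glcm, dtype=float)
    g = p.shape[0]
    i = np.arange(1, g + 1)
    I, J = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # p_{x+y}(k), k = 2..2G and p_{x-y}(k), k = 0..G-1
    sums = I + J
    diffs = np.abs(I - J)
    p_sum = np.array([p[sums == k].sum() for k in range(2, 2 * g + 1)])
    k_sum = np.arange(2, 2 * g + 1)
    p_diff = np.array([p[diffs == k].sum() for k in range(g)])
    k_diff = np.arange(g)

    autocorrelation = float(np.sum(I * J * p))
    contrast = float(np.sum((I - J) ** 2 * p))
    if sd_x > 0 and sd_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    cluster_prominence = float(np.sum((I + J - mu_x - mu_y) ** 4 * p))
    cluster_shade = float(np.sum((I + J - mu_x - mu_y) ** 3 * p))
    dissimilarity = float(np.sum(np.abs(I - J) * p))
    energy = float(np.sum(p**2))
    entropy = float(-np.sum(_xlogx(p)))
    homogeneity = float(np.sum(p / (1.0 + (I - J) ** 2)))
    maximum_probability = float(p.max())
    sum_of_squares = float(np.sum((I - mu_x) ** 2 * p))
    sum_average = float(np.sum(k_sum * p_sum))
    sum_entropy = float(-np.sum(_xlogx(p_sum)))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * p_sum))
    mu_diff = float(np.sum(k_diff * p_diff))
    difference_variance = float(np.sum((k_diff - mu_diff) ** 2 * p_diff))
    difference_entropy = float(-np.sum(_xlogx(p_diff)))

    hx = float(-np.sum(_xlogx(px)))
    hy = float(-np.sum(_xlogx(py)))
    outer = np.outer(px, py)
    mask = outer > 0
    hxy1 = float(-np.sum(p[mask] * np.log(outer[mask])))
    hxy2 = float(-np.sum(_xlogx(outer)))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    inverse_difference_normalized = float(np.sum(p / (1.0 + np.abs(I - J) / g)))
    inverse_difference_moment_normalized = float(np.sum(p / (1.0 + (I - J) ** 2 / g**2)))

    values = (
        autocorrelation, contrast, correlation, cluster_prominence, cluster_shade,
        dissimilarity, energy, entropy, homogeneity, maximum_probability,
        sum_of_squares, sum_average, sum_entropy, sum_variance,
        difference_variance, difference_entropy, imc1, imc2,
        inverse_difference_normalized, inverse_difference_moment_normalized,
    )
    return dict(zip(STATISTIC_NAMES, values))


def texture_glcms(roi_pixels: np.ndarray, params: GlcmParams | None = None) -> list[Glcm]:
    """All GLCMs of the parameter grid, ordered (distance asc, angle asc)."""
    params = params or GlcmParams()
    q = quantize(roi_pixels, params.gray_levels)
    return [
        compute_glcm(q, d, a, params.gray_levels, params.symmetric, params.normalized)
        for d in params.distances
        for a in params.angles
    ]


def texture_feature_set(
    roi_pixels: np.ndarray,
    params: GlcmParams | None = None,
    normalize: bool = True,
) -> FeatureSet:
    """The texture feature vector of one ROI.

    Default parameters give 10 distances x 4 angles x 20 statistics =
    800 features, named ``texture:d<d>:a<angle>:<statistic>`` and
    ordered (distance asc, angle asc, statistic order).  The set is
    l2-normalized when used standalone (``normalize=True``).
    """
    params = params or GlcmParams()
    values: list[float] = []
    names: list[str] = []
    for glcm in texture_glcms(roi_pixels, params):
        stats = glcm_statistics(glcm)
        for stat in STATISTIC_NAMES:
            values.append(stats[stat])
            names.append(f"texture:d{glcm.distance}:a{glcm.angle}:{stat}")
    arr = np.asarray(values, dtype=float)
    flag = False
    if normalize:
        arr, flag = l2_normalize(arr)
    return FeatureSet(values=arr, names=names, level_tag="texture", zero_norm=flag)
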