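"""Morphological features of the tumor outline.

Eighteen shape descriptors are computed from the binary tumor mask:
ten directly from the outline (area, perimeter, form factor, roundness,
aspect ratio, convexity, solidity, extent, undulation, compactness),
two from the normalized radial length (NRL) profile (entropy, variance),
and six from the best-fit ellipse (major/minor axis lengths, axis ratio,
ellipse/tumor perimeter ratio, orientation angle, ellipse-tumor overlap).

Benign breast lesions tend toward smooth, elliptical outlines (form
factor and solidity near 1, low NRL variance); malignant lesions are
irregular and spiculated (low form factor, undulating boundaries, high
NRL variance), which is what these features quantify.

Conventions
-----------
* Boundary: sub-pixel contour from marching squares; perimeter is its
  polygon arc length.  Area is the foreground pixel count.
* Roundness uses the maximum Feret diameter in its denominator.
* Aspect ratio is bounding-box height/width, reported >= 1.
* Undulation: number of concave excursions — maximal boundary runs lying
  more than 1 px inside the convex hull — divided by the number of
  boundary samples.
* NRL entropy: Shannon entropy (natural log) of a 10-bin histogram on
  (0, 1]; NRL variance with ddof=0.
* Best-fit ellipse from second-order central moments of the mask (the
  ellipse with the same normalized moments); angle of the major axis
  measured from the image x-axis (columns), in [0, 180) degrees.
* Lengths/areas are in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from shapely.geometry import Point, Polygon
from skimage import measure

from .deep_features import FeatureSet, l2_normalize

__all__ = [
    "ContourGeometry",
    "NrlProfile",
    "EllipseFit",
    "contour_geometry",
    "nrl_profile",
    "nrl_statistics",
    "fit_ellipse",
    "morphology_feature_set",
    "MORPHOLOGY_FEATURE_NAMES",
]

MORPHOLOGY_FEATURE_NAMES = (
    "area",
    "perimeter",
    "form_factor",
    "roundness",
    "aspect_ratio",
    "convexity",
    "solidity",
    "extent",
    "undulation",
    "compactness",
    "nrl_entropy",
    "nrl_variance",
    "ellipse_major_axis",
    "ellipse_minor_axis",
    "ellipse_axis_ratio",
    "ellipse_perimeter_ratio",
    "ellipse_angle",
    "ellipse_overlap",
)

NRL_HISTOGRAM_BINS = 10


@dataclass
class ContourGeometry:
    boundary: np.ndarray  # closed (n, 2) array of (row, col) sub-pixel points
    centroid: tuple[float, float]
    area: float
    perimeter: float
    hull: np.ndarray  # (m, 2) hull vertices (row, col)
    hull_area: float
    hull_perimeter: float
    bbox: tuple[int, int, int, int]  # rmin, rmax, cmin, cmax inclusive


@dataclass
class NrlProfile:
    values: np.ndarray  # normalized radial lengths in (0, 1], max == 1


@dataclass
class EllipseFit:
    center: tuple[float, float]  # (row, col)
    a: float  # semi-major
    b: float  # semi-minor
    angle_deg: float  # major-axis angle from the x (column) axis, [0, 180)


def _closed_polyline_length(points: np.ndarray) -> float:
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def contour_geometry(mask: np.ndarray) -> ContourGeometry:
    """Trace the outline and measure area, perimeter, hull, bounding box."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    labeled, n = ndimage.label(mask)
    if n > 1:
        raise ValueError(f"mask has {n} connected components; expected 1")
    # pad so contours of blobs touching the border still close
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    boundary = max(contours, key=len) - 1.0  # undo pad offset
    if len(boundary) >= 8:
        # light circular smoothing removes the marching-squares staircase,
        # which otherwise inflates perimeters by ~5%
        boundary = np.column_stack(
            [
                ndimage.uniform_filter1d(boundary[:, 0], 5, mode="wrap"),
                ndimage.uniform_filter1d(boundary[:, 1], 5, mode="wrap"),
            ]
        )
    rows, cols = np.nonzero(mask)
    area = float(mask.sum())
    centroid = (float(rows.mean()), float(cols.mean()))
    perimeter = _closed_polyline_length(boundary)
    hull = ConvexHull(boundary)
    hull_pts = boundary[hull.vertices]
    # qhull 2-D: volume = area, area = perimeter
    return ContourGeometry(
        boundary=boundary,
        centroid=centroid,
        area=area,
        perimeter=perimeter,
        hull=hull_pts,
        hull_area=float(hull.volume),
        hull_perimeter=float(hull.area),
        bbox=(int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())),
    )


def nrl_profile(geom: ContourGeometry) -> NrlProfile:
    """Boundary-to-centroid distances normalized by their maximum."""
    d = np.sqrt(((geom.boundary - np.asarray(geom.centroid)) ** 2).sum(axis=1))
    dmax = d.max()
    if dmax == 0:
        raise ValueError("degenerate boundary: zero radial extent")
    return NrlProfile(values=d / dmax)


def nrl_statistics(profile: NrlProfile) -> tuple[float, float]:
    """(entropy, variance) of the NRL profile.

    Entropy is the Shannon entropy (natural log) of a 10-equal-bin
    histogram of the profile on (0, 1]; variance is the ddof=0 variance
    of the raw profile.
    """
    v = profile.values
    if len(v) < 8:
        raise ValueError("NRL profile needs >= 8 boundary samples")
    hist, _ = np.histogram(v, bins=NRL_HISTOGRAM_BINS, range=(0.0, 1.0))
    p = hist / hist.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log(p)).sum())
    return entropy, float(np.var(v))


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Best-fit ellipse from second-order central moments of the mask.

    The returned ellipse has the same area-normalized second moments as
    the region (semi-axes ``2*sqrt(eigenvalue)``), matching the moment
    convention used for the six ellipse features.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 16:
        raise ValueError("mask too small for a stable ellipse fit (area < 16)")
    rows, cols = np.nonzero(mask)
    rc, cc = rows.mean(), cols.mean()
    dr, dc = rows - rc, cols - cc
    mu_rr = float(np.mean(dr * dr))
    mu_cc = float(np.mean(dc * dc))
    mu_rc = float(np.mean(dr * dc))
    raw_min = np.linalg.eigvalsh(np.array([[mu_rr, mu_rc], [mu_rc, mu_cc]]))[0]
    if raw_min <= 1e-6:
        raise ValueError("degenerate moments: mask is line-like")
    # +1/12 per axis: moments of the unit pixel square, stabilizes thin shapes
    cov = np.array([[mu_rr + 1.0 / 12.0, mu_rc], [mu_rc, mu_cc + 1.0 / 12.0]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    a = 2.0 * np.sqrt(evals[1])
    b = 2.0 * np.sqrt(evals[0])
    major = evecs[:, 1]  # (d_row, d_col)
    angle = np.degrees(np.arctan2(-major[0], major[1]))  # x right, y up
    angle %= 180.0
    return EllipseFit(center=(float(rc), float(cc)), a=float(a), b=float(b), angle_deg=float(angle))


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def _rasterize_ellipse(fit: EllipseFit, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - fit.center[0]
    dc = cc - fit.center[1]
    theta = np.radians(fit.angle_deg)
    # major-axis direction in (row, col): x right, y up -> row decreases with +y
    u = dc * np.cos(theta) - dr * np.sin(theta)
    v = dc * np.sin(theta) + dr * np.cos(theta)
    return (u / fit.a) ** 2 + (v / fit.b) ** 2 <= 1.0


def _undulation(geom: ContourGeometry, depth_px: float = 1.0) -> float:
    """Fraction-normalized count of concave boundary excursions.

    A run of consecutive boundary points lying more than ``depth_px``
    inside the convex hull counts as one excursion; the count is divided
    by the number of boundary samples so the measure is resolution-
    comparable.
    """
    hull_ring = Polygon(geom.hull).exterior
    depths = np.array([hull_ring.distance(Point(p)) for p in geom.boundary])
    inside = depths > depth_px
    if not inside.any():
        return 0.0
    if inside.all():
        return 1.0 / len(geom.boundary)
    # rotate the circular sequence so it starts outside, then count rising edges
    start = int(np.argmin(inside))
    rolled = np.roll(inside, -start).astype(int)
    runs = int((np.diff(rolled) == 1).sum())
    return runs / len(geom.boundary)


def morphology_feature_set(mask: np.ndarray, normalize: bool = False) -> FeatureSet:
    """The 18-feature morphology vector of a tumor mask, fixed order.

    Set ``normalize=True`` to l2-normalize the vector when the family is
    used standalone.
    """
    geom = contour_geometry(mask)
    if geom.area < 16:
        raise ValueError("degenerate mask: area < 16 px")
    profile = nrl_profile(geom)
    nrl_ent, nrl_var = nrl_statistics(profile)
    fit = fit_ellipse(mask)

    a_px, p_px = geom.area, geom.perimeter
    rmin, rmax, cmin, cmax = geom.bbox
    bb_h, bb_w = rmax - rmin + 1, cmax - cmin + 1
    feret = float(pdist(geom.hull).max()) if len(geom.hull) > 1 else 0.0

    form_factor = 4.0 * np.pi * a_px / p_px**2
    roundness = 4.0 * a_px / (np.pi * feret**2) if feret > 0 else 0.0
    aspect = max(bb_h / bb_w, bb_w / bb_h)
    convexity = geom.hull_perimeter / p_px
    solidity = a_px / geom.hull_area if geom.hull_area > 0 else 0.0
    extent = a_px / (bb_h * bb_w)
    undulation = _undulation(geom)
    compactness = p_px**2 / (4.0 * np.pi * a_px)

    ell_perim = _ellipse_perimeter(fit.a, fit.b)
    ell_mask = _rasterize_ellipse(fit, mask.shape)
    m = np.asarray(mask).astype(bool)
    union = np.logical_or(ell_mask, m).sum()
    overlap = np.logical_and(ell_mask, m).sum() / union if union > 0 else 0.0

    values = np.array(
        [
            a_px,
            p_px,
            form_factor,
            roundness,
            aspect,
            convexity,
            solidity,
            extent,
            undulation,
            compactness,
            nrl_ent,
            nrl_var,
            2.0 * fit.a,
            2.0 * fit.b,
            fit.a / fit.b,
            ell_perim / p_px,
            fit.angle_deg,
            overlap,
        ]
    )
    names = [f"morph:{n}" for n in MORPHOLOGY_FEATURE_NAMES]
    flag = False
    if normalize:
        values, flag = l2_normalize(values)
    return FeatureSet(values=values, names=names, level_tag="morphology", zero_norm=flag)
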