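"""Two-stage subpixel detection of the three circular fiducial markers.

Stage one finds approximate marker positions on the whole slice: an HSV
colour filter calibrated on the manually marked base-image markers, median
filtering and morphological closing of the resulting mask, then a circular
Hough transform whose three strongest mutually non-overlapping peaks give the
coarse centres.  Stage two refines each centre on a cropped detail image:
Canny edge detection, a second Hough vote restricted to the expected radius
range, selection of the edge pixels consistent with the winning circle, and a
closed-form algebraic (Kåsa) least-squares circle fit on those inliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.morphology import closing, disk
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "ColorFilterParams",
    "MarkerDetection",
    "CalibrationError",
    "DetectionError",
    "build_color_filter",
    "coarse_detect",
    "refine_center",
    "fit_circle",
    "detect_markers",
]


class CalibrationError(ValueError):
    """Seed-point colours are unusable for building a colour filter."""


class DetectionError(RuntimeError):
    """The expected number of circular markers could not be found."""


# ---------------------------------------------------------------------------
# Colour filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColorFilterParams:
    """Inclusive HSV bounds; hue is circular and the range may wrap 1 -> 0.

    All channels live in [0, 1] (skimage convention).  ``hue_range`` with
    ``lo > hi`` denotes a wrapped interval.  A saturation range reaching
    (near) zero makes the hue unconstrained, since hue is undefined for grey
    pixels.
    """

    hue_range: tuple[float, float]
    saturation_range: tuple[float, float]
    value_range: tuple[float, float]

    def mask(self, image_rgb: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside the HSV box."""
        hsv = rgb2hsv(image_rgb)
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        lo, hi = self.hue_range
        if lo <= hi:
            m_h = (h >= lo) & (h <= hi)
        else:  # wrapped
            m_h = (h >= lo) | (h <= hi)
        if self.saturation_range[0] <= 0.05:
            # Hue is meaningless for achromatic pixels.
            m_h = m_h | (s <= 0.05)
        m_s = (s >= self.saturation_range[0]) & (s <= self.saturation_range[1])
        m_v = (v >= self.value_range[0]) & (v <= self.value_range[1])
        return m_h & m_s & m_v


def _circular_span(hues: np.ndarray) -> tuple[float, float]:
    """Smallest circular interval [lo, hi] covering the hue samples."""
    h = np.sort(np.mod(hues, 1.0))
    if len(h) == 1:
        return float(h[0]), float(h[0])
    gaps = np.diff(np.concatenate([h, h[:1] + 1.0]))
    k = int(np.argmax(gaps))
    lo = h[(k + 1) % len(h)]
    hi = h[k]
    return float(lo), float(hi)


def build_color_filter(
    base_image: np.ndarray,
    seed_points: np.ndarray,
    tolerance: float = 0.08,
    sanity_width: float = 0.35,
) -> ColorFilterParams:
    """Calibrate the HSV filter from user-marked pixels on the base image.

    ``seed_points`` are (x, y) pixel positions on the three markers.  A 3x3
    neighbourhood around each seed is sampled; the per-channel min/max padded
    by ``tolerance`` forms the filter.  If the sampled colours span more than
    ``sanity_width`` in saturation or value (mutually inconsistent seeds, or
    a seed off the marker), a :class:`CalibrationError` is raised.
    """
    pts = np.atleast_2d(np.asarray(seed_points, dtype=float))
    hsv = rgb2hsv(base_image)
    h, w = hsv.shape[:2]
    samples = []
    for x, y in pts:
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < w and 0 <= yi < h):
            raise CalibrationError(f"seed point ({x}, {y}) outside the image")
        patch = hsv[max(yi - 1, 0):yi + 2, max(xi - 1, 0):xi + 2]
        samples.append(patch.reshape(-1, 3))
    smp = np.concatenate(samples)

    s_lo, s_hi = smp[:, 1].min(), smp[:, 1].max()
    v_lo, v_hi = smp[:, 2].min(), smp[:, 2].max()
    if (s_hi - s_lo) > sanity_width or (v_hi - v_lo) > sanity_width:
        raise CalibrationError(
            "seed-point colours are mutually inconsistent "
            f"(saturation span {s_hi - s_lo:.2f}, value span {v_hi - v_lo:.2f})"
        )
    if smp[:, 1].max() <= 0.05:
        hue_lo, hue_hi = 0.0, 1.0  # achromatic markers: hue unconstrained
    else:
        hue_lo, hue_hi = _circular_span(smp[:, 0])
        hue_lo = np.mod(hue_lo - tolerance, 1.0)
        hue_hi = np.mod(hue_hi + tolerance, 1.0)
    return ColorFilterParams(
        hue_range=(float(hue_lo), float(hue_hi)),
        saturation_range=(max(0.0, float(s_lo - tolerance)),
                          min(1.0, float(s_hi + tolerance))),
        value_range=(max(0.0, float(v_lo - tolerance)),
                     min(1.0, float(v_hi + tolerance))),
    )


# ---------------------------------------------------------------------------
# Coarse detection (whole slice)
# ---------------------------------------------------------------------------

def coarse_detect(
    image: np.ndarray,
    color_filter: ColorFilterParams,
    radius_range_px: tuple[float, float],
    n_expected: int = 3,
    median_size: int = 5,
    closing_radius: int = 5,
    downscale: int = 2,
) -> np.ndarray:
    """Approximate marker centres from the colour mask, ~2 px accurate.

    Pipeline: HSV mask -> median filter -> morphological closing -> circular
    Hough transform on the mask boundary -> the ``n_expected`` strongest
    mutually non-overlapping accumulator peaks.  The Hough vote runs on a
    ``downscale``-times reduced mask for speed; peak coordinates are mapped
    back to full resolution.

    Raises :class:`DetectionError` when fewer than ``n_expected`` circles are
    found, reporting how many there were.
    """
    ds = max(1, int(downscale))
    # The coarse pass only needs ~2 px accuracy, so it runs on a decimated
    # view of the slice; kernel sizes and radii scale along.
    small_img = image[::ds, ::ds]
    mask = color_filter.mask(small_img)
    med = max(3, int(round(median_size / ds)) | 1)
    mask = ndimage.median_filter(mask.astype(np.uint8), size=med) > 0
    close_r = max(2, int(round(closing_radius / ds)))
    mask = closing(mask, disk(close_r))

    # Boundary of the mask as the edge map for the Hough vote.
    er = ndimage.binary_erosion(mask)
    edges = mask & ~er

    r_lo = max(3, int(np.floor(radius_range_px[0] / ds)))
    r_hi = max(r_lo + 1, int(np.ceil(radius_range_px[1] / ds)))
    radii = np.arange(r_lo, r_hi + 1, max(1, (r_hi - r_lo) // 10))
    acc = hough_circle(edges, radii)
    if acc.size == 0 or acc.max() <= 0:
        raise DetectionError(f"found 0 circular markers, expected {n_expected}")
    votes, cx, cy, rad = hough_circle_peaks(
        acc, radii,
        min_xdistance=int(1.5 * r_lo),
        min_ydistance=int(1.5 * r_lo),
        total_num_peaks=n_expected,
        normalize=True,
    )
    if len(cx) < n_expected:
        raise DetectionError(
            f"found {len(cx)} circular markers, expected {n_expected}"
        )
    # Deterministic ordering: highest vote first, ties by (y, x).
    order = np.lexsort((cx, cy, -np.round(np.asarray(votes, float), 12)))
    centers = np.column_stack([cx, cy]).astype(float)[order] * ds
    return centers


# ---------------------------------------------------------------------------
# Subpixel refinement (detail image)
# ---------------------------------------------------------------------------

@dataclass
class MarkerDetection:
    """A refined fiducial detection.

    ``center_px`` is in the coordinate frame of the *full* image when
    produced by :func:`detect_markers`, or of the detail crop when produced
    directly by :func:`refine_center`.  ``status`` is "ok" or
    "low-confidence"; ``fit_rms_px`` is NaN when no circle could be fitted.
    """

    center_px: tuple[float, float]
    radius_px: float
    detail_bbox: tuple[int, int, int, int]  # x0, y0, width, height
    status: str = "ok"
    fit_rms_px: float = float("nan")
    n_edge_px: int = 0


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic (Kåsa) least-squares circle through >= 3 points.

    Minimises ``sum (|p - c|^2 - r^2)^2``, which is linear in
    ``(2cx, 2cy, r^2 - |c|^2)`` and therefore has a closed-form solution that
    is exact for points lying exactly on a circle.  Returns ``(center,
    radius, rms)`` where ``rms`` is the root-mean-square *geometric* residual
    ``|p - c| - r``.  Raises for collinear configurations.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
        raise ValueError("need at least three 2D points")
    A = np.column_stack([2 * p[:, 0], 2 * p[:, 1], np.ones(len(p))])
    b = np.sum(p**2, axis=1)
    # Collinearity makes the normal matrix singular.
    _, sing, _ = np.linalg.svd(A - A.mean(axis=0), full_matrices=False)
    if sing[0] < 1e-12 or sing[1] / sing[0] < 1e-9:
        raise ValueError("collinear points do not determine a circle")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    r2 = sol[2] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(p - center, axis=1) - radius
    rms = float(np.sqrt(np.mean(resid**2)))
    return center, radius, rms


def refine_center(
    detail_image: np.ndarray,
    approx_center_px: np.ndarray,
    radius_range_px: tuple[float, float],
    canny_sigma: float = 2.0,
    inlier_band_px: float = 2.0,
    min_edge_px: int = 12,
) -> MarkerDetection:
    """Subpixel marker centre on a cropped detail image.

    Canny edge map -> circular Hough vote restricted to ``radius_range_px``
    -> edge pixels within ``inlier_band_px`` of the winning circle ->
    algebraic circle fit on those inliers.  Fewer than ``min_edge_px``
    usable edge pixels yields a low-confidence detection (never an
    exception), falling back on the Hough (or supplied) estimate.
    """
    img = np.asarray(detail_image)
    gray = img.mean(axis=-1) if img.ndim == 3 else img.astype(float)
    gray = gray / 255.0 if gray.max() > 1.5 else gray
    h, w = gray.shape
    bbox = (0, 0, w, h)
    approx = np.asarray(approx_center_px, dtype=float)

    edges = canny(gray, sigma=canny_sigma)
    ey, ex = np.nonzero(edges)
    if len(ex) < min_edge_px:
        return MarkerDetection(
            center_px=tuple(approx), radius_px=float(np.mean(radius_range_px)),
            detail_bbox=bbox, status="low-confidence",
            fit_rms_px=float("nan"), n_edge_px=len(ex),
        )

    r_lo = max(3, int(np.floor(radius_range_px[0])))
    r_hi = max(r_lo + 1, int(np.ceil(radius_range_px[1])))
    radii = np.arange(r_lo, r_hi + 1, max(1, (r_hi - r_lo) // 10))
    acc = hough_circle(edges, radii)
    _, cx, cy, rad = hough_circle_peaks(acc, radii, total_num_peaks=1)
    if len(cx) == 0:
        return MarkerDetection(
            center_px=tuple(approx), radius_px=float(np.mean(radius_range_px)),
            detail_bbox=bbox, status="low-confidence",
            fit_rms_px=float("nan"), n_edge_px=0,
        )
    c0 = np.array([cx[0], cy[0]], dtype=float)
    r0 = float(rad[0])

    pts = np.column_stack([ex, ey]).astype(float)
    dist = np.abs(np.linalg.norm(pts - c0, axis=1) - r0)
    inliers = pts[dist <= inlier_band_px]
    if len(inliers) < min_edge_px:
        return MarkerDetection(
            center_px=tuple(c0), radius_px=r0, detail_bbox=bbox,
            status="low-confidence", fit_rms_px=float("nan"),
            n_edge_px=len(inliers),
        )
    try:
        center, radius, rms = fit_circle(inliers)
    except ValueError:
        return MarkerDetection(
            center_px=tuple(c0), radius_px=r0, detail_bbox=bbox,
            status="low-confidence", fit_rms_px=float("nan"),
            n_edge_px=len(inliers),
        )
    # A fit that wandered far from the Hough vote, or a circle partly
    # outside the detail crop (clipped marker), is not fully trustworthy.
    status = "ok"
    if np.linalg.norm(center - c0) > inlier_band_px * 2 or not (
        0 <= center[0] < w and 0 <= center[1] < h
    ):
        status = "low-confidence"
    phi = np.linspace(0.0, 2 * np.pi, 72, endpoint=False)
    ring_x = center[0] + radius * np.cos(phi)
    ring_y = center[1] + radius * np.sin(phi)
    outside = ((ring_x < 0) | (ring_x > w - 1)
               | (ring_y < 0) | (ring_y > h - 1)).mean()
    if outside > 0.15:
        status = "low-confidence"
    return MarkerDetection(
        center_px=(float(center[0]), float(center[1])),
        radius_px=radius, detail_bbox=bbox, status=status,
        fit_rms_px=rms, n_edge_px=len(inliers),
    )


def detect_markers(
    image: np.ndarray,
    color_filter: ColorFilterParams,
    radius_range_px: tuple[float, float],
    n_expected: int = 3,
    crop_margin_factor: float = 1.5,
) -> list[MarkerDetection]:
    """Full per-slice detection: coarse Hough pass, then subpixel refinement.

    Detail crops extend ``crop_margin_factor`` times the maximum expected
    radius on each side of the coarse centre (clipped to the image).
    Detections are returned in the coarse-pass order; ``center_px`` and
    ``detail_bbox`` are expressed in full-image coordinates.
    """
    coarse = coarse_detect(image, color_filter, radius_range_px, n_expected)
    margin = int(np.ceil(crop_margin_factor * radius_range_px[1]))
    h, w = image.shape[:2]
    out: list[MarkerDetection] = []
    for cx, cy in coarse:
        x0 = int(max(0, np.floor(cx - margin)))
        y0 = int(max(0, np.floor(cy - margin)))
        x1 = int(min(w, np.ceil(cx + margin)))
        y1 = int(min(h, np.ceil(cy + margin)))
        det = refine_center(
            image[y0:y1, x0:x1],
            np.array([cx - x0, cy - y0]),
            radius_range_px,
        )
        out.append(MarkerDetection(
            center_px=(det.center_px[0] + x0, det.center_px[1] + y0),
            radius_px=det.radius_px,
            detail_bbox=(x0, y0, x1 - x0, y1 - y0),
            status=det.status,
            fit_rms_px=det.fit_rms_px,
            n_edge_px=det.n_edge_px,
        ))
    return out
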