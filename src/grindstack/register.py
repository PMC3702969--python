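"""Landmark-based slice registration.

Every grinding image is aligned directly onto the first (base) image of the
series with a *linear conformal* transform — a 2D similarity (isotropic scale,
rotation and translation, no reflection) fitted by least squares to the three
detected fiducial centres.  Registering to the base image rather than chaining
slice-to-slice avoids the accumulation of registration error along the stack.

The module also owns the metric calibration (pixel spacing from the known
inter-marker distances), a consistency check on the three marker distances,
and the second-pass correction for fiducial pins that were not drilled
perfectly perpendicular to the grinding plane.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import warp

__all__ = [
    "SimilarityTransform2D",
    "MarkerTrack",
    "DegenerateConfigurationError",
    "estimate_similarity",
    "apply_transform",
    "compute_pixel_spacing",
    "check_marker_distances",
    "DistanceVerdict",
    "TiltEstimate",
    "estimate_tilt_and_correct",
]


class DegenerateConfigurationError(ValueError):
    """Raised when a landmark configuration does not determine a transform."""


# ---------------------------------------------------------------------------
# Similarity transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform2D:
    """Conformal map ``p' = s * R(theta) * p + t`` on pixel coordinates.

    ``scale`` must be positive; the linear part is a proper rotation times a
    positive scale, so reflections are excluded by construction (three markers
    drilled into a physical block cannot mirror between slices).
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale!r}")
        object.__setattr__(self, "translation_px",
                           tuple(float(v) for v in self.translation_px))

    @property
    def linear(self) -> np.ndarray:
        """The 2x2 linear part ``s * R``."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        return self.scale * np.array([[c, -s], [s, c]])

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on ``(x, y, 1)`` column vectors."""
        m = np.eye(3)
        m[:2, :2] = self.linear
        m[:2, 2] = self.translation_px
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` (or a single ``(2,)``) point array."""
        p = np.asarray(points, dtype=float)
        return p @ self.linear.T + np.asarray(self.translation_px)

    def inverse(self) -> "SimilarityTransform2D":
        inv_lin = self.linear
        t = np.asarray(self.translation_px)
        th = np.deg2rad(-self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        rinv = np.array([[c, -s], [s, c]]) / self.scale
        return SimilarityTransform2D(
            scale=1.0 / self.scale,
            rotation_deg=-self.rotation_deg,
            translation_px=tuple(-(rinv @ t)),
        )

    def compose(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        t = self.apply(np.asarray(other.translation_px))
        return SimilarityTransform2D(
            scale=self.scale * other.scale,
            rotation_deg=self.rotation_deg + other.rotation_deg,
            translation_px=tuple(t),
        )

    @staticmethod
    def identity() -> "SimilarityTransform2D":
        return SimilarityTransform2D()


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    p = np.asarray(points, dtype=float)
    if len(p) < 3:
        return True
    p0 = p - p.mean(axis=0)
    # Rank of the centred configuration: collinear iff smallest singular
    # value is negligible against the largest.
    s = np.linalg.svd(p0, compute_uv=False)
    return s[0] < tol or s[-1] / s[0] < tol


def estimate_similarity(
    src: np.ndarray, dst: np.ndarray
) -> tuple[SimilarityTransform2D, float]:
    """Least-squares conformal fit mapping ``src`` landmarks onto ``dst``.

    Minimises ``sum |s R src_i + t - dst_i|^2`` in closed form by treating the
    planar points as complex numbers: with centred coordinates the optimal
    ``a = s e^{i theta}`` is ``<d, s> / <s, s>``, which has positive scale and
    can never produce a reflection.

    Returns the transform and the fiducial registration error (root mean
    square residual in pixels).  Raises :class:`DegenerateConfigurationError`
    for collinear landmark triplets.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (N, 2) arrays")
    if len(src) < 2:
        raise DegenerateConfigurationError("need at least two landmarks")
    if len(src) >= 3 and (_collinear(src) or _collinear(dst)):
        raise DegenerateConfigurationError("collinear landmark triplet")

    zs = src[:, 0] + 1j * src[:, 1]
    zd = dst[:, 0] + 1j * dst[:, 1]
    ms, md = zs.mean(), zd.mean()
    zs0, zd0 = zs - ms, zd - md
    denom = np.vdot(zs0, zs0).real
    if denom < 1e-12:
        raise DegenerateConfigurationError("source landmarks coincide")
    a = np.vdot(zs0, zd0) / denom  # vdot conjugates the first argument
    t = md - a * ms
    tform = SimilarityTransform2D(
        scale=float(abs(a)),
        rotation_deg=float(np.rad2deg(np.angle(a))),
        translation_px=(t.real, t.imag),
    )
    resid = tform.apply(src) - dst
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return tform, fre


def apply_transform(
    image: np.ndarray,
    tform: SimilarityTransform2D,
    out_size: tuple[int, int] | None = None,
    fill: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``image`` under ``tform`` (source pixel -> output pixel).

    Each output pixel ``p`` takes the bilinear sample of the source at
    ``tform^{-1}(p)``.  Returns ``(aligned, valid)`` where ``valid`` flags
    output pixels whose pre-image fell inside the source frame; invalid
    pixels hold ``fill``.

    ``out_size`` is ``(height, width)``; default is the input shape.
    """
    if out_size is None:
        out_size = image.shape[:2]
    h, w = out_size
    # skimage treats a matrix inverse_map as acting on (x, y) = (col, row)
    # homogeneous coordinates, matching our convention.
    inv = tform.inverse().matrix

    img = np.asarray(image)
    aligned = warp(
        img.astype(float),
        inverse_map=inv,
        output_shape=(h, w) + img.shape[2:],
        order=1,
        mode="constant",
        cval=fill,
        preserve_range=True,
    )
    # Validity from the geometric pre-image, not the sampled values.
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    pre = tform.inverse().apply(pts)
    hs, ws = img.shape[:2]
    valid = (
        (pre[:, 0] >= 0) & (pre[:, 0] <= ws - 1)
        & (pre[:, 1] >= 0) & (pre[:, 1] <= hs - 1)
    ).reshape(h, w)
    if np.issubdtype(img.dtype, np.integer):
        aligned = np.clip(np.rint(aligned), 0, 255).astype(img.dtype)
    return aligned, valid


# ---------------------------------------------------------------------------
# Metric calibration
# ---------------------------------------------------------------------------

def compute_pixel_spacing(
    px_distances: np.ndarray, mm_distances: np.ndarray
) -> float:
    """Pixel spacing in µm/px from the three inter-marker distances.

    The known metric distance of each marker pair (from the CNC drilling) is
    divided by the corresponding base-image pixel distance; the *mean of the
    three individual ratios* is the spacing.
    """
    px = np.asarray(px_distances, dtype=float)
    mm = np.asarray(mm_distances, dtype=float)
    if px.shape != mm.shape:
        raise ValueError("distance lists must have matching length")
    if np.any(px <= 0) or np.any(mm <= 0):
        raise ValueError("all distances must be positive")
    return float(np.mean(mm * 1000.0 / px))


# ---------------------------------------------------------------------------
# Marker track and distance consistency
# ---------------------------------------------------------------------------

@dataclass
class MarkerTrack:
    """Per-slice matched marker centres and slice depths.

    ``centers_px`` has shape ``(n_slices, 3, 2)`` with a fixed marker
    labelling across slices; ``z_um`` is strictly increasing with
    ``z_um[0] == 0``.
    """

    centers_px: np.ndarray
    z_um: np.ndarray

    def __post_init__(self) -> None:
        self.centers_px = np.asarray(self.centers_px, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.centers_px.ndim != 3 or self.centers_px.shape[1:] != (3, 2):
            raise ValueError("centers_px must have shape (n_slices, 3, 2)")
        if len(self.z_um) != len(self.centers_px):
            raise ValueError("z_um length must match the number of slices")
        if np.any(np.diff(self.z_um) <= 0):
            raise ValueError("z_um must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return len(self.z_um)

    def pairwise_distances_px(self) -> np.ndarray:
        """(n_slices, 3) distances for pairs (0,1), (0,2), (1,2)."""
        c = self.centers_px
        pairs = [(0, 1), (0, 2), (1, 2)]
        return np.stack(
            [np.linalg.norm(c[:, i] - c[:, j], axis=1) for i, j in pairs],
            axis=1,
        )


class DistanceVerdict(enum.Enum):
    ALL_CONSISTENT = "all-consistent"
    ONE_OUTLIER = "one-outlier"
    ALL_INCONSISTENT = "all-inconsistent"


MARKER_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class DistanceCheck:
    verdict: DistanceVerdict
    relative_deviation: tuple[float, float, float]
    outlier_pair: tuple[int, int] | None = None
    conformable_pairs: tuple[tuple[int, int], ...] = ()
    recommendation: str = ""


def check_marker_distances(
    track: MarkerTrack,
    design_mm: np.ndarray,
    pixel_spacing_um_per_px: float,
    rel_tolerance: float = 0.01,
) -> DistanceCheck:
    """Compare the slice-averaged inter-marker distances with design values.

    If exactly one of the three pairwise distances deviates beyond
    ``rel_tolerance`` while the other two agree, the verdict names that pair
    as outlier and recommends computing the pixel spacing from the two
    conformable distances only; otherwise the verdict is all-consistent or
    all-inconsistent.
    """
    mean_px = track.pairwise_distances_px().mean(axis=0)
    meas_mm = mean_px * pixel_spacing_um_per_px / 1000.0
    design = np.asarray(design_mm, dtype=float)
    rel = np.abs(meas_mm - design) / design
    bad = rel > rel_tolerance
    n_bad = int(bad.sum())
    if n_bad == 0:
        return DistanceCheck(DistanceVerdict.ALL_CONSISTENT, tuple(rel))
    if n_bad == 1:
        k = int(np.argmax(bad))
        conformable = tuple(p for i, p in enumerate(MARKER_PAIRS) if i != k)
        return DistanceCheck(
            DistanceVerdict.ONE_OUTLIER,
            tuple(rel),
            outlier_pair=MARKER_PAIRS[k],
            conformable_pairs=conformable,
            recommendation=(
                "compute pixel spacing with only the two conformable "
                f"marker distances {conformable}"
            ),
        )
    return DistanceCheck(DistanceVerdict.ALL_INCONSISTENT, tuple(rel))


# ---------------------------------------------------------------------------
# Tilt (non-perpendicular pin) estimation and second-pass correction
# ---------------------------------------------------------------------------

def _fit_slope(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line ``y = c0 + m z``; returns (c0, m)."""
    z = np.asarray(z, dtype=float)
    zc = z - z.mean()
    denom = np.sum(zc**2)
    m = float(np.sum(zc * (y - y.mean())) / denom)
    c0 = float(y.mean() - m * z.mean())
    return c0, m


@dataclass
class TiltEstimate:
    """Per-marker drift vectors (px/µm) and the regression intercepts (px)."""

    drift_px_per_um: np.ndarray   # (3, 2)
    intercepts_px: np.ndarray     # (3, 2) marker positions extrapolated to z=0
    residual_slope_px_per_um: np.ndarray  # non-similarity component, (3, 2)


def register_track(
    track: MarkerTrack,
    base_centers_px: np.ndarray | None = None,
    targets_px: np.ndarray | None = None,
) -> tuple[list[SimilarityTransform2D], np.ndarray]:
    """Register every slice's marker triplet onto per-slice target points.

    ``targets_px`` has shape (n_slices, 3, 2); by default every slice is
    mapped onto ``base_centers_px`` (the base-image markers, defaulting to
    slice 0 of the track).  Returns the transforms and per-slice fiducial
    registration errors.
    """
    if targets_px is None:
        if base_centers_px is None:
            base_centers_px = track.centers_px[0]
        targets_px = np.broadcast_to(
            np.asarray(base_centers_px, dtype=float),
            track.centers_px.shape,
        )
    transforms: list[SimilarityTransform2D] = []
    fres = np.empty(track.n_slices)
    for i in range(track.n_slices):
        tf, fre = estimate_similarity(track.centers_px[i], targets_px[i])
        transforms.append(tf)
        fres[i] = fre
    return transforms, fres


def estimate_tilt_and_correct(
    track: MarkerTrack,
    base_centers_px: np.ndarray | None = None,
) -> tuple[TiltEstimate, list[SimilarityTransform2D], np.ndarray]:
    """Estimate per-marker depth drift and re-register with compensation.

    A pin drilled at an angle makes its circular cross-section drift linearly
    with depth *in the specimen*.  First-pass registration (which forces all
    markers back onto their base positions) then drags the whole image along
    the drift, shearing the reconstructed specimen.

    The drift of each marker is estimated from two observable pieces:

    * the depth trend of the first-pass registration *residuals* at each
      marker (the component of the drift field that a similarity transform
      cannot absorb), and
    * the depth trend of the first-pass transform *parameters* themselves
      (the similarity-shaped component of the drift, which the transforms
      absorb).  Attributing this trend to the markers assumes the true
      slice-to-slice repositioning has no systematic depth trend.

    The second pass registers each slice onto drift-compensated targets
    ``c0_k + m_k * z`` so that tilted pins no longer shear the specimen.

    Requires at least 5 slices.  Returns the tilt estimate, the corrected
    transforms and their fiducial registration errors.
    """
    if track.n_slices < 5:
        raise ValueError("tilt estimation requires at least 5 slices")
    if base_centers_px is None:
        base_centers_px = track.centers_px[0]
    base_centers_px = np.asarray(base_centers_px, dtype=float)
    z = track.z_um
    n = track.n_slices

    drift = np.zeros((3, 2))
    intercepts = base_centers_px.copy()
    resid_slope_first = np.zeros((3, 2))
    transforms: list[SimilarityTransform2D] = []
    fres = np.zeros(n)

    # The update below is exact only to first order in the drift, so iterate:
    # once the targets model the drift correctly, both the residual trends
    # and the transform-parameter trends vanish and the loop is a fixed
    # point.  A handful of iterations removes the linearisation error.
    for it in range(4):
        targets = intercepts[None, :, :] + drift[None, :, :] * z[:, None, None]
        transforms, fres = register_track(track, targets_px=targets)

        reg = np.stack(
            [transforms[i].apply(track.centers_px[i]) for i in range(n)]
        )
        resid = reg - targets
        resid_slope = np.empty((3, 2))
        resid_icept = np.empty((3, 2))
        for k in range(3):
            for d in range(2):
                resid_icept[k, d], resid_slope[k, d] = _fit_slope(
                    z, resid[:, k, d]
                )
        if it == 0:
            resid_slope_first = resid_slope.copy()

        # Depth trend of the transform parameters: the similarity-shaped
        # component of any unmodelled drift, absorbed with opposite sign.
        theta = np.unwrap(
            np.array([np.deg2rad(t.rotation_deg) for t in transforms])
        )
        lns = np.array([np.log(t.scale) for t in transforms])
        tx = np.array([t.translation_px[0] for t in transforms])
        ty = np.array([t.translation_px[1] for t in transforms])
        _, dtheta = _fit_slope(z, theta)
        _, dlns = _fit_slope(z, lns)
        _, dtx = _fit_slope(z, tx)
        _, dty = _fit_slope(z, ty)

        # Velocity of the absorbed similarity field at the current targets
        # (rotation/scale act about the pixel origin, matching the
        # transform parameterisation).
        update = np.empty((3, 2))
        for k in range(3):
            x, y = intercepts[k]
            vx = dtx + dlns * x - dtheta * y
            vy = dty + dlns * y + dtheta * x
            update[k] = resid_slope[k] - np.array([vx, vy])
        drift = drift + update
        intercepts = intercepts + resid_icept
        if np.max(np.abs(update)) * (z[-1] - z[0]) < 1e-9:
            break

    targets = intercepts[None, :, :] + drift[None, :, :] * z[:, None, None]
    transforms, fres = register_track(track, targets_px=targets)
    est = TiltEstimate(
        drift_px_per_um=drift,
        intercepts_px=intercepts,
        residual_slope_px_per_um=resid_slope_first,
    )
    return est, transforms, fres
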