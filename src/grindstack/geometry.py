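"""Geometric accuracy evaluation on the reconstructed reference object.

Mirrors the reference-object procedure used to validate the reconstruction:
the embedded cuboid is segmented from the stack by thresholding, twenty
surface points are sampled per face, a total-least-squares plane is fitted to
each face, edges are derived as intersections of adjacent planes and corners
as intersections of three planes, and the report compares edge lengths with
the reference dimensions and angles with the ideal 0° (parallel faces) and
90° (adjacent faces and meeting edges).

Lengths are split into *in grinding plane* (unaffected by slice spacing) and
*in grinding direction* (directly dependent on the measured abrasion).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .stack import ReconstructedStack

__all__ = [
    "BinaryVolume",
    "PlaneFit",
    "GeometryReport",
    "SegmentationError",
    "threshold_segment",
    "estimate_cuboid_axes",
    "sample_face_points",
    "fit_plane",
    "intersect_planes",
    "intersect_three_planes",
    "angle_deviation",
    "geometry_report",
    "quantize_deviation",
    "measure_reference_object",
]

FACE_IDS = tuple(
    (axis, sign) for axis in (0, 1, 2) for sign in (-1, +1)
)


class SegmentationError(RuntimeError):
    pass


@dataclass
class BinaryVolume:
    """Thresholded voxel volume with anisotropic, non-equidistant spacing.

    ``mask`` is indexed ``(slice, row, col)``; a voxel centre maps to the
    metric point ``(col * s, row * s, z_um[slice] / 1000)`` mm where ``s`` is
    the in-plane pixel spacing in mm.
    """

    mask: np.ndarray
    pixel_spacing_um_per_px: float
    z_um: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.mask.ndim != 3 or len(self.z_um) != self.mask.shape[0]:
            raise ValueError("mask must be (n_slices, H, W) matching z_um")

    @property
    def spacing_mm(self) -> float:
        return self.pixel_spacing_um_per_px / 1000.0

    def voxel_volume_mm3(self) -> float:
        """Total segmented volume, each slice weighted by its local thickness."""
        z = self.z_um / 1000.0
        gaps = np.diff(z)
        thick = np.empty(len(z))
        thick[0] = gaps[0]
        thick[-1] = gaps[-1]
        if len(z) > 2:
            thick[1:-1] = 0.5 * (gaps[:-1] + gaps[1:])
        counts = self.mask.sum(axis=(1, 2))
        return float(np.sum(counts * thick) * self.spacing_mm**2)


def threshold_segment(
    stack: ReconstructedStack,
    threshold: float,
    channel: int = 0,
    object_side: str = "above",
) -> BinaryVolume:
    """Segment the reference object by thresholding one colour channel.

    ``object_side`` states on which side of the threshold the object lies
    ("above" or "below").  Raises :class:`SegmentationError` when nothing is
    segmented.
    """
    vol = stack.voxel_array()
    if vol.ndim == 4:
        chan = vol[..., channel].astype(float)
    else:
        chan = vol.astype(float)
    if object_side == "above":
        mask = chan > threshold
    elif object_side == "below":
        mask = chan < threshold
    else:
        raise ValueError("object_side must be 'above' or 'below'")
    if not mask.any():
        raise SegmentationError("threshold segmentation produced no voxels")
    return BinaryVolume(
        mask=mask,
        pixel_spacing_um_per_px=stack.pixel_spacing_um_per_px,
        z_um=stack.z_um,
    )


def _voxel_points_mm(volume: BinaryVolume, kk, rr, cc) -> np.ndarray:
    s = volume.spacing_mm
    return np.column_stack([
        np.asarray(cc, float) * s,
        np.asarray(rr, float) * s,
        volume.z_um[np.asarray(kk)] / 1000.0,
    ])


def estimate_cuboid_axes(volume: BinaryVolume) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes of the segmented object and its centroid (mm).

    Returns ``(axes, centroid)`` where the columns of ``axes`` are unit
    directions sorted by decreasing extent — for a cuboid with distinct edge
    lengths these are the edge directions, longest first.
    """
    kk, rr, cc = np.nonzero(volume.mask)
    pts = _voxel_points_mm(volume, kk, rr, cc)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evecs[:, order], centroid


# ---------------------------------------------------------------------------
# Surface sampling
# ---------------------------------------------------------------------------

_NEIGHBOR_DIRS = np.array([
    [0, 0, 1], [0, 0, -1],   # +x / -x  (col)
    [0, 1, 0], [0, -1, 0],   # +y / -y  (row)
    [1, 0, 0], [-1, 0, 0],   # +z / -z  (slice)
])
_DIR_VECS = np.array([
    [1, 0, 0], [-1, 0, 0],
    [0, 1, 0], [0, -1, 0],
    [0, 0, 1], [0, 0, -1],
], dtype=float)  # physical (x, y, z) unit vectors per lattice direction


def _surface_voxels(volume: BinaryVolume) -> tuple[np.ndarray, np.ndarray]:
    """Surface voxel indices and their local outward normals.

    A surface voxel is an object voxel with at least one non-object
    6-neighbour (out-of-bounds counts as non-object); its local normal is the
    normalised sum of the physical unit vectors toward empty neighbours.
    """
    m = volume.mask
    pad = np.pad(m, 1, constant_values=False)
    empties = []
    for d in _NEIGHBOR_DIRS:
        sl = tuple(slice(1 + s, 1 + s + n) for s, n in zip(d, m.shape))
        empties.append(~pad[sl])
    empties = np.stack(empties, axis=-1) & m[..., None]
    surf = empties.any(axis=-1)
    kk, rr, cc = np.nonzero(surf)
    normals = empties[kk, rr, cc].astype(float) @ _DIR_VECS
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 0  # opposing empty neighbours (thin slab) cancel out
    normals = normals[ok] / norms[ok, None]
    return np.column_stack([kk, rr, cc])[ok], normals


def sample_face_points(
    volume: BinaryVolume,
    face_id: tuple[int, int],
    n_points: int = 20,
    seed: int = 0,
    axes: np.ndarray | None = None,
    match_margin: float = 0.2,
) -> np.ndarray:
    """Sample ``n_points`` metric surface points (mm) on one cuboid face.

    ``face_id`` is ``(axis_index, sign)`` referring to the columns of
    ``axes`` (estimated from the volume when not supplied).  Surface voxels
    are assigned to the face whose outward normal best matches their local
    normal; ambiguous voxels (edge/corner staircase, margin below
    ``match_margin``) are discarded.  Points are drawn uniformly without
    replacement, reproducibly from ``seed``, and each sampled voxel centre is
    shifted half a voxel along the blocked lattice axis so that the expected
    face position is unbiased despite the binary segmentation.
    """
    if face_id not in FACE_IDS:
        raise ValueError(f"face_id must be one of {FACE_IDS}")
    if axes is None:
        axes, _ = estimate_cuboid_axes(volume)
    axis, sign = face_id
    face_normal = sign * axes[:, axis]

    idx, normals = _surface_voxels(volume)
    if len(idx) == 0:
        raise SegmentationError("volume has no surface voxels")

    # All 6 candidate face normals; a voxel belongs to the face with the
    # clearly best local-normal match.
    cand = np.stack([s * axes[:, a] for a, s in FACE_IDS])
    dots = normals @ cand.T
    best = np.argmax(dots, axis=1)
    sorted_dots = np.sort(dots, axis=1)
    clear = (sorted_dots[:, -1] - sorted_dots[:, -2]) > match_margin
    face_index = FACE_IDS.index(face_id)
    sel = (best == face_index) & clear
    if sel.sum() == 0:
        raise SegmentationError(f"face {face_id} does not intersect the volume")
    if sel.sum() < n_points:
        raise SegmentationError(
            f"face {face_id} has only {int(sel.sum())} usable surface voxels, "
            f"need {n_points}"
        )

    rng = np.random.default_rng(seed)
    pick = rng.choice(np.nonzero(sel)[0], size=n_points, replace=False)
    kk, rr, cc = idx[pick].T
    pts = _voxel_points_mm(volume, kk, rr, cc)

    # Half-voxel offset along the dominant blocked axis of the face normal:
    # a binary mask localises the face only to the last occupied voxel, so
    # pushing each sample half a voxel outward centres the error at zero.
    dom = int(np.argmax(np.abs(face_normal)))
    dsign = np.sign(face_normal[dom])
    if dom == 2:  # grinding direction: local slice gap varies
        z = volume.z_um / 1000.0
        n = len(z)
        for j, k in enumerate(kk):
            if dsign > 0:
                gap = z[min(k + 1, n - 1)] - z[min(k, n - 2)]
            else:
                gap = z[max(k, 1)] - z[max(k - 1, 0)]
            pts[j, 2] += dsign * gap / 2.0
    else:
        pts[:, dom] += dsign * volume.spacing_mm / 2.0
    return pts


# ---------------------------------------------------------------------------
# Plane fitting and intersections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneFit:
    """Total-least-squares plane ``n . x = offset`` (mm)."""

    unit_normal: tuple[float, float, float]
    offset: float
    rms_mm: float
    n_points: int

    def __post_init__(self) -> None:
        n = np.asarray(self.unit_normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector")
        if self.rms_mm < 0 or self.n_points < 3:
            raise ValueError("invalid plane fit")

    @property
    def normal(self) -> np.ndarray:
        return np.asarray(self.unit_normal)

    def oriented(self, direction: np.ndarray) -> "PlaneFit":
        """Flip the normal (and offset) to point along ``direction``."""
        if float(self.normal @ np.asarray(direction)) < 0:
            return PlaneFit(
                unit_normal=tuple(-self.normal), offset=-self.offset,
                rms_mm=self.rms_mm, n_points=self.n_points,
            )
        return self


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Orthogonal-distance (total least squares) plane through >= 3 points.

    The normal is the singular direction of least variance of the centred
    points; exact on coplanar points.  Raises on (near-)collinear input.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise ValueError("need at least three 3D points")
    centroid = p.mean(axis=0)
    q = p - centroid
    _, sing, vt = np.linalg.svd(q, full_matrices=False)
    if sing[0] < 1e-12 or sing[1] / sing[0] < 1e-9:
        raise ValueError("collinear points do not determine a plane")
    normal = vt[-1]
    offset = float(normal @ centroid)
    rms = float(np.sqrt(np.mean((q @ normal) ** 2)))
    return PlaneFit(
        unit_normal=tuple(normal), offset=offset, rms_mm=rms, n_points=len(p)
    )


def intersect_planes(
    p1: PlaneFit, p2: PlaneFit, angle_tol_deg: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Intersection line of two planes as ``(point, unit_direction)``.

    The direction is the normalised cross product of the normals; the point
    is the minimum-norm solution of the two plane equations.  Planes whose
    normals are within ``angle_tol_deg`` of (anti-)parallel raise a
    degenerate-intersection error.
    """
    n1, n2 = p1.normal, p2.normal
    cross = np.cross(n1, n2)
    norm = np.linalg.norm(cross)
    if norm < np.sin(np.deg2rad(angle_tol_deg)):
        raise ValueError("planes are (near-)parallel: no well-defined edge")
    direction = cross / norm
    A = np.vstack([n1, n2])
    b = np.array([p1.offset, p2.offset])
    point = np.linalg.lstsq(A, b, rcond=None)[0]
    return point, direction


def intersect_three_planes(
    p1: PlaneFit, p2: PlaneFit, p3: PlaneFit, cond_max: float = 100.0
) -> np.ndarray:
    """Corner point where three planes meet (unique 3x3 solution).

    Raises with the condition estimate when the normal matrix is too
    ill-conditioned (default bound 100, i.e. normals less than ~0.6° from
    coplanar/parallel are rejected).
    """
    A = np.vstack([p1.normal, p2.normal, p3.normal])
    b = np.array([p1.offset, p2.offset, p3.offset])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_max:
        raise ValueError(
            f"ill-conditioned plane triple (condition number {cond:.3g} "
            f"> {cond_max:g})"
        )
    return np.linalg.solve(A, b)


def angle_deviation(
    a: np.ndarray, b: np.ndarray, mode: str = "parallel"
) -> float:
    """Angular deviation in degrees between two directions.

    The raw angle is folded to [0°, 90°] (directions are unsigned).  Mode
    "parallel" returns the folded angle itself (0° for parallel lines or
    coplanar plane normals); mode "perpendicular" returns |90° - angle|.
    """
    va = np.asarray(a, dtype=float)
    vb = np.asarray(b, dtype=float)
    va = va / np.linalg.norm(va)
    vb = vb / np.linalg.norm(vb)
    theta = np.rad2deg(np.arccos(np.clip(abs(va @ vb), 0.0, 1.0)))
    if mode == "parallel":
        return float(theta)
    if mode == "perpendicular":
        return float(abs(90.0 - theta))
    raise ValueError("mode must be 'parallel' or 'perpendicular'")


def quantize_deviation(value_mm: float, step_mm: float = 0.1) -> float:
    """Round to the nearest multiple of ``step_mm``, halves away from zero.

    Emulates a measurement readout limited to 0.1 mm steps: deviations below
    half a step read as zero.
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    v = value_mm / step_mm
    # Small epsilon so values that are exact halves up to floating-point
    # representation (0.15/0.1 -> 1.4999...) still round away from zero.
    return float(np.sign(v) * np.floor(abs(v) + 0.5 + 1e-9) * step_mm)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class GeometryReport:
    """Accuracy metrics of the reconstructed reference cuboid.

    Edge lengths are grouped by orientation: *in grinding plane* (dominant
    direction perpendicular to the grinding axis) versus *in grinding
    direction*.  All angular deviations are against the ideal 0° / 90° and
    therefore non-negative.
    """

    edge_lengths_mm: dict
    reference_lengths_mm: dict
    length_error_pct_in_plane: np.ndarray
    length_error_pct_grinding: np.ndarray
    parallelism_deg: np.ndarray
    rectangularity_planes_deg: np.ndarray
    rectangularity_edges_deg: np.ndarray
    corners_mm: dict = field(default_factory=dict)

    def summary(self) -> dict:
        def ms(x):
            x = np.asarray(x, dtype=float)
            if x.size == 0:
                return {"mean": float("nan"), "sd": float("nan"), "n": 0}
            return {
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "n": int(x.size),
            }

        return {
            "length_in_plane_pct": ms(self.length_error_pct_in_plane),
            "length_grinding_direction_pct": ms(self.length_error_pct_grinding),
            "parallelism_planes_deg": ms(self.parallelism_deg),
            "rectangularity_planes_deg": ms(self.rectangularity_planes_deg),
            "rectangularity_edges_deg": ms(self.rectangularity_edges_deg),
        }

    def mean_angular_deviation_deg(self) -> float:
        """Mean over every parallelism and rectangularity deviation."""
        allv = np.concatenate([
            np.atleast_1d(self.parallelism_deg),
            np.atleast_1d(self.rectangularity_planes_deg),
            np.atleast_1d(self.rectangularity_edges_deg),
        ])
        return float(np.mean(allv))


def geometry_report(
    planes: dict,
    reference_lengths_mm: np.ndarray,
    grinding_axis: np.ndarray = (0.0, 0.0, 1.0),
) -> GeometryReport:
    """Derive edges, corners and accuracy metrics from six face planes.

    ``planes`` maps each ``(axis, sign)`` face id to its :class:`PlaneFit`
    with outward-oriented normal; ``reference_lengths_mm`` gives the true
    edge length per axis index.  Corners come from triple-plane
    intersections, edge lengths from corner-to-corner distances and edge
    directions from pairwise plane intersections.
    """
    missing = [f for f in FACE_IDS if f not in planes]
    if missing:
        raise ValueError(f"missing face planes: {missing}")
    ref = np.asarray(reference_lengths_mm, dtype=float)
    g = np.asarray(grinding_axis, dtype=float)
    g = g / np.linalg.norm(g)

    # Corners indexed by the sign triple.
    corners = {}
    for signs in itertools.product((-1, 1), repeat=3):
        corners[signs] = intersect_three_planes(
            planes[(0, signs[0])], planes[(1, signs[1])], planes[(2, signs[2])]
        )

    # Mean direction of each axis from the opposing outward normals.
    axis_dirs = []
    for a in range(3):
        d = planes[(a, 1)].normal - planes[(a, -1)].normal
        axis_dirs.append(d / np.linalg.norm(d))
    grinding_axis_index = int(np.argmax([abs(d @ g) for d in axis_dirs]))

    edge_lengths: dict = {0: [], 1: [], 2: []}
    err_in_plane, err_grinding = [], []
    for a in range(3):
        b, c = [x for x in range(3) if x != a]
        for sb, sc in itertools.product((-1, 1), repeat=2):
            lo = {a: -1, b: sb, c: sc}
            hi = {a: +1, b: sb, c: sc}
            p_lo = corners[(lo[0], lo[1], lo[2])]
            p_hi = corners[(hi[0], hi[1], hi[2])]
            length = float(np.linalg.norm(p_hi - p_lo))
            edge_lengths[a].append(length)
            err = abs(length - ref[a]) / ref[a] * 100.0
            if a == grinding_axis_index:
                err_grinding.append(err)
            else:
                err_in_plane.append(err)

    parallelism = np.array([
        angle_deviation(planes[(a, 1)].normal, planes[(a, -1)].normal,
                        mode="parallel")
        for a in range(3)
    ])

    rect_planes = []
    for (a, sa), (b, sb) in itertools.combinations(FACE_IDS, 2):
        if a == b:
            continue
        rect_planes.append(angle_deviation(
            planes[(a, sa)].normal, planes[(b, sb)].normal,
            mode="perpendicular",
        ))
    rect_planes = np.array(rect_planes)

    # Edges meeting at each corner: for corner s, the edge along axis a is
    # the intersection line of the two faces selected by the other axes.
    rect_edges = []
    for signs in itertools.product((-1, 1), repeat=3):
        dirs = []
        for a in range(3):
            b, c = [x for x in range(3) if x != a]
            _, d = intersect_planes(
                planes[(b, signs[b])], planes[(c, signs[c])]
            )
            dirs.append(d)
        for da, db in itertools.combinations(dirs, 2):
            rect_edges.append(angle_deviation(da, db, mode="perpendicular"))
    rect_edges = np.array(rect_edges)

    return GeometryReport(
        edge_lengths_mm={a: np.array(v) for a, v in edge_lengths.items()},
        reference_lengths_mm={a: float(ref[a]) for a in range(3)},
        length_error_pct_in_plane=np.array(err_in_plane),
        length_error_pct_grinding=np.array(err_grinding),
        parallelism_deg=parallelism,
        rectangularity_planes_deg=rect_planes,
        rectangularity_edges_deg=rect_edges,
        corners_mm={s: c for s, c in corners.items()},
    )


def measure_reference_object(
    stack: ReconstructedStack,
    reference_edges_mm: np.ndarray,
    threshold: float,
    channel: int = 0,
    object_side: str = "above",
    n_points: int = 20,
    seed: int = 0,
) -> tuple[GeometryReport, dict]:
    """End of the evaluation chain: segment, fit all six faces, report.

    ``reference_edges_mm`` are the true cuboid edge lengths in any order;
    they are matched to the principal axes of the segmented object by
    decreasing extent.  Returns the report and the fitted face planes.
    """
    volume = threshold_segment(stack, threshold, channel=channel,
                               object_side=object_side)
    axes, _ = estimate_cuboid_axes(volume)
    ref_sorted = np.sort(np.asarray(reference_edges_mm, dtype=float))[::-1]

    planes: dict = {}
    for face in FACE_IDS:
        axis, sign = face
        pts = sample_face_points(
            volume, face, n_points=n_points,
            seed=seed + 7919 * FACE_IDS.index(face), axes=axes,
        )
        planes[face] = fit_plane(pts).oriented(sign * axes[:, axis])
    report = geometry_report(planes, ref_sorted)
    return report, planes
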