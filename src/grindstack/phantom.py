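"""Synthetic serial-microgrinding phantom.

Emulates the digitised grinding surfaces of a specimen embedded in an opaque
epoxy cylinder: three high-contrast cylindrical fiducial pins (nominally
perpendicular to the grinding plane, optionally tilted), an embedded cuboid
reference object of known dimensions, and circumferential grooves.  Every
slice is rendered under a random per-slice similarity transform (manual
repositioning under the macroscope) and each grinding step removes a slightly
random amount of material around the 100 µm nominal.

The generator returns full ground truth (true transforms, true marker
centres, true abrasions, analytic cuboid geometry) so that every downstream
stage — detection, registration, stack assembly, geometric metrology — can be
validated without external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .register import SimilarityTransform2D
from .stack import AbrasionLedger, build_ledger

__all__ = [
    "ColorScheme",
    "REFERENCE_SCHEME",
    "SPECIMEN_SCHEME",
    "PhantomSpec",
    "PhantomValidationError",
    "NoiseModel",
    "Phantom",
    "GroundTruth",
    "SliceSeries",
    "make_phantom",
    "render_slice",
    "draw_abrasions",
    "simulate_grinding",
    "MATERIAL_OUTSIDE",
    "MATERIAL_EPOXY",
    "MATERIAL_MARKER",
    "MATERIAL_TISSUE",
    "MATERIAL_GROOVE",
]

# Material labels: every queried point receives exactly one of these.
MATERIAL_OUTSIDE = 0
MATERIAL_EPOXY = 1
MATERIAL_MARKER = 2
MATERIAL_TISSUE = 3
MATERIAL_GROOVE = 4


class PhantomValidationError(ValueError):
    """A phantom specification violates one of its invariants."""


@dataclass(frozen=True)
class ColorScheme:
    """8-bit RGB colours per material label."""

    background: tuple[int, int, int]
    marker: tuple[int, int, int]
    tissue: tuple[int, int, int]
    outside: tuple[int, int, int] = (6, 6, 6)
    groove: tuple[int, int, int] = (0, 0, 0)

    def lut(self) -> np.ndarray:
        out = np.zeros((5, 3), dtype=np.uint8)
        out[MATERIAL_OUTSIDE] = self.outside
        out[MATERIAL_EPOXY] = self.background
        out[MATERIAL_MARKER] = self.marker
        out[MATERIAL_TISSUE] = self.tissue
        out[MATERIAL_GROOVE] = self.groove
        return out


#: Reference-object run: epoxy dyed dark blue, white pins, red reference brick.
REFERENCE_SCHEME = ColorScheme(
    background=(28, 34, 116), marker=(250, 250, 250), tissue=(208, 42, 52)
)
#: Specimen run: TiO2-whitened epoxy, black pins, acid-violet stained tissue.
SPECIMEN_SCHEME = ColorScheme(
    background=(233, 228, 222), marker=(14, 14, 14), tissue=(148, 58, 146)
)


def _rotation_matrix(rotation_deg: tuple[float, float, float]) -> np.ndarray:
    """Euler xyz rotation (R = Rz @ Ry @ Rx), degrees."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of the embedded specimen.

    Lengths are millimetres in the specimen frame: x/y span the grinding
    plane (origin on the cylinder axis), z increases with grinding depth and
    z = 0 is the first exposed surface.  The cuboid reference object sits
    near the cylinder axis with a small default rotation against the grinding
    axis — a hand-embedded object is never machine-aligned, and the oblique
    pose spreads its end faces over several slices.
    """

    cylinder_diameter_mm: float = 30.0
    cylinder_height_mm: float = 40.0
    marker_diameter_mm: float = 3.2
    marker_centers_mm: tuple[tuple[float, float], ...] = (
        (5.2, 0.2), (-2.4, 4.4), (-2.8, -4.5),
    )
    #: Lateral drift of each pin centre per unit depth (mm/mm); zero for
    #: pins drilled perfectly perpendicular to the grinding plane.
    marker_tilt_mm_per_mm: tuple[tuple[float, float], ...] = (
        (0.0, 0.0), (0.0, 0.0), (0.0, 0.0),
    )
    cuboid_center_mm: tuple[float, float, float] = (0.0, 0.0, 7.6)
    cuboid_edges_mm: tuple[float, float, float] = (5.6, 4.4, 12.8)
    cuboid_rotation_deg: tuple[float, float, float] = (3.0, 4.0, 2.0)
    groove_angles_deg: tuple[float, ...] = (15.0, 135.0, 255.0)
    groove_radius_mm: float = 0.6
    colors: ColorScheme = REFERENCE_SCHEME
    pixel_spacing_um_per_px: float = 16.0
    image_size_px: tuple[int, int] = (1280, 1280)

    def __post_init__(self) -> None:
        if self.marker_diameter_mm <= 0:
            raise PhantomValidationError("marker_diameter_mm must be positive")
        if self.pixel_spacing_um_per_px <= 0:
            raise PhantomValidationError("pixel_spacing must be positive")
        if self.cylinder_diameter_mm <= 0 or self.cylinder_height_mm <= 0:
            raise PhantomValidationError("cylinder dimensions must be positive")
        if any(e <= 0 for e in self.cuboid_edges_mm):
            raise PhantomValidationError("cuboid edges must be positive")
        centers = np.asarray(self.marker_centers_mm, dtype=float)
        if centers.shape != (3, 2):
            raise PhantomValidationError("exactly three marker centres required")
        if len(np.unique(centers, axis=0)) != 3:
            raise PhantomValidationError("marker centres must be pairwise distinct")
        d1 = centers[1] - centers[0]
        d2 = centers[2] - centers[0]
        area2 = abs(d1[0] * d2[1] - d1[1] * d2[0])
        if area2 < 1e-9:
            raise PhantomValidationError("marker centres must be non-collinear")
        r_cyl = self.cylinder_diameter_mm / 2.0
        r_marker = self.marker_diameter_mm / 2.0
        tilt = np.asarray(self.marker_tilt_mm_per_mm, dtype=float)
        if tilt.shape != (3, 2):
            raise PhantomValidationError("need one tilt vector per marker")
        for z in (0.0, self.cylinder_height_mm):
            drifted = centers + tilt * z
            radii = np.linalg.norm(drifted, axis=1)
            if np.any(radii + r_marker >= r_cyl):
                raise PhantomValidationError(
                    "marker does not lie strictly inside the cylinder"
                )
        corners = self.cuboid_corners_mm()
        if np.any(np.linalg.norm(corners[:, :2], axis=1) >= r_cyl):
            raise PhantomValidationError(
                "cuboid does not lie strictly inside the cylinder"
            )
        if np.any(corners[:, 2] < 0) or np.any(corners[:, 2] > self.cylinder_height_mm):
            raise PhantomValidationError("cuboid exceeds the cylinder height")

    # -- analytic cuboid geometry -----------------------------------------

    def cuboid_rotation(self) -> np.ndarray:
        return _rotation_matrix(self.cuboid_rotation_deg)

    def cuboid_corners_mm(self) -> np.ndarray:
        """The 8 corner points in the specimen frame, shape (8, 3)."""
        R = self.cuboid_rotation()
        c = np.asarray(self.cuboid_center_mm)
        h = np.asarray(self.cuboid_edges_mm) / 2.0
        signs = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
            dtype=float,
        )
        return c + (signs * h) @ R.T

    def cuboid_axes(self) -> np.ndarray:
        """Unit edge directions in the specimen frame (columns of R)."""
        return self.cuboid_rotation()

    def known_marker_distances_mm(self) -> np.ndarray:
        """The three pairwise pin distances (0-1, 0-2, 1-2), from the CNC plan."""
        c = np.asarray(self.marker_centers_mm)
        return np.array([
            np.linalg.norm(c[0] - c[1]),
            np.linalg.norm(c[0] - c[2]),
            np.linalg.norm(c[1] - c[2]),
        ])


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic imperfections of the manual grinding/imaging loop.

    ``abrasion_bias_um``/``abrasion_sd_um`` model systematic and random
    deviation of each grinding step from the nominal; per-slice transforms
    are drawn uniformly within the stated ranges (manual repositioning and
    refocusing); ``detection_jitter_px`` shifts each rendered marker disk by
    a uniform per-slice offset, emulating boundary localisation noise.
    ``measurement_sd_um`` optionally corrupts the tactile abrasion readings
    recorded in the ledger (the true abrasions stay in the ground truth).
    """

    abrasion_bias_um: float = 2.0
    abrasion_sd_um: float = 3.0
    rotation_deg: float = 5.0
    translation_px: float = 20.0
    scale_fraction: float = 0.01
    detection_jitter_px: float = 0.2
    measurement_sd_um: float = 0.0
    seed: int = 0

    def validate(self, nominal_um: float) -> None:
        if self.abrasion_sd_um < 0:
            raise ValueError("abrasion_sd_um must be non-negative")
        if self.scale_fraction < 0 or self.scale_fraction >= 1:
            raise ValueError("scale_fraction must lie in [0, 1)")
        if self.detection_jitter_px < 0 or self.measurement_sd_um < 0:
            raise ValueError("jitter/measurement noise must be non-negative")
        if nominal_um + self.abrasion_bias_um - 3 * self.abrasion_sd_um <= 0:
            raise ValueError(
                "abrasion must stay strictly positive "
                "(nominal + bias - 3*sd <= 0)"
            )


class Phantom:
    """Analytic phantom; query any specimen-frame point for its material."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec

    @property
    def depth_mm(self) -> float:
        return self.spec.cylinder_height_mm

    def marker_centers_mm_at(self, z_um: float) -> np.ndarray:
        """Pin centres (3, 2) at depth ``z_um``, following any tilt."""
        c = np.asarray(self.spec.marker_centers_mm, dtype=float)
        tilt = np.asarray(self.spec.marker_tilt_mm_per_mm, dtype=float)
        return c + tilt * (z_um / 1000.0)

    def material(
        self,
        x_mm: np.ndarray,
        y_mm: np.ndarray,
        z_um: float,
        marker_offsets_mm: np.ndarray | None = None,
    ) -> np.ndarray:
        """Material label for each (x, y) point of the surface at ``z_um``.

        Labels partition the plane: outside the cylinder, epoxy, marker pin,
        reference-object (tissue) or groove.  ``marker_offsets_mm`` adds a
        per-marker lateral displacement (rendering jitter).
        """
        if not (0.0 <= z_um <= self.depth_mm * 1000.0):
            raise ValueError(
                f"z={z_um} µm outside the phantom depth "
                f"[0, {self.depth_mm * 1000.0}] µm"
            )
        spec = self.spec
        x = np.asarray(x_mm, dtype=np.float32)
        y = np.asarray(y_mm, dtype=np.float32)
        labels = np.full(x.shape, MATERIAL_EPOXY, dtype=np.uint8)
        flat_x, flat_y, flat_l = x.ravel(), y.ravel(), labels.ravel()

        def _in_box(xmin, xmax, ymin, ymax):
            return ((flat_x >= xmin) & (flat_x <= xmax)
                    & (flat_y >= ymin) & (flat_y <= ymax))

        r_cyl = spec.cylinder_diameter_mm / 2.0
        # Only points that can be outside the cylinder need the radius test.
        cand = ~_in_box(-r_cyl / np.sqrt(2), r_cyl / np.sqrt(2),
                        -r_cyl / np.sqrt(2), r_cyl / np.sqrt(2))
        if cand.any():
            xs, ys = flat_x[cand], flat_y[cand]
            flat_l[np.nonzero(cand)[0][xs * xs + ys * ys >= r_cyl**2]] = (
                MATERIAL_OUTSIDE
            )

        # Circumferential grooves: notches milled into the cylinder surface.
        gr = spec.groove_radius_mm
        for ang in spec.groove_angles_deg:
            a = np.deg2rad(ang)
            gx, gy = r_cyl * np.cos(a), r_cyl * np.sin(a)
            cand = _in_box(gx - gr, gx + gr, gy - gr, gy + gr)
            if not cand.any():
                continue
            ci = np.nonzero(cand)[0]
            xs, ys = flat_x[ci], flat_y[ci]
            hit = ((xs - gx) ** 2 + (ys - gy) ** 2 < gr**2) & (
                xs * xs + ys * ys < r_cyl**2
            )
            flat_l[ci[hit]] = MATERIAL_GROOVE

        # Reference cuboid, tested in its own frame within its bounding box.
        R = spec.cuboid_rotation()
        c = np.asarray(spec.cuboid_center_mm)
        h = np.asarray(spec.cuboid_edges_mm) / 2.0
        corners = self.spec.cuboid_corners_mm()
        cand = _in_box(corners[:, 0].min(), corners[:, 0].max(),
                       corners[:, 1].min(), corners[:, 1].max())
        if cand.any():
            ci = np.nonzero(cand)[0]
            d = np.empty((len(ci), 3), dtype=np.float64)
            d[:, 0] = flat_x[ci] - c[0]
            d[:, 1] = flat_y[ci] - c[1]
            d[:, 2] = z_um / 1000.0 - c[2]
            local = d @ R  # == R.T applied to each row vector
            inside = np.all(np.abs(local) <= h, axis=-1)
            flat_l[ci[inside]] = MATERIAL_TISSUE

        # Fiducial pins win over everything inside the cylinder: they are
        # drilled after embedding.
        centers = self.marker_centers_mm_at(z_um)
        if marker_offsets_mm is not None:
            centers = centers + np.asarray(marker_offsets_mm, dtype=float)
        mr = spec.marker_diameter_mm / 2.0
        for cx, cy in centers:
            cand = _in_box(cx - mr, cx + mr, cy - mr, cy + mr)
            if not cand.any():
                continue
            ci = np.nonzero(cand)[0]
            xs, ys = flat_x[ci], flat_y[ci]
            hit = (xs - cx) ** 2 + (ys - cy) ** 2 < mr * mr
            flat_l[ci[hit]] = MATERIAL_MARKER
        return labels


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Validate ``spec`` and return the analytic phantom (default spec if None)."""
    if spec is None:
        spec = PhantomSpec()
    return Phantom(spec)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SS = 4  # supersampling factor per axis (4x4 samples per boundary pixel)


def render_slice(
    phantom: Phantom,
    z_um: float,
    transform: SimilarityTransform2D,
    image_size_px: tuple[int, int] | None = None,
    marker_offsets_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Render the grinding surface at depth ``z_um`` as an 8-bit RGB image.

    ``transform`` maps specimen-frame pixel coordinates (mm * 1000 / pixel
    spacing) to image pixel coordinates; each image pixel takes the colour of
    the material at the inverse-transformed specimen position.  Material
    boundaries are anti-aliased by exact 4x4 supersampling, evaluated only on
    pixels adjacent to a label change (identical to supersampling everywhere,
    since the interior of a material region is constant).
    """
    spec = phantom.spec
    if image_size_px is None:
        image_size_px = spec.image_size_px
    h, w = image_size_px
    inv = transform.inverse()
    mm_per_px = spec.pixel_spacing_um_per_px / 1000.0

    # The inverse map on a regular grid is separable: build it from 1D axes.
    lin = (inv.linear * mm_per_px).astype(np.float32)
    t = (np.asarray(inv.translation_px) * mm_per_px).astype(np.float32)
    xs = np.arange(w, dtype=np.float32)
    ys = np.arange(h, dtype=np.float32)
    src_x = lin[0, 0] * xs[None, :] + lin[0, 1] * ys[:, None] + t[0]
    src_y = lin[1, 0] * xs[None, :] + lin[1, 1] * ys[:, None] + t[1]
    labels = phantom.material(
        src_x, src_y, z_um, marker_offsets_mm=marker_offsets_mm,
    )

    lut = spec.colors.lut().astype(np.float64)
    out = lut[labels]

    # Pixels whose 4-neighbourhood crosses a label change get supersampled.
    edge = np.zeros((h, w), dtype=bool)
    edge[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    edge[:, :-1] |= labels[:, 1:] != labels[:, :-1]
    edge[1:, :] |= labels[1:, :] != labels[:-1, :]
    edge[:-1, :] |= labels[1:, :] != labels[:-1, :]
    for _ in range(2):
        grown = edge.copy()
        grown[1:, :] |= edge[:-1, :]
        grown[:-1, :] |= edge[1:, :]
        grown[:, 1:] |= edge[:, :-1]
        grown[:, :-1] |= edge[:, 1:]
        edge = grown

    ey, ex = np.nonzero(edge)
    if len(ey):
        offs = ((np.arange(_SS) + 0.5) / _SS - 0.5).astype(np.float32)
        ox, oy = np.meshgrid(offs, offs)
        sub_px = (ex[:, None] + ox.ravel()[None, :]).ravel().astype(np.float32)
        sub_py = (ey[:, None] + oy.ravel()[None, :]).ravel().astype(np.float32)
        sub_x = lin[0, 0] * sub_px + lin[0, 1] * sub_py + t[0]
        sub_y = lin[1, 0] * sub_px + lin[1, 1] * sub_py + t[1]
        sub_labels = phantom.material(
            sub_x, sub_y, z_um,
            marker_offsets_mm=marker_offsets_mm,
        )
        sub_colors = lut[sub_labels].reshape(len(ey), _SS * _SS, 3)
        out[ey, ex] = sub_colors.mean(axis=1)

    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Series simulation
# ---------------------------------------------------------------------------

@dataclass
class SliceSeries:
    """An ordered series of grinding-surface images (8-bit RGB)."""

    images: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.images)

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write numbered TIFF files ``slice_0000.tif`` ... into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, img in enumerate(self.images):
            p = out / f"slice_{i:04d}.tif"
            tifffile.imwrite(p, img)
            paths.append(p)
        return paths

    @classmethod
    def read(cls, in_dir: str | Path) -> "SliceSeries":
        paths = sorted(Path(in_dir).glob("slice_*.tif"))
        if not paths:
            raise FileNotFoundError(f"no slice_*.tif files in {in_dir}")
        return cls(images=[tifffile.imread(p) for p in paths])


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover."""

    true_transforms: list[SimilarityTransform2D]
    true_abrasions_um: np.ndarray
    slice_z_um: np.ndarray
    true_marker_centers_px: np.ndarray  # (n_slices, 3, 2), jitter-free
    spec: PhantomSpec

    def __post_init__(self) -> None:
        self.true_abrasions_um = np.asarray(self.true_abrasions_um, dtype=float)
        self.slice_z_um = np.asarray(self.slice_z_um, dtype=float)
        self.true_marker_centers_px = np.asarray(
            self.true_marker_centers_px, dtype=float
        )
        if self.slice_z_um[0] != 0:
            raise ValueError("slice_z_um must start at 0")
        if np.any(np.diff(self.slice_z_um) <= 0):
            raise ValueError("slice_z_um must be strictly increasing")
        if len(self.slice_z_um) != len(self.true_abrasions_um) + 1:
            raise ValueError("need exactly n_slices - 1 abrasions")

    def to_json(self, path: str | Path) -> None:
        data = {
            "true_transforms": [
                {
                    "scale": t.scale,
                    "rotation_deg": t.rotation_deg,
                    "translation_px": list(t.translation_px),
                }
                for t in self.true_transforms
            ],
            "true_abrasions_um": self.true_abrasions_um.tolist(),
            "slice_z_um": self.slice_z_um.tolist(),
            "true_marker_centers_px": self.true_marker_centers_px.tolist(),
            "spec": _spec_to_jsonable(self.spec),
        }
        Path(path).write_text(json.dumps(data, indent=1))


def _spec_to_jsonable(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["colors"] = dataclasses.asdict(spec.colors)
    return d


def draw_abrasions(
    rng: np.random.Generator,
    n_steps: int,
    nominal_um: float,
    noise: NoiseModel,
) -> np.ndarray:
    """Per-step abrasion: nominal + bias + N(0, sd), truncated at 1 µm."""
    a = nominal_um + noise.abrasion_bias_um + rng.normal(
        0.0, noise.abrasion_sd_um, size=n_steps
    )
    return np.maximum(a, 1.0)


def simulate_grinding(
    phantom: Phantom,
    n_slices: int,
    nominal_um: float = 100.0,
    noise: NoiseModel | None = None,
) -> tuple[SliceSeries, AbrasionLedger, GroundTruth]:
    """Simulate the full manual grinding/imaging loop.

    Each step removes ``nominal + bias + N(0, sd)`` micrometres (truncated at
    1 µm so abrasion is strictly positive); each exposed surface is rendered
    under an independently drawn similarity transform (the first slice is the
    base image).  The returned ledger holds the measured abrasions — exact
    copies of the true ones unless ``measurement_sd_um`` is set.  Fully
    reproducible from ``noise.seed``.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if noise is None:
        noise = NoiseModel()
    noise.validate(nominal_um)
    rng = np.random.default_rng(noise.seed)
    spec = phantom.spec

    abrasions = draw_abrasions(rng, n_slices - 1, nominal_um, noise)
    z_um = np.concatenate([[0.0], np.cumsum(abrasions)])
    if z_um[-1] > phantom.depth_mm * 1000.0:
        raise ValueError("grinding depth exceeds the phantom height")

    h, w = spec.image_size_px
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    mm_per_px = spec.pixel_spacing_um_per_px / 1000.0

    transforms: list[SimilarityTransform2D] = []
    images: list[np.ndarray] = []
    true_centers = np.empty((n_slices, 3, 2))
    for i in range(n_slices):
        s = 1.0 + rng.uniform(-noise.scale_fraction, noise.scale_fraction)
        rot = rng.uniform(-noise.rotation_deg, noise.rotation_deg)
        t = center + rng.uniform(-noise.translation_px, noise.translation_px, 2)
        tf = SimilarityTransform2D(scale=s, rotation_deg=rot,
                                   translation_px=tuple(t))
        transforms.append(tf)

        jitter_px = rng.uniform(
            -noise.detection_jitter_px, noise.detection_jitter_px, (3, 2)
        )
        img = render_slice(
            phantom, z_um[i], tf,
            marker_offsets_mm=jitter_px * mm_per_px,
        )
        images.append(img)
        true_centers[i] = tf.apply(
            phantom.marker_centers_mm_at(z_um[i]) / mm_per_px
        )

    measured = abrasions.copy()
    if noise.measurement_sd_um > 0:
        measured = np.maximum(
            measured + rng.normal(0.0, noise.measurement_sd_um, measured.shape),
            1.0,
        )
    ledger = build_ledger(measured, nominal_um=nominal_um)
    truth = GroundTruth(
        true_transforms=transforms,
        true_abrasions_um=abrasions,
        slice_z_um=z_um,
        true_marker_centers_px=true_centers,
        spec=spec,
    )
    return SliceSeries(images=images), ledger, truth
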