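"""End-to-end reconstruction pipeline and the synthetic validation run.

Chains the stages in the order the method runs on real data: calibrate the
colour filter on the base image, detect the three fiducials on every slice,
label them consistently across slices, register everything onto the base
image (optionally with the tilt-compensated second pass), derive the metric
pixel spacing from the known inter-marker distances, assemble the aligned
slices at their measured depths, and evaluate the embedded reference object.

``run_synthetic_experiment`` wires the phantom generator into this pipeline
and compares every recovered quantity against the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import geometry as geo
from . import markers as mk
from . import register as reg
from . import stack as st
from .phantom import (
    NoiseModel, Phantom, PhantomSpec, SliceSeries, make_phantom,
    simulate_grinding,
)

__all__ = [
    "ReconstructionResult",
    "reconstruct_series",
    "run_synthetic_experiment",
]

_AMBIGUITY_PX = 5.0


class MarkerLabelError(RuntimeError):
    """Marker correspondence across slices could not be resolved safely."""


def _match_markers(
    detected: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Assign 3 detected centres to 3 reference positions (labels).

    Optimal assignment by total distance; two assignments whose candidate
    distances differ by less than 5 px are treated as ambiguous and raise
    instead of guessing.
    """
    cost = np.linalg.norm(detected[:, None, :] - reference[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    for r, c in zip(rows, cols):
        rivals = cost[r, [j for j in range(3) if j != c]]
        if np.any(np.abs(rivals - cost[r, c]) < _AMBIGUITY_PX):
            raise MarkerLabelError(
                "ambiguous marker correspondence "
                f"(two assignments within {_AMBIGUITY_PX} px)"
            )
    out = np.empty_like(detected)
    out[cols] = detected[rows]
    return out


@dataclass
class ReconstructionResult:
    """Everything the reconstruction produced, plus per-stage diagnostics."""

    track: reg.MarkerTrack
    transforms: list
    fre_px: np.ndarray
    pixel_spacing_um_per_px: float
    stack: st.ReconstructedStack
    color_filter: mk.ColorFilterParams
    detections: list
    tilt: reg.TiltEstimate | None = None
    first_pass_transforms: list | None = None
    distance_check: reg.DistanceCheck | None = None


def reconstruct_series(
    series: SliceSeries,
    ledger: st.AbrasionLedger,
    marker_mm: np.ndarray,
    seed_points_px: np.ndarray,
    radius_range_px: tuple[float, float],
    filter_tolerance: float = 0.08,
    tilt_correction: bool = False,
    crop_half_px: int = 280,
    mask_markers: bool = True,
) -> ReconstructionResult:
    """Register a slice series onto its base image and assemble the stack.

    ``marker_mm`` are the known metric distances of the marker pairs (0-1),
    (0-2), (1-2) *in the labelling established by the base image detection
    order*.  ``seed_points_px`` are the manually marked marker positions on
    the base image used to calibrate the colour filter.  The aligned stack
    is cropped to a ``2*crop_half_px`` square about the marker centroid (the
    region holding the relevant structures); with ``mask_markers`` the
    fiducial disks themselves are painted out with black so they cannot leak
    into a later threshold segmentation.
    """
    if len(series) != ledger.n_slices:
        raise ValueError(
            f"{len(series)} images but ledger describes {ledger.n_slices}"
        )
    base = series.images[0]
    color_filter = mk.build_color_filter(base, seed_points_px,
                                         tolerance=filter_tolerance)

    # Detect and label every slice, propagating labels with the running
    # transform estimate (nearest neighbour under the previous slice's map).
    detections: list = []
    all_centers = np.empty((len(series), 3, 2))
    all_radii = np.empty((len(series), 3))
    base_centers: np.ndarray | None = None
    prev_tf = reg.SimilarityTransform2D.identity()
    for i, img in enumerate(series.images):
        dets = mk.detect_markers(img, color_filter, radius_range_px)
        detections.append(dets)
        centers = np.array([d.center_px for d in dets])
        radii = np.array([d.radius_px for d in dets])
        if i == 0:
            base_centers = centers
            matched = centers
        else:
            mapped = prev_tf.apply(centers)
            order_cost = np.linalg.norm(
                mapped[:, None, :] - base_centers[None, :, :], axis=2
            )
            rows, cols = linear_sum_assignment(order_cost)
            matched = np.empty_like(centers)
            matched[cols] = centers[rows]
            radii_m = np.empty_like(radii)
            radii_m[cols] = radii[rows]
            radii = radii_m
            # Ambiguity guard on the mapped configuration.
            _match_markers(mapped, base_centers)
        all_centers[i] = matched
        all_radii[i] = radii
        tf, _ = reg.estimate_similarity(matched, base_centers)
        prev_tf = tf

    track = reg.MarkerTrack(centers_px=all_centers, z_um=ledger.z_um)

    tilt: reg.TiltEstimate | None = None
    first_pass: list | None = None
    if tilt_correction:
        first_pass, _ = reg.register_track(track, base_centers)
        tilt, transforms, fres = reg.estimate_tilt_and_correct(
            track, base_centers
        )
    else:
        transforms, fres = reg.register_track(track, base_centers)

    # Metric scale from the base image and the known pin distances.
    base_px = np.array([
        np.linalg.norm(base_centers[i] - base_centers[j])
        for i, j in reg.MARKER_PAIRS
    ])
    spacing = reg.compute_pixel_spacing(base_px, marker_mm)
    check = reg.check_marker_distances(track, marker_mm, spacing)

    # Warp directly into the evaluation crop about the marker centroid.
    centroid = base_centers.mean(axis=0)
    x0 = int(round(centroid[0])) - crop_half_px
    y0 = int(round(centroid[1])) - crop_half_px
    side = 2 * crop_half_px
    shift = reg.SimilarityTransform2D(translation_px=(-x0, -y0))
    aligned: list[np.ndarray] = []
    for i, img in enumerate(series.images):
        tf_crop = shift.compose(transforms[i])
        warped, _ = reg.apply_transform(img, tf_crop, out_size=(side, side))
        if mask_markers:
            registered = transforms[i].apply(all_centers[i])
            yy, xx = np.mgrid[0:side, 0:side]
            for k in range(3):
                cx, cy = registered[k] - (x0, y0)
                rad = 1.2 * all_radii[i][k] * transforms[i].scale
                disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
                warped[disk] = 0
        aligned.append(warped)

    stk = st.assemble_stack(
        aligned, ledger, spacing,
        provenance={
            "crop_origin_px": (x0, y0),
            "tilt_correction": bool(tilt_correction),
        },
    )
    return ReconstructionResult(
        track=track,
        transforms=transforms,
        fre_px=fres,
        pixel_spacing_um_per_px=spacing,
        stack=stk,
        color_filter=color_filter,
        detections=detections,
        tilt=tilt,
        first_pass_transforms=first_pass,
        distance_check=check,
    )


# ---------------------------------------------------------------------------
# Synthetic end-to-end experiment
# ---------------------------------------------------------------------------

def _label_permutation(
    detected_base: np.ndarray, truth_base: np.ndarray
) -> np.ndarray:
    """perm[label] = phantom marker index, matched by nearest neighbour."""
    cost = np.linalg.norm(
        detected_base[:, None, :] - truth_base[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(3, dtype=int)
    perm[rows] = cols
    return perm


def run_synthetic_experiment(
    spec: PhantomSpec | None = None,
    n_slices: int = 150,
    nominal_um: float = 100.0,
    noise: NoiseModel | None = None,
    tilt_correction: bool = False,
    segmentation_threshold: float = 120.0,
    crop_half_px: int = 280,
    eval_seed: int = 0,
) -> dict:
    """Phantom -> detect -> register -> stack -> segment -> report, vs truth.

    Returns a dictionary with the reconstruction result, the geometry
    report(s) and ground-truth comparisons (marker detection error,
    registration recovery error, pixel-spacing recovery, abrasion error
    statistics).  With ``tilt_correction`` the uncorrected geometry report is
    computed as well, so the benefit of the second pass is measurable.
    """
    phantom = make_phantom(spec)
    spec = phantom.spec
    if noise is None:
        noise = NoiseModel()
    series, ledger, truth = simulate_grinding(
        phantom, n_slices, nominal_um=nominal_um, noise=noise
    )

    r_px = spec.marker_diameter_mm * 1000.0 / spec.pixel_spacing_um_per_px / 2.0
    radius_range = (0.8 * r_px, 1.2 * r_px)
    seed_points = truth.true_marker_centers_px[0]

    # Known CNC distances must follow the detector's labelling, which is
    # established by the base image; permute accordingly.
    base_dets = mk.detect_markers(
        series.images[0],
        mk.build_color_filter(series.images[0], seed_points),
        radius_range,
    )
    base_centers = np.array([d.center_px for d in base_dets])
    perm = _label_permutation(base_centers, truth.true_marker_centers_px[0])
    true_mm = spec.known_marker_distances_mm()  # pairs (0-1), (0-2), (1-2)
    pair_lookup = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
    marker_mm = np.array([
        true_mm[pair_lookup[tuple(sorted((perm[i], perm[j])))]]
        for i, j in reg.MARKER_PAIRS
    ])

    result = reconstruct_series(
        series, ledger, marker_mm, seed_points, radius_range,
        tilt_correction=tilt_correction, crop_half_px=crop_half_px,
    )

    # --- ground-truth comparisons -------------------------------------
    truth_perm = truth.true_marker_centers_px[:, perm, :]
    detection_err = np.linalg.norm(
        result.track.centers_px - truth_perm, axis=2
    )
    # Alignment recovery: where the true marker positions land under the
    # estimated transforms, versus where the base image truly has them.
    recovery = np.empty(n_slices)
    for i in range(n_slices):
        mapped = result.transforms[i].apply(truth_perm[i])
        if tilt_correction:
            # Tilted pins legitimately drift in the aligned frame; measure
            # against the drift-compensated targets instead of the base.
            target = (result.tilt.intercepts_px
                      + result.tilt.drift_px_per_um * ledger.z_um[i])
        else:
            target = truth_perm[0]
        recovery[i] = np.sqrt(np.mean(np.sum((mapped - target) ** 2, axis=1)))

    out = {
        "spec": spec,
        "noise": noise,
        "ledger": ledger,
        "truth": truth,
        "result": result,
        "error_report": st.error_report(ledger),
        "detection_error_px": detection_err,
        "registration_recovery_px": recovery,
        "pixel_spacing_um_per_px": result.pixel_spacing_um_per_px,
        "pixel_spacing_true": spec.pixel_spacing_um_per_px,
    }

    ref_edges = np.asarray(spec.cuboid_edges_mm)
    report, planes = geo.measure_reference_object(
        result.stack, ref_edges, threshold=segmentation_threshold,
        channel=0, object_side="above", seed=eval_seed,
    )
    out["geometry_report"] = report
    out["face_planes"] = planes

    if tilt_correction:
        uncorrected = reconstruct_series(
            series, ledger, marker_mm, seed_points, radius_range,
            tilt_correction=False, crop_half_px=crop_half_px,
        )
        rep_u, _ = geo.measure_reference_object(
            uncorrected.stack, ref_edges, threshold=segmentation_threshold,
            channel=0, object_side="above", seed=eval_seed,
        )
        out["geometry_report_uncorrected"] = rep_u
        # True drift in base-image pixels per µm of depth, for comparison:
        # lateral mm/mm -> specimen px/µm, then through the base transform's
        # linear part into base-image pixels.
        mm_per_px = spec.pixel_spacing_um_per_px / 1000.0
        tilt_mm = np.asarray(spec.marker_tilt_mm_per_mm, dtype=float)[perm]
        base_lin = truth.true_transforms[0].linear
        out["true_drift_px_per_um"] = (
            (tilt_mm / mm_per_px / 1000.0) @ base_lin.T
        )
    return out
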