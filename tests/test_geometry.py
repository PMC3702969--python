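"""Plane-fit metrology: segmentation, sampling, intersections, report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grindstack as gs
from grindstack.geometry import (
    FACE_IDS, SegmentationError, estimate_cuboid_axes, geometry_report,
)
from grindstack.phantom import _rotation_matrix


def _analytic_planes(center, edges, R):
    """Exact outward-oriented face planes of a rotated cuboid."""
    planes = {}
    for axis, sign in FACE_IDS:
        n = sign * R[:, axis]
        offset = float(n @ (np.asarray(center) + sign * edges[axis] / 2.0
                            * R[:, axis]))
        planes[(axis, sign)] = gs.PlaneFit(
            unit_normal=tuple(n), offset=offset, rms_mm=0.0, n_points=20
        )
    return planes


def _synthetic_volume(edges=(3.2, 2.4, 1.8), rot=(0, 0, 0), spacing=0.05,
                      dz=0.05, pad=8):
    """Binary voxelisation of a rotated cuboid (synthetic stand-in)."""
    R = _rotation_matrix(rot)
    nz = int(round(edges[2] / dz)) + 2 * pad
    ny = int(round(edges[1] / spacing)) + 2 * pad
    nx = int(round(edges[0] / spacing)) + 2 * pad
    z = np.arange(nz) * dz
    yy, xx = np.mgrid[0:ny, 0:nx]
    center = np.array([nx * spacing / 2, ny * spacing / 2, nz * dz / 2])
    mask = np.zeros((nz, ny, nx), dtype=bool)
    h = np.asarray(edges) / 2.0
    for k in range(nz):
        d = np.stack([
            xx * spacing - center[0],
            yy * spacing - center[1],
            np.full_like(xx, z[k], dtype=float) - center[2],
        ], axis=-1)
        local = d @ R
        mask[k] = np.all(np.abs(local) <= h, axis=-1)
    vol = gs.BinaryVolume(mask=mask, pixel_spacing_um_per_px=spacing * 1000,
                          z_um=z * 1000.0)
    return vol, R, center


class TestFitPlane:
    def test_horizontal_plane(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 10, 30),
                               rng.uniform(0, 10, 30),
                               np.full(30, 5.0)])
        fit = gs.fit_plane(pts)
        assert abs(fit.normal[2]) == pytest.approx(1.0, abs=1e-12)
        assert abs(fit.offset) == pytest.approx(5.0, abs=1e-12)
        assert fit.rms_mm == pytest.approx(0.0, abs=1e-12)

    def test_oblique_coplanar_points(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(-5, 5, (40, 2))
        pts = np.column_stack([xy, 1.0 - xy.sum(axis=1)])  # x + y + z = 1
        fit = gs.fit_plane(pts)
        expect = np.ones(3) / np.sqrt(3)
        assert np.allclose(np.abs(fit.normal), expect, atol=1e-9)
        assert fit.rms_mm == pytest.approx(0.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        """TLS plane agrees with an independent eigen-decomposition of the
        scatter matrix to 1e-9."""
        rng = np.random.default_rng(2)
        xy = rng.uniform(-3, 3, (60, 2))
        pts = np.column_stack([xy, 0.3 * xy[:, 0] - 0.7 * xy[:, 1] + 2.0])
        pts += rng.normal(0, 0.01, pts.shape)
        fit = gs.fit_plane(pts)

        centred = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(centred.T @ centred)
        n_oracle = evecs[:, 0]
        assert min(np.linalg.norm(fit.normal - n_oracle),
                   np.linalg.norm(fit.normal + n_oracle)) < 1e-9
        rms_oracle = np.sqrt(evals[0] / len(pts))
        assert fit.rms_mm == pytest.approx(rms_oracle, abs=1e-9)

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0),
                               np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            gs.fit_plane(pts)

    @settings(derandomize=True, max_examples=25)
    @given(rx=st.floats(-180, 180), ry=st.floats(-89, 89),
           rz=st.floats(-180, 180))
    def test_rotation_equivariance(self, rx, ry, rz):
        rng = np.random.default_rng(3)
        xy = rng.uniform(-2, 2, (25, 2))
        pts = np.column_stack([xy, 0.1 * xy[:, 0] + 0.2])
        R = _rotation_matrix((rx, ry, rz))
        f0 = gs.fit_plane(pts)
        f1 = gs.fit_plane(pts @ R.T)
        rotated = R @ f0.normal
        assert min(np.linalg.norm(f1.normal - rotated),
                   np.linalg.norm(f1.normal + rotated)) < 1e-9


class TestIntersections:
    def _plane(self, n, d):
        n = np.asarray(n, dtype=float)
        n = n / np.linalg.norm(n)
        return gs.PlaneFit(unit_normal=tuple(n), offset=d, rms_mm=0.0,
                           n_points=3)

    def test_axis_plane_intersection(self):
        point, direction = gs.intersect_planes(
            self._plane((0, 0, 1), 0.0), self._plane((0, 1, 0), 0.0)
        )
        assert np.allclose(np.abs(direction), (1, 0, 0), atol=1e-12)
        assert np.allclose(point, 0, atol=1e-12)

    def test_parallel_planes_raise(self):
        with pytest.raises(ValueError, match="parallel"):
            gs.intersect_planes(self._plane((0, 0, 1), 0.0),
                                self._plane((0, 0, 1), 1.0))

    def test_line_satisfies_both_equations(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p1 = self._plane(rng.normal(size=3), rng.uniform(-5, 5))
            p2 = self._plane(rng.normal(size=3), rng.uniform(-5, 5))
            if gs.angle_deviation(p1.normal, p2.normal) < 2:
                continue
            point, direction = gs.intersect_planes(p1, p2)
            for lam in (-3.0, 0.0, 7.0):
                q = point + lam * direction
                assert abs(p1.normal @ q - p1.offset) < 1e-9
                assert abs(p2.normal @ q - p2.offset) < 1e-9

    def test_three_axis_planes_meet_at_origin_and_point(self):
        p = gs.intersect_three_planes(
            self._plane((1, 0, 0), 0), self._plane((0, 1, 0), 0),
            self._plane((0, 0, 1), 0))
        assert np.allclose(p, 0, atol=1e-12)
        p = gs.intersect_three_planes(
            self._plane((1, 0, 0), 1), self._plane((0, 1, 0), 2),
            self._plane((0, 0, 1), 3))
        assert np.allclose(p, (1, 2, 3), atol=1e-12)

    def test_near_parallel_triple_ill_conditioned(self):
        th = np.deg2rad(0.1)
        with pytest.raises(ValueError, match="condition"):
            gs.intersect_three_planes(
                self._plane((0, 0, 1), 0),
                self._plane((np.sin(th), 0, np.cos(th)), 0.5),
                self._plane((0, 1, 0), 0),
            )


class TestAngles:
    def test_examples(self):
        assert gs.angle_deviation((0, 0, 1), (0, 0, 1)) == 0.0
        th = np.deg2rad(1.0)
        assert gs.angle_deviation(
            (0, 0, 1), (np.sin(th), 0, np.cos(th))
        ) == pytest.approx(1.0, abs=1e-9)
        assert gs.angle_deviation((1, 0, 0), (0, 1, 0),
                                  mode="perpendicular") == 0.0
        # Folding: opposite vectors are parallel.
        assert gs.angle_deviation((0, 0, 1), (0, 0, -1)) == pytest.approx(
            0.0, abs=1e-6
        )


class TestQuantize:
    @pytest.mark.parametrize("value,expect", [
        (0.04, 0.0), (0.26, 0.3), (0.05, 0.1), (-0.05, -0.1),
        (0.1499, 0.1), (0.15, 0.2), (0.0, 0.0),
    ])
    def test_rounding(self, value, expect):
        assert gs.quantize_deviation(value) == pytest.approx(expect, abs=1e-12)

    def test_step_must_be_positive(self):
        with pytest.raises(ValueError):
            gs.quantize_deviation(1.0, step_mm=0.0)


class TestGeometryReport:
    def test_perfect_cuboid_zero_deviations(self):
        edges = np.array([6.0, 5.0, 3.0])
        R = _rotation_matrix((11.0, -7.0, 23.0))
        planes = _analytic_planes((1.0, -2.0, 4.0), edges, R)
        rep = geometry_report(planes, edges)
        for a in range(3):
            assert np.allclose(rep.edge_lengths_mm[a], edges[a], atol=1e-9)
        assert np.allclose(rep.length_error_pct_in_plane, 0, atol=1e-9)
        assert np.allclose(rep.length_error_pct_grinding, 0, atol=1e-9)
        assert np.allclose(rep.parallelism_deg, 0, atol=1e-9)
        assert np.allclose(rep.rectangularity_planes_deg, 0, atol=1e-9)
        assert np.allclose(rep.rectangularity_edges_deg, 0, atol=1e-9)
        assert rep.mean_angular_deviation_deg() == pytest.approx(0, abs=1e-9)

    def test_sheared_cuboid_shows_tilt(self):
        """Tilting one face pair by 0.5° shows up as ~0.5° rectangularity
        deviation in the affected plane pairs."""
        edges = np.array([6.0, 5.0, 3.0])
        planes = _analytic_planes((0.0, 0.0, 0.0), edges, np.eye(3))
        th = np.deg2rad(0.5)
        tilted = np.array([np.sin(th), 0.0, np.cos(th)])
        for sign in (-1, 1):
            planes[(2, sign)] = gs.PlaneFit(
                unit_normal=tuple(sign * tilted),
                offset=float(sign * tilted @ (0, 0, sign * edges[2] / 2)),
                rms_mm=0.0, n_points=20,
            )
        rep = geometry_report(planes, edges)
        pairs = rep.rectangularity_planes_deg
        assert pairs.max() == pytest.approx(0.5, abs=1e-9)
        # x-z face pairs are affected, y-z pairs are not.
        assert np.sum(np.isclose(pairs, 0.5, atol=1e-9)) == 4
        assert np.allclose(rep.parallelism_deg, 0, atol=1e-9)

    def test_missing_face_rejected(self):
        planes = _analytic_planes((0, 0, 0), np.array([2, 2, 2.0]), np.eye(3))
        del planes[(1, -1)]
        with pytest.raises(ValueError, match="missing"):
            geometry_report(planes, np.array([2, 2, 2.0]))


class TestSegmentationAndSampling:
    def test_voxel_count_matches_analytic_volume(self):
        vol, _, _ = _synthetic_volume(rot=(3, 4, 2))
        assert vol.voxel_volume_mm3() == pytest.approx(
            np.prod([3.2, 2.4, 1.8]), rel=0.02
        )

    def test_threshold_directions_and_empty(self):
        rng = np.random.default_rng(0)
        imgs = [np.full((10, 10, 3), 40, np.uint8) for _ in range(3)]
        imgs[1][2:5, 3:7] = 200
        stack = gs.assemble_stack(imgs, gs.build_ledger([100.0] * 2), 16.0)
        above = gs.threshold_segment(stack, 120, channel=0)
        assert above.mask.sum() == 3 * 4
        below = gs.threshold_segment(stack, 120, channel=0,
                                     object_side="below")
        assert (above.mask & below.mask).sum() == 0
        assert (above.mask | below.mask).all()
        with pytest.raises(SegmentationError):
            gs.threshold_segment(stack, 250, channel=0)

    def test_face_points_count_and_determinism(self):
        vol, R, _ = _synthetic_volume(rot=(3, 4, 2))
        pts1 = gs.sample_face_points(vol, (0, 1), n_points=20, seed=5)
        pts2 = gs.sample_face_points(vol, (0, 1), n_points=20, seed=5)
        pts3 = gs.sample_face_points(vol, (0, 1), n_points=20, seed=6)
        assert pts1.shape == (20, 3)
        assert np.array_equal(pts1, pts2)
        assert not np.array_equal(pts1, pts3)

    def test_sampled_points_lie_near_true_face(self):
        vol, R, center = _synthetic_volume(rot=(3, 4, 2))
        axes, _ = estimate_cuboid_axes(vol)
        edges_sorted = np.array([3.2, 2.4, 1.8])  # already descending
        for axis, sign in FACE_IDS:
            pts = gs.sample_face_points(vol, (axis, sign), seed=1, axes=axes)
            n_est = sign * axes[:, axis]
            # Identify which true face this axis corresponds to.
            dots = np.abs(R.T @ n_est)
            true_axis = int(np.argmax(dots))
            n_true = R[:, true_axis] * np.sign(R[:, true_axis] @ n_est)
            d = (pts - center) @ n_true
            half = edges_sorted[true_axis] / 2
            assert np.all(np.abs(d - half) < 0.08)

    def test_insufficient_face_voxels_rejected(self):
        vol, _, _ = _synthetic_volume(edges=(0.6, 0.5, 0.4), spacing=0.1,
                                      dz=0.1, pad=3)
        with pytest.raises(SegmentationError):
            gs.sample_face_points(vol, (0, 1), n_points=200, seed=0)

    def test_degenerate_face_rejected(self):
        """A one-voxel-thick slab has no usable top/bottom face voxels:
        opposing empty neighbours cancel the local normal."""
        mask = np.zeros((5, 20, 20), dtype=bool)
        mask[2, 4:16, 4:16] = True
        vol = gs.BinaryVolume(mask=mask, pixel_spacing_um_per_px=50.0,
                              z_um=np.arange(5) * 100.0)
        axes = np.eye(3)
        with pytest.raises(SegmentationError):
            gs.sample_face_points(vol, (2, 1), seed=0, axes=axes)
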