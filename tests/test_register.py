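"""Conformal registration, metric calibration and tilt correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grindstack as gs
from grindstack.register import (
    DegenerateConfigurationError, MarkerTrack, DistanceVerdict,
    check_marker_distances, register_track,
)

TRIANGLE = np.array([[120.0, 80.0], [520.0, 110.0], [300.0, 470.0]])

transforms = st.builds(
    gs.SimilarityTransform2D,
    st.floats(0.5, 2.0),
    st.floats(-170.0, 170.0),
    st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
)


class TestEstimateSimilarity:
    def test_identity(self):
        tf, fre = gs.estimate_similarity(TRIANGLE, TRIANGLE)
        assert tf.scale == pytest.approx(1.0, abs=1e-12)
        assert tf.rotation_deg == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.translation_px, 0, atol=1e-9)
        assert fre == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_recovery(self):
        truth = gs.SimilarityTransform2D(1.02, 10.0, (31.0, -7.0))
        tf, fre = gs.estimate_similarity(TRIANGLE, truth.apply(TRIANGLE))
        assert tf.scale == pytest.approx(1.02, abs=1e-9)
        assert tf.rotation_deg == pytest.approx(10.0, abs=1e-9)
        assert np.allclose(tf.translation_px, (31.0, -7.0), atol=1e-9)
        assert fre == pytest.approx(0.0, abs=1e-9)

    def test_collinear_raises(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateConfigurationError):
            gs.estimate_similarity(src, TRIANGLE)

    def test_never_reflects(self):
        dst = TRIANGLE.copy()
        dst[:, 0] *= -1  # mirrored configuration
        tf, fre = gs.estimate_similarity(TRIANGLE, dst)
        assert np.linalg.det(tf.linear) > 0
        assert fre > 0  # a proper similarity cannot reproduce a mirror

    def test_fre_matches_grid_search_oracle(self):
        """Residual of the closed form agrees with a dense search over
        (rotation, scale) with the centroid-optimal translation."""
        rng = np.random.default_rng(4)
        truth = gs.SimilarityTransform2D(0.98, -7.0, (12.0, 40.0))
        dst = truth.apply(TRIANGLE) + rng.normal(0, 0.3, (3, 2))
        tf, fre = gs.estimate_similarity(TRIANGLE, dst)

        best = np.inf
        ms, md = TRIANGLE.mean(axis=0), dst.mean(axis=0)
        for rot in np.arange(-7.5, -6.5, 0.002):
            th = np.deg2rad(rot)
            R = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
            for s in np.arange(0.975, 0.985, 1e-4):
                t = md - s * (R @ ms)
                resid = (TRIANGLE @ (s * R).T + t) - dst
                cost = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
                best = min(best, cost)
        assert fre == pytest.approx(best, abs=1e-4)

    def test_agrees_with_independent_umeyama(self):
        """Cross-check against scikit-image's landmark similarity fit."""
        from skimage.transform import SimilarityTransform as SkSim

        rng = np.random.default_rng(11)
        src = rng.uniform(0, 500, (3, 2))
        dst = rng.uniform(0, 500, (3, 2))
        tf, _ = gs.estimate_similarity(src, dst)
        sk = SkSim.from_estimate(src, dst)
        assert np.allclose(tf.matrix, sk.params, atol=1e-8)


class TestTransformAlgebra:
    @settings(derandomize=True, max_examples=50)
    @given(t=transforms)
    def test_inverse_roundtrip(self, t):
        ident = t.compose(t.inverse())
        assert ident.scale == pytest.approx(1.0, rel=1e-9)
        assert ident.rotation_deg % 360 == pytest.approx(0.0, abs=1e-6) or \
            ident.rotation_deg % 360 == pytest.approx(360.0, abs=1e-6)
        assert np.allclose(ident.translation_px, 0, atol=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(t=transforms)
    def test_forward_backward_estimation_composes_to_identity(self, t):
        dst = t.apply(TRIANGLE)
        fwd, _ = gs.estimate_similarity(TRIANGLE, dst)
        bwd, _ = gs.estimate_similarity(dst, TRIANGLE)
        comp = fwd.compose(bwd)
        assert comp.scale == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(comp.translation_px, 0, atol=1e-5)

    def test_reflection_rejected_by_constructor(self):
        with pytest.raises(ValueError):
            gs.SimilarityTransform2D(scale=-1.0)


class TestApplyTransform:
    def test_identity_is_noop(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (40, 50, 3)).astype(np.uint8)
        out, valid = gs.apply_transform(
            img, gs.SimilarityTransform2D.identity()
        )
        assert np.array_equal(out, img)
        assert valid.all()

    def test_integer_translation_exact(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (40, 50)).astype(np.uint8)
        t = gs.SimilarityTransform2D(translation_px=(7, 3))
        out, valid = gs.apply_transform(img, t)
        assert np.array_equal(out[3:, 7:], img[:37, :43])
        assert not valid[:3, :].any() and not valid[:, :7].any()

    def test_roundtrip_within_interpolation_tolerance(self, default_slice):
        phantom, img, _ = default_slice
        t = gs.SimilarityTransform2D(1.01, 4.0, (9.5, -3.25))
        fwd, _ = gs.apply_transform(img, t)
        back, valid = gs.apply_transform(fwd, t.inverse())
        diff = np.abs(back[200:-200, 200:-200].astype(float)
                      - img[200:-200, 200:-200].astype(float))
        assert diff.mean() < 2.0


class TestPixelSpacing:
    def test_forced_arithmetic(self):
        assert gs.compute_pixel_spacing([750, 750, 750], [12, 12, 12]) == 16.0

    def test_mean_of_ratios_not_ratio_of_means(self):
        px = np.array([738.0, 741.0, 740.0])
        mm = np.array([12.0, 12.0, 12.0])
        expect = np.mean([12000 / 738, 12000 / 741, 12000 / 740])
        got = gs.compute_pixel_spacing(px, mm)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got != pytest.approx(12000 * 3 / px.sum(), abs=1e-9)

    def test_invalid_distances(self):
        with pytest.raises(ValueError):
            gs.compute_pixel_spacing([0.0, 750, 750], [12, 12, 12])

    def test_invariant_under_base_motion(self):
        """A global rotation/translation of the base image leaves the
        spacing estimate unchanged."""
        pts = TRIANGLE
        moved = gs.SimilarityTransform2D(1.0, 33.0, (51.0, -9.0)).apply(pts)
        pairs = [(0, 1), (0, 2), (1, 2)]
        d0 = [np.linalg.norm(pts[i] - pts[j]) for i, j in pairs]
        d1 = [np.linalg.norm(moved[i] - moved[j]) for i, j in pairs]
        mm = [9.0, 8.7, 8.4]
        assert gs.compute_pixel_spacing(d0, mm) == pytest.approx(
            gs.compute_pixel_spacing(d1, mm), abs=1e-9
        )


def _make_track(n=12, scale_px_distances=1.0):
    centers = np.broadcast_to(TRIANGLE * scale_px_distances, (n, 3, 2)).copy()
    z = np.arange(n) * 100.0
    return MarkerTrack(centers_px=centers, z_um=z)


class TestDistanceCheck:
    def _design(self, track, spacing=16.0):
        d = track.pairwise_distances_px()[0]
        return d * spacing / 1000.0

    def test_all_consistent(self):
        tr = _make_track()
        design = self._design(tr)
        res = check_marker_distances(tr, design, 16.0, rel_tolerance=0.01)
        assert res.verdict is DistanceVerdict.ALL_CONSISTENT

    def test_single_outlier_names_pair(self):
        tr = _make_track()
        design = self._design(tr)
        design[0] *= 1.03  # distance 0-1 inflated 3 %
        res = check_marker_distances(tr, design, 16.0, rel_tolerance=0.01)
        assert res.verdict is DistanceVerdict.ONE_OUTLIER
        assert res.outlier_pair == (0, 1)
        assert set(res.conformable_pairs) == {(0, 2), (1, 2)}
        assert "conformable" in res.recommendation

    def test_all_inconsistent(self):
        tr = _make_track()
        design = self._design(tr) * np.array([1.05, 0.94, 1.08])
        res = check_marker_distances(tr, design, 16.0, rel_tolerance=0.01)
        assert res.verdict is DistanceVerdict.ALL_INCONSISTENT


class TestRegistrationRecovery:
    def test_fre_bound_under_bounded_detection_noise(self):
        """With detection noise bounded by 0.3 px per coordinate, the
        fiducial alignment error to ground truth stays below 0.5 px for
        every slice."""
        rng = np.random.default_rng(123)
        n = 150
        worst = 0.0
        for _ in range(3):
            base = TRIANGLE + rng.uniform(-20, 20, (3, 2))
            for _ in range(n):
                t = gs.SimilarityTransform2D(
                    1 + rng.uniform(-0.01, 0.01),
                    rng.uniform(-5, 5),
                    tuple(rng.uniform(-20, 20, 2)),
                )
                detected = t.inverse().apply(base) + rng.uniform(
                    -0.3, 0.3, (3, 2)
                )
                est, fre = gs.estimate_similarity(detected, base)
                recovered = est.apply(t.inverse().apply(base))
                err = np.sqrt(np.mean(np.sum((recovered - base) ** 2, axis=1)))
                worst = max(worst, err)
        assert worst <= 0.5


class TestTiltCorrection:
    def _simulate_track(self, drift_px_per_um, n=150, noise=0.0, seed=0,
                        jitter=(1.0, 5.0, 0.003)):
        """Marker track with per-marker linear drift, random per-slice
        transforms and optional detection noise; returns (track, truth)."""
        rng = np.random.default_rng(seed)
        z = np.cumsum(np.concatenate([[0.0], rng.uniform(95, 109, n - 1)]))
        rot, tr, sc = jitter
        centers = np.empty((n, 3, 2))
        for i in range(n):
            spec_pts = TRIANGLE + drift_px_per_um * z[i]
            t = gs.SimilarityTransform2D(
                1 + rng.uniform(-sc, sc), rng.uniform(-rot, rot),
                tuple(rng.uniform(-tr, tr, 2)),
            )
            centers[i] = t.apply(spec_pts) + rng.uniform(-noise, noise, (3, 2))
        track = MarkerTrack(centers_px=centers, z_um=z)
        return track

    def test_zero_drift_constant_transforms_identical(self):
        n = 20
        centers = np.broadcast_to(TRIANGLE, (n, 3, 2)).copy()
        z = np.arange(n) * 100.0
        track = MarkerTrack(centers_px=centers, z_um=z)
        first, _ = register_track(track, TRIANGLE)
        est, corrected, _ = gs.estimate_tilt_and_correct(track, TRIANGLE)
        assert np.allclose(est.drift_px_per_um, 0, atol=1e-12)
        for a, b in zip(first, corrected):
            assert a.scale == pytest.approx(b.scale, abs=1e-9)
            assert a.rotation_deg == pytest.approx(b.rotation_deg, abs=1e-9)
            assert np.allclose(a.translation_px, b.translation_px, atol=1e-9)

    def test_single_pin_drift_recovered_within_5pct(self):
        drift = np.zeros((3, 2))
        drift[0] = (0.004, 0.009)  # px/µm, one tilted pin
        track = self._simulate_track(drift, noise=0.1, seed=2)
        est, _, _ = gs.estimate_tilt_and_correct(track)
        mag_true = np.linalg.norm(drift[0])
        mag_est = np.linalg.norm(est.drift_px_per_um[0])
        assert abs(mag_est - mag_true) / mag_true <= 0.05

    def test_noise_only_slopes_within_confidence_band(self):
        """Zero-mean detection noise alone: estimated drift magnitudes are
        statistically indistinguishable from zero."""
        noise = 0.3
        track = self._simulate_track(np.zeros((3, 2)), noise=noise, seed=5,
                                     jitter=(0.0, 0.0, 0.0))
        est, _, _ = gs.estimate_tilt_and_correct(track)
        z = track.z_um
        # Regression-slope sampling sd for uniform(-noise, noise) residuals.
        sd = (noise / np.sqrt(3)) / np.sqrt(np.sum((z - z.mean()) ** 2))
        assert np.all(np.abs(est.drift_px_per_um) < 4 * sd)

    def test_needs_five_slices(self):
        track = _make_track(n=4)
        with pytest.raises(ValueError, match="5"):
            gs.estimate_tilt_and_correct(track)
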