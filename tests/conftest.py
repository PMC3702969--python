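"""Shared fixtures: small phantoms and cached renders.

Everything is generated at test time; the heavy fixtures are session-scoped
so renders and detections are reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import grindstack as gs


@pytest.fixture(scope="session")
def well_separated_spec() -> gs.PhantomSpec:
    """Markers placed in the positive quadrant so an identity transform
    keeps all three disks fully inside a 760 px frame."""
    return gs.PhantomSpec(
        marker_centers_mm=((3.0, 3.0), (9.0, 3.0), (6.0, 8.0)),
        cuboid_center_mm=(6.0, 5.0, 7.6),
        cuboid_edges_mm=(2.0, 1.6, 12.8),
        cuboid_rotation_deg=(0.0, 0.0, 0.0),
        image_size_px=(760, 760),
    )


@pytest.fixture(scope="session")
def rendered_identity(well_separated_spec):
    """(phantom, image) rendered at z=500 µm under the identity transform."""
    phantom = gs.make_phantom(well_separated_spec)
    img = gs.render_slice(phantom, 500.0, gs.SimilarityTransform2D.identity())
    return phantom, img


@pytest.fixture(scope="session")
def default_slice():
    """A default-spec slice rendered under a centring transform, with the
    subpixel marker truth, shared by the detection tests."""
    phantom = gs.make_phantom()
    tf = gs.SimilarityTransform2D(1.0, 2.0, (640.0, 640.0))
    z = 5000.0
    img = gs.render_slice(phantom, z, tf)
    mm_per_px = phantom.spec.pixel_spacing_um_per_px / 1000.0
    true_centers = tf.apply(phantom.marker_centers_mm_at(z) / mm_per_px)
    return phantom, img, true_centers


@pytest.fixture(scope="session")
def marker_radius_px():
    spec = gs.PhantomSpec()
    return spec.marker_diameter_mm * 1000.0 / spec.pixel_spacing_um_per_px / 2.0


@pytest.fixture(scope="session")
def small_e2e():
    """A fast 32-slice end-to-end run on a depth-scaled phantom."""
    from grindstack.pipeline import run_synthetic_experiment

    spec = gs.PhantomSpec(
        cuboid_center_mm=(0.0, 0.0, 1.6), cuboid_edges_mm=(5.2, 4.0, 2.4)
    )
    return run_synthetic_experiment(
        spec=spec, n_slices=32, noise=gs.NoiseModel(seed=3)
    )
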