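# grindstack

Fiducial-based 3D reconstruction of serial microgrinding histology, with a
built-in synthetic phantom for validation.

Serial microgrinding produces high-contrast images of both soft and bony
tissue (e.g. the membranous structures of the inner ear) by grinding an
epoxy-embedded specimen away ~100 µm at a time and photographing each
freshly exposed surface.  The method is destructive and every surface is
photographed after manual repositioning, so a spatially correct volume has
to be rebuilt afterwards.  `grindstack` implements that reconstruction for
anyone running (or simulating) such a protocol:

* **Fiducial detection** — three cylindrical pins (3.2 mm ∅) drilled
  perpendicular to the grinding plane appear as circles in every image.
  They are found with an HSV colour filter, median filtering, morphological
  closing and a circular Hough transform, then refined to sub-pixel
  accuracy with Canny edges, a second restricted Hough vote and an
  algebraic (Kåsa) least-squares circle fit.
* **Registration** — every slice is mapped onto the first (base) image by a
  linear conformal transform `p' = s·R(θ)·p + t` (similarity, no
  reflection) fitted in closed form to the three marker centres; a second
  pass can estimate and compensate the linear drift `c(z) = c₀ + m·z` of
  non-perpendicular pins.
* **Metric stack** — slice depths are the cumulative sum of the *measured*
  per-step abrasions (nominal 100 µm steps overshoot in practice); the
  pixel spacing is the mean of (known pin distance in mm) / (pixel distance
  in the base image) over the three pairs.  The stack is exported as a
  DICOM secondary-capture series (slice thickness 0.001 mm, positions in
  mm) readable by clinical planning software.
* **Accuracy evaluation** — an embedded reference cuboid is segmented by
  thresholding; 20 surface points per face are sampled, total-least-squares
  planes fitted, edges and corners derived by plane intersection, and the
  report gives length errors (in grinding plane vs in grinding direction),
  parallelism (vs 0°) and rectangularity (vs 90°) of planes and edges.
* **Phantom** — an analytic generator renders the whole protocol (epoxy
  cylinder, pins with optional tilt, reference cuboid, per-slice random
  repositioning, noisy abrasion) with complete ground truth, so every stage
  is testable without laboratory data.

## Worked example

Simulate a 32-slice grinding series (depth-scaled phantom), run the whole
pipeline against its ground truth, and print the accuracy report:

```python
import grindstack as gs
from grindstack.pipeline import run_synthetic_experiment

spec = gs.PhantomSpec(cuboid_center_mm=(0, 0, 1.6),
                      cuboid_edges_mm=(5.2, 4.0, 2.4))
out = run_synthetic_experiment(spec=spec, n_slices=32,
                               noise=gs.NoiseModel(seed=3))

rep = out["geometry_report"]
print(f"pixel spacing     : {out['pixel_spacing_um_per_px']:.3f} um/px")
print(f"max registration  : {out['registration_recovery_px'].max():.3f} px")
err = out["error_report"]
print(f"abrasion          : {err.abrasion_mean_um:.1f} +/- {err.abrasion_sd_um:.1f} um")
print(f"max accumulated   : {err.max_accumulated_um:.0f} um, type {err.propagation_type}")
for key, row in rep.summary().items():
    print(f"{key:32s}: {row['mean']:.3f} +/- {row['sd']:.3f} (n={row['n']})")
```

prints

```
pixel spacing     : 15.954 um/px
max registration  : 0.365 px
abrasion          : 102.1 +/- 3.4 um
max accumulated   : 65 um, type 1
length_in_plane_pct             : 0.125 +/- 0.029 (n=8)
length_grinding_direction_pct   : 1.041 +/- 0.504 (n=4)
parallelism_planes_deg          : 0.213 +/- 0.314 (n=3)
rectangularity_planes_deg       : 0.154 +/- 0.223 (n=12)
rectangularity_edges_deg        : 0.154 +/- 0.218 (n=24)
```

Reading the numbers: the metric scale was recovered to 16 µm/px from the
known pin distances (the base image happened to be rendered ~0.3 % larger
than nominal, which the metric calibration absorbs — in-plane lengths are
still recovered to 0.13 %).  Registration reproduces the simulated
per-slice transforms to well under half a pixel.  The grinding steps
averaged 102.1 µm instead of the nominal 100 (the simulated +2 µm
overshoot); had the stack assumed equidistant 100 µm slices, one slice
would sit 65 µm off — instead the measured abrasions place every slice
correctly, leaving a 1 % length error along the grinding direction for this
deliberately short (2.4 mm) cuboid and angular deviations of ~0.2°.

The same stages are scriptable from the shell:

```sh
grindstack simulate --out run/ --seed 3 --n-slices 32
grindstack reconstruct --in run/ --ledger run/ledger.csv \
    --marker-mm 8.69 9.13 8.91 --seed-points 950 660 450 369 477 924 \
    --radius-px 100 --out run/stack
grindstack report --ledger run/ledger.csv --nominal 100 --plot run/errors.png
grindstack evaluate --stack run/stack/dicom --reference cuboid.yaml --seed 0
```

See `docs/methods.md` for the models, defaults and their rationale.

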