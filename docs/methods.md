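# Methods

`grindstack` reconstructs a metrically correct 3D image stack from serial
microgrinding photographs and quantifies the geometric accuracy of that
reconstruction.  This note records the models, the defaults and the design
choices, and what the synthetic validation does and does not demonstrate.

## The measurement problem

Serial microgrinding destroys an epoxy-embedded specimen one layer at a
time; each freshly exposed surface is photographed.  Three error sources
separate the raw photographs from a correct 3D volume:

1. **In-plane misalignment.**  The specimen is removed, ground, stained and
   repositioned under the macroscope for every layer, so consecutive images
   differ by a rotation, a translation, and a small isotropic scale change
   (refocusing).  No reflection is physically possible.
2. **Unknown slice spacing.**  The nominal abrasion per step (100 µm) is
   set mechanically, but the achieved abrasion varies and tends to
   overshoot; assuming equidistant slices accumulates depth error along the
   stack.  The abrasion of every step is therefore measured with a tactile
   gauge and the slice depth is the cumulative sum of measured abrasions,
   starting at 0 for the first surface.
3. **Unknown metric scale.**  Pixel size follows from the known distances
   between three fiducial pins (drilled on a CNC machine): each known
   distance in mm is divided by the corresponding pixel distance in the
   base image, and the pixel spacing is the mean of the three ratios.

## Fiducial detection

Each slice contains the circular cross-sections of three cylindrical pins
(3.2 mm diameter).  Detection is two-stage:

* **Coarse pass** — an HSV colour filter calibrated from user-marked pixels
  on the base image (per-channel min/max over 3×3 neighbourhoods, padded by
  a tolerance of 0.08; hue treated circularly and released entirely for
  achromatic marker colours), median filtering (5×5) and morphological
  closing (disk, r=5 px) of the mask, then a circular Hough transform over
  the expected radius ±20 %.  The three strongest mutually non-overlapping
  accumulator peaks are the coarse centres (≤2 px).  The pass runs on a 2×
  decimated view; kernel sizes and radii scale along, which changes nothing
  at the ~2 px level the pass is specified to.
* **Refinement** — a detail crop of 1.5× the maximal radius around each
  coarse centre; Canny edges (σ=2), a second Hough vote restricted to the
  radius range, edge pixels within 2 px of the winning circle, and a
  closed-form algebraic least-squares circle fit (Kåsa: minimise
  Σ(|p−c|²−r²)²) on those inliers.  The Kåsa fit is exact on noiseless
  circles and linear-solve cheap; at the sub-pixel noise levels involved its
  known bias (∝σ²/r) is far below the 0.3 px accuracy target.  Fits with
  fewer than 12 inlier edge pixels, fits that wander >4 px from the Hough
  vote, and circles clipped more than 15 % by the crop are flagged
  low-confidence rather than raised as errors.

Markers are labelled by the base-image detection order; subsequent slices
are matched by optimal assignment after mapping through the previous
slice's transform, and any two candidate assignments within 5 px of each
other abort with an error rather than guess.

## Registration

Each slice is registered *directly* onto the base image (never chained
slice-to-slice, which accumulates error).  The transform is a linear
conformal map `p' = s·R(θ)·p + t` fitted to the three marker
correspondences by least squares; writing the planar points as complex
numbers gives the closed-form optimum with a positive scale, so a
reflection cannot arise.  The fiducial registration error (FRE) is the RMS
residual.

### Non-perpendicular pins (second pass)

A pin drilled at an angle makes its cross-section drift linearly with depth
(straight, rigid pins ⇒ linear model `center(z) = c₀ + m·z`).  First-pass
registration drags each slice so the markers coincide with the base
positions, which *shears the specimen* by exactly the similarity-shaped
component of the drift field — and that component is invisible in the
registration residuals, because the per-slice transform absorbs it.  The
residuals only expose the non-similarity component.

The estimator therefore combines two regressions against depth: the
residual trend per marker (non-similarity component) and the trend of the
transform parameters themselves (the absorbed similarity component, read
off rotation/log-scale/translation slopes).  Attributing the parameter
trend to the pins assumes the true slice-to-slice repositioning has no
systematic depth trend — true by construction for the generator, and
plausible for manual grinding, but it is an identifiability assumption, not
a theorem: a stage that genuinely drifted with depth would be
indistinguishable from tilted pins using marker data alone.  Because the
update is first-order in the drift, it is iterated (register → measure
trends → update targets, 4 rounds); the fixed point has trend-free
residuals and parameters.  The second pass registers every slice onto the
drift-compensated targets `c₀ + m·z`, which removes the shear while letting
the markers drift where they physically are.

With zero drift and trend-free transforms the procedure returns the first
pass unchanged; with per-slice random transforms the parameter-trend
regression adds sampling noise of order `σ_param /(σ_z √n)`, which is why
the tilt experiment uses moderate repositioning jitter and ≥80 slices.

## Stack assembly and DICOM

Aligned slices are placed at their measured depths.  The series is written
as DICOM secondary-capture files (8-bit RGB, explicit VR little endian):
pixel spacing = stack spacing in mm for rows and columns; slice thickness
fixed at 0.001 mm to respect the two-dimensional character of a ground
surface; image position/slice location = cumulative measured abrasion in
mm; axial identity orientation; all UIDs derived deterministically from a
seed by hashing.  Reading sorts by slice location and rejects files with
inconsistent spacing.

The error report mirrors the grinding-protocol bookkeeping: the *error of
abrasion* is |measured − nominal| (absolute — a ledger whose signed errors
cancel still has a positive mean error), signed errors are kept alongside,
the *accumulated error* is `z_i − i·nominal`, and its extremum is reported
signed but selected by magnitude.  The propagation classifier calls a
series **type 1** (systematic overshoot) when the mean signed step error
exceeds 1 µm *and* ≥70 % of steps grow the magnitude of the accumulated
error, otherwise **type 2** (non-predictable with partial compensation).
Both thresholds are exposed in the API; the two regimes are qualitative in
origin and the defaults are this package's operationalisation.

## Geometric accuracy evaluation

The embedded reference cuboid is segmented from the aligned stack by
thresholding one colour channel (voxel sizes: spacing × spacing × local
slice gap, non-equidistant in z).  Because the fiducial disks would pass a
brightness threshold too, the pipeline masks the detected marker disks
(radius ×1.2) out of each aligned slice before evaluation — the digital
equivalent of cropping them away.

For each of the six faces, 20 surface points are sampled uniformly without
replacement (reproducibly from a seed) among the surface voxels assigned to
that face.  Surface voxels are object voxels with ≥1 empty 6-neighbour;
their local outward normal (sum of unit steps toward empty neighbours) must
match one face normal clearly (best-vs-second dot-product margin 0.2), so
staircase edge voxels are excluded.  Face normals come from the principal
axes of the segmented volume (distinct edge lengths make the PCA axes the
edge directions, sorted by extent).  Each sampled voxel centre is shifted
half a voxel outward along the blocked lattice axis: a binary mask
localises a face only to the last occupied voxel, so the un-shifted
estimate is biased inward by half a voxel per face — roughly half a slice
gap (~50 µm) on the end faces, which alone would consume an entire 0.5 %
length budget on a ~13 mm edge.  The shift centres the error at zero; the
residual quantisation scatter remains visible in the plane-fit RMS.

Planes are fitted by total least squares (smallest singular direction of
the centred points) — faces are oblique after registration and embedding,
so a fixed-axis regression would be wrong.  Edges are intersection lines of
adjacent planes (direction = normalised cross product; point = minimum-norm
solution), corners are triple-plane intersections (rejected above condition
number 100), edge lengths are corner-to-corner distances, and angles come
from normals/directions folded to [0°, 90°]: parallelism is the deviation
from 0° over the 3 opposite-face pairs, rectangularity the deviation from
90° over the 12 adjacent-face pairs and the 24 corner edge pairs.  All
edges are reported with group labels (in grinding plane vs in grinding
direction, by the dominant component of the edge direction along z).  A
`quantize_deviation` helper reproduces a measurement readout limited to
0.1 mm steps (halves away from zero).

## The phantom (synthetic study conditions)

The generator emulates the reference-object run: a 30 mm epoxy cylinder
(dark blue), three white pins of 3.2 mm diameter at mutual distances of
8.7–9.1 mm around the axis, an embedded red cuboid, and three
circumferential grooves.  A specimen-style colour scheme (light epoxy,
black pins, violet tissue) is selectable.  Rendering is exact 4×4
supersampling at material boundaries (the interior of a material region is
constant, so supersampling is only evaluated near label changes), at
16 µm/px on a 1280² frame — matching the reported optics, where one pixel
is about the optical resolution limit.

Defaults are the study conditions: 100 µm nominal abrasion with +2 µm bias
and 3 µm Gaussian scatter truncated at 1 µm (overshoot, never undershoot,
matches the observed grinding behaviour; the tactile measurement is taken
as exact unless a measurement-noise option is set); per-slice transforms
uniform within ±5°, ±20 px, ±1 % scale; marker boundary jitter uniform
within ±0.2 px per coordinate.  The default cuboid is 5.6 × 4.4 × 12.8 mm,
centred on the axis at mid-depth and rotated (3°, 4°, 2°) against the
grinding frame: a hand-embedded object is never machine-aligned, and the
oblique pose spreads each end face over ~6 slices so the z-quantisation of
a binary segmentation averages out in the plane fits instead of appearing
as a common-mode offset.  The main experiment grinds 150 slices (~15.3 mm),
comfortably crossing both end faces.

The tilt experiment uses a shorter cuboid (6.6 mm tall) over 80 slices and
one pin tilted 0.16 mm/mm roughly tangentially (drift 0.01 px/µm), with
gentler repositioning jitter (±1°, ±5 px, ±0.3 %) — the parameter-trend
regression that separates pin tilt from stage motion has sampling noise
proportional to the jitter, and these are the conditions under which a
~1 % drift-recovery error is expected a priori.

**What the phantom does not emulate:** photometric realism (illumination
gradients, staining variability, surface scratches), optical distortion of
the imaging system, debris or partial slices, segmentation ambiguity
between tissue classes, and non-straight (bent) pins.  Passing the
end-to-end bounds therefore demonstrates that the *algorithms* recover
known geometry under realistic geometric and statistical perturbations; it
does not certify performance on real stained histology, where colour-filter
calibration and segmentation thresholds are the operator-dependent steps.

## Numerical choices

* Image coordinates are 0-based with x = column, y = row and pixel centres
  on integer coordinates; z increases with grinding depth, slice 0 at z=0,
  and n slices have n−1 measured abrasions (no abrasion is defined for the
  first surface).
* Conformal estimation is closed-form (complex least squares); collinear
  landmark triplets raise a degenerate-configuration error.
* Resampling is bilinear with out-of-source pixels fill-valued and flagged.
* Circle and plane fits reject collinear input via singular-value ratios
  (<1e−9); near-parallel plane intersections are rejected at 1° (pairs) or
  condition 100 (triples).
* Hough peaks are ordered by vote, ties broken by (y, x); radii are scanned
  in ~10 steps across the configured range.
* DICOM floats are stored as decimal strings; positions survive a roundtrip
  to well below 1e−9 mm at the depths involved here.

## Problem sizes

The shipped tests and the acceptance script run the main experiment at 150
slices of 1280² px and the tilt experiment at 80 slices, the sizes chosen
for the synthetic study; the smaller fixtures used by the unit tests scale
the cuboid depth to the ground depth so every face remains observable.

## Known limitations

* The tilt/stage-drift decomposition relies on the trend-free-repositioning
  assumption discussed above.
* Face sampling assumes a convex, roughly cuboidal object with distinct
  edge lengths; equal edges would make the PCA axes degenerate.
* The classifier thresholds are calibrated to the 100 µm / +2 µm / 3 µm
  regime; very small biases with strong scatter are classified type 2 by
  design.
* Geometry metrics are single-realisation: a given seed draws one staircase
  phase per face, so per-run numbers scatter within the quantisation budget
  derived above.
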