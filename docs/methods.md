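# Methods

## Scope and model

`canopykit` implements the computational stack that sits *after* an
instance-segmentation model in an orchard machine-vision pipeline: fruit
sizing from masks plus depth, occlusion-aware fruit counting, workspace
filtering for branch avoidance during robotic harvesting, and the
statistics used to evaluate and compare the segmentation models
themselves. Training and inference of the CNN models are out of scope; the
package consumes their outputs (masks, boxes, scores) or exact synthetic
stand-ins.

All geometry is in the camera frame: x right, y down, z forward along the
optical axis, millimetres throughout. Depth images store perpendicular
z-depth (not ray length) as 16-bit PNG with 0 encoding "no return", the
convention of consumer RGB-D hardware.

## Synthetic canopy scenes

The generator emulates night-time imaging of mango canopies under LED
lighting at 1.5–3 m range on 640×540 tiles: fruit as prolate ellipsoids
hanging with the long axis vertical, branches as long cylinders of 10–50 mm
radius crossing the frame roughly horizontally, leaves as discs used as
occluders (rendered but not labelled as a class — the labelled classes are
fruit and branch only). Default fruit lengths are Normal(105 mm, 10 mm)
truncated to [80, 130] mm with width/length aspect U(0.60, 0.75); the
source orchards' true size distributions are not published, so these
defaults are a field-plausible choice for commercial mango near harvest,
configurable and not claimed to match any specific dataset.

Rendering is per-pixel ray casting with closed-form ray–quadric
intersections and a nearest-hit z-buffer. Rays are parametrised with unit
z-component so the ray parameter at the hit *is* the stored z-depth.
Branch cylinders expose their lateral surface only (no end caps): branches
are long relative to the frame, so their cut ends face out of view.
Gaussian depth noise and dropout, both driven deterministically by the
scene seed, perturb the depth raster only; instance maps and ground-truth
records always reflect noiseless geometry. Per-fruit `occluded_fraction`
compares visible pixels in the full scene against a solo re-render of that
fruit.

Fruit are placed on a jittered angular grid, which guarantees (without
rejection sampling) that fruit do not occlude one another; occlusion
studies instead place a leaf disc deliberately on the line of sight of a
chosen fraction of fruit, offset to hide roughly one lateral half of the
silhouette. What the generator does **not** emulate: photometric realism,
leaf botanical shape, depth-sensor artefacts other than Gaussian noise and
dropout (no flying pixels, no multi-path), mask errors of a real
segmentation model (synthetic masks are pixel-exact), and fruit clusters
touching in the image. Passing tests therefore demonstrate correctness of
the downstream geometry and statistics, not robustness to real
segmentation noise.

## Fruit sizing

The camera-to-fruit range Z is the median of valid depths under the mask
after one pass of median-absolute-deviation rejection (discard values with
|d − median| > 3·MAD, then re-take the median). Masks of real detectors
leak onto background foliage hundreds of millimetres behind the fruit;
the MAD-filtered median tracks the majority surface. Length and width are
the axis-aligned mask extents converted per axis: length = h·Z/fy,
width = w·Z/fx. Axis-aligned extents (rather than fitted-ellipse axes) are
the primary measurement because the target fruit hang approximately
vertically; the fitted axes are exposed in the diagnostics for fruit at an
angle.

Known bias structure at 2 m with fy = 600: one pixel subtends ≈ 3.3 mm;
the silhouette boundary quantisation adds up to +1 px per side while using
the front-surface depth (median over a convex fruit face) underestimates
the centre distance by roughly the fruit's semi-depth relative to its
centre — the two effects largely cancel, and measured |bias| stays below
one pixel-equivalent with RMSE under two pixel-equivalents on noiseless
synthetic fruit.

### Ellipse occlusion filter

An ellipse is fitted from the mask's second-order central moments
(scikit-image regionprops axes). The filter passes a mask iff

* major/minor axis ratio lies in a whole-fruit window, default [1.1, 2.0];
* the Jaccard overlap between the mask and the fitted ellipse (rasterised
  at the mask centroid with the fitted orientation) is at least 0.85.

The overlap definition is a deliberate design choice over the simpler
"mask area / ellipse area" quotient: a moments-fitted ellipse nearly
conserves its mask's area even for a half silhouette (quotient 0.95 for a
60×40 ellipse with one half erased), so an area quotient cannot detect
chord truncation by an occluder, whereas the overlap drops to ≈ 0.81 for
the half silhouette and ≈ 0.77 when three quarters are erased while
staying ≥ 0.99 for whole convex fruit. Both thresholds are
configuration-exposed; the defaults are not field-calibrated values and a
cultivar-specific deployment should narrow the ratio window around the
cultivar's length/width ratio.

Accuracy statistics: bias = mean(error), RMSE, and bias-corrected
RMSE-bc = √(mean((error − bias)²)); rmse² = bias² + rmse_bc² holds exactly
on the same error vector. `bias_corrected_rmse` applies the identity to
summary values when the raw errors are unavailable.

## Workspace filtering

A pick cycle sweeps a convex 8-vertex prism from the gripper home position
to the target fruit: cross-section W wide (camera-horizontal) and H1 tall,
with the home face enlarged to H2 when the arm platform travels vertically
during the pick (the two side faces then become trapezoids). "Vertical" is
camera −y; the prism axis follows the home→fruit vector, and the target
fruit point is taken as the back-projected mask centroid at the median
mask depth.

Face planes are computed by the cross product of two in-face edge vectors
and oriented so the prism centroid evaluates negative; a point is inside
iff ax + by + cz + d ≤ 0 on all six planes. Numerical choices: boundary
points count as inside (a point exactly on a face is treated as a
collision risk, the conservative direction), with a relative tolerance of
1e-9 scaled by the plane normal and point magnitude; the centroid anchor
makes the sign convention unambiguous and testable. For axis-aligned
rectangular workspaces the equivalent min/max coordinate test is provided;
its `as_printed` variant reproduces a published abridged form whose z test
is one-sided only (no near bound), kept for comparison but not the
default, since it admits points nearer than the home plane.

Four filtering strategies mirror the published timing comparison:
rectangular-bounding-box only, trapezoidal only, trapezoidal after a
rectangular pre-filter, and both reported together. Because the trapezoid
is contained in its bounding box, the pre-filtered strategy returns
exactly the trapezoidal inside set — the decomposition is a pure
optimisation, which the acceptance suite verifies by set equality.

## Evaluation metrics

Matching is the COCO protocol: per image and class, predictions in
descending score order are each matched to the unmatched ground truth of
highest IoU ≥ threshold; score ties keep input order; a double detection
of one object yields one TP and one FP. AP integrates the
precision-envelope over recall at 101 points (recall 0, 0.01, …, 1);
exact all-point integration is available via a flag and agrees within the
documented 1-percentage-point discretisation bound on small sets.
mAP50-95 averages per-class AP over IoU 0.50–0.95 in 0.05 steps.
Conventions: a class with predictions but no ground truth scores AP 0;
with no predictions and no ground truth, P/R/F1 are reported as 0 with a
`defined=False` flag; with ground truth and no predictions, P = 100
(vacuous) and R = 0.

The repeated-training variation summary uses the sample SD (n−1
denominator); the published summaries do not state the denominator, and
both conventions reproduce the printed CVs at printed precision.
CV = SD/mean × 100.

## Counting

Machine count = detections of the class with score ≥ threshold (boundary
inclusive). The occlusion correction factor is the ratio of totals
Σmanual/Σmachine over calibration trees — chosen over the mean of
per-tree ratios because it tolerates zero-count trees and is exact in
closure (applying the factor back to the calibration set reproduces the
manual total).

## Problem sizes in the validation suite

The acceptance computations use 20 random workspaces × 10⁵ points for the
prism oracle, 50 random 10⁴-point clouds for strategy equivalence, 100
synthetic fruit at 2 m (noiseless and with 5 mm depth noise) for sizing
recovery, and 200 fruit (half deliberately occluded) for filter
discrimination — sizes at which the binomial/sampling error of each check
is far smaller than the margins asserted, while the full run stays in the
tens of seconds.

## Known limitations

* Synthetic masks are pixel-perfect; sizing error under a real detector's
  boundary noise will be larger than the discretisation-level figures
  reported here.
* The ellipse filter sees only second-order shape; an occluder whose edge
  happens to leave an elliptical silhouette of in-range ratio passes.
* The trapezoidal workspace assumes the home→fruit axis is not vertical
  (the horizontal cross-section frame is undefined there; the constructor
  raises).
* `rect_only` filtering uses the axis-aligned bounding box of the swept
  prism, which over-flags obstacles for strongly oblique picks — by
  design, as the cheap conservative pre-filter.
* COCO RLE masks are not supported (polygon segmentations only), and the
  counting module does not deduplicate fruit seen from both row sides.
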