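# Methods

## Problem and model

Percutaneous closure of the left atrial appendage (LAA) anchors an
occluder in the *landing zone*, a roughly elliptical cross-section of the
appendage neck. Two planning computations are implemented:

1. **Localization/accuracy**: a diameter annotated in 2D on a fluoroscopy
   frame is localized on the 3D surface model so the same anatomical
   location can be measured tomographically.
2. **Prospective planning**: a landing-zone plane chosen on 3D imaging is
   sized, and the patient-specific optimal C-arm angulation is predicted.

Both are wrapped by agreement statistics that quantify how measurements
from different modalities relate.

## C-arm geometry

The gantry is a pinhole camera. In DICOM LPS patient coordinates the
central beam (source → detector) is

    v(α, β) = (sin α cos β, −cos α cos β, sin β),

with primary angle α (LAO positive, RAO negative) and secondary angle β
(CRAN positive, CAUD negative); the clinically recommended working
projection RAO20-30/CAUD20-30 is α, β ∈ [−30°, −20°]. The source sits at
−SOD·v from the isocenter; the detector plane is orthogonal to v at SID
from the source; detector coordinates are mm from the principal point with
the row axis the horizontal patient axis rotated by α. Defaults
SOD = 765 mm, SID = 1100 mm are typical interventional values. Setting
SID = ∞ selects an orthographic mode used only for analytic tests.
Assumptions: isocentric gantry, no table offset, no detector roll, no
distortion — adequate for planning-level geometry, not for calibration
work. Angle comparisons are always the 3D angle between beam vectors, not
differences in (α, β), which overstate separation away from the equator.
At |β| = 90° the primary angle is degenerate and reported as 0.

## Localization rule

Each annotation endpoint back-projects to a ray; all ray–mesh
intersections (vectorized Möller–Trumbore over every triangle,
duplicate/grazing hits merged within 1e-6 mm) are candidates. The chosen
pair — one point per ray — minimizes the depth disparity along the beam,
because the endpoints of a measured diameter lie on opposite walls at the
same depth. Silhouette annotations are tangent rays; exact tangency is
numerically fragile and an outward click misses the wall, so a ray with no
intersection captures the nearest wall vertex within 2 mm (about 1.5
voxels of the emulated 1.3 mm imaging). The cross-section plane is spanned
by the recovered segment and the beam: normal = (b − a) × v, anchored at
the midpoint. Under a tangential view this reconstructs the anatomical
cross-section plane; it is isolated behind `landing_plane` so
centerline-based constructions can replace it.

## Sizing

On the section polygon (all closed loops of the plane–mesh intersection,
the loop nearest the landing-zone midpoint selected): perimeter and area
are taken on the raw contour (shoelace); caliper metrics d_max (hull
maximum chord, with direction) and d_min (rotating-calipers minimum
width) on the convex hull, matching how calipers are placed on an image;
d_peri = p/π and d_area = 2√(a/π) are the equivalent-circle diameters,
and ovality = d_max − d_min. For any convex section, d_area ≤ d_peri
(isoperimetric inequality) and d_min ≤ d_peri ≤ d_max (Cauchy's mean
width: p = π·mean width). d_min and d_area are *not* ordered for general
convex shapes — an equilateral triangle has width 0.866·s but
equal-area-circle diameter 0.742·s — though d_min ≤ d_area does hold for
ellipses (2b ≤ 2√(ab)); the tests assert exactly these facts. Device
charts are user-supplied half-open [lower, upper) intervals; none is
hardcoded because published charts assume echo-based measurement.

## Angulation prediction

The optimal beam v = ±(n × d̂) lies in the section plane (edge-on view)
and is perpendicular to the maximal diameter (no foreshortening). Of the
two antiparallel solutions the one angularly closer to RAO25/CAUD25 (the
center of the recommended range) is chosen — clinical access favors that
quadrant and the construction is otherwise sign-symmetric. Predictions
are compared to used angulations with a configurable threshold, default
10°: inter-reader variability of such predictions is of order 7–8°, so
smaller deviations carry no information. A deviation of exactly the
threshold counts as agreement (strict >). Range membership uses closed
intervals. For a circular section the major-axis direction, hence the
prediction, is undefined; the phantom cohort therefore keeps ovality
≥ 2 mm (see below).

## MPR

Volumes carry spacing, origin and an orthonormal direction matrix
(center-of-voxel, 0-based; NIfTI affines are converted RAS↔LPS on I/O).
Reformatting samples a square grid on the requested plane by trilinear
interpolation with a constant fill (default 0) outside the volume.
Trilinear interpolation reproduces affine intensity fields exactly at
interior samples, which the tests exploit as an oracle.

## Agreement statistics

Bland-Altman: differences d = a − b; bias = mean, sd with n−1, limits of
agreement bias ± 1.96·sd, bias CI via the t distribution. Paired-test
selection: Shapiro-Wilk on the differences; p ≥ 0.05 → paired t-test,
else Wilcoxon signed-rank (zeros dropped, exact null for n ≤ 25 — small
cohorts demand it; normal approximation with continuity correction
above). Levene's test is reported alongside but does not drive the
choice. Pearson r carries the Taylor qualitative scale (0.35/0.67/0.9).
ICC(2,1) — single rating, absolute agreement, two-way random effects —
is computed from the ANOVA mean squares

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

with the McGraw–Wong F-based confidence interval, labeled by the Koo–Li
thresholds (0.5/0.75/0.9); it is cross-checked in the tests against an
explicit double-loop oracle (1e-10) and against pingouin. Report tables
render "bias ± sd; p" (one decimal, p < 0.05 as "<0.05") and "r; p"
(two decimals).

## Synthetic phantoms

Phantoms are watertight swept-ellipse tubes: straight or circular-arc
centerline, linearly tapering semi-axes, optional linear twist, capped
ends. Everything downstream has a closed-form or quadrature ground truth
(ellipse perimeter via the complete elliptic integral), so pipeline
validation is parameter recovery, never self-comparison. The phantom is
oriented so its landing section is viewed tangentially from a
configurable pose, default RAO25/CAUD25, mirroring how the anatomy is
imaged; voxelized volumes default to 1.3 mm isotropic spacing, the
resolution of the emulated tomographic acquisition. Cohorts draw the
maximal diameter from N(22, 3²) mm clipped at 12 mm and ovality uniform
on [2, 8] mm — clinically plausible landing-zone sizes, with the lower
ovality bound away from zero so the angulation prediction is well-posed.
Annotation noise is isotropic 2D Gaussian jitter on the detector; reader
panels add per-reader offsets and Gaussian noise, and a second modality
adds a systematic bias (negative values emulate the underestimation of
projective/echo sizing relative to tomography).

What the phantoms do **not** emulate: real LAA morphology (lobes,
trabeculation, chicken-wing bends), segmentation error, registration
error between mesh and XR geometry, cardiac/respiratory motion, and image
intensity characteristics. Passing tests therefore demonstrate that the
geometric and statistical machinery is correct and self-consistent at
clinical scales — not that clinical accuracy on patient data would match.

## Numerical choices

* Mesh resolution defaults 128 circumferential × 64 longitudinal
  segments: section metrics converge ~quadratically, within 1% of truth
  at 128 segments and 0.1% at 512 (asserted).
* Ray-hit deduplication and grazing tolerance 1e-6 mm; degenerate-face
  area threshold 1e-12 mm²; unit-vector and orthogonality checks at 1e-9.
* Voxelization decides insideness per (x, y) column by ray-crossing
  parity along z; an odd (grazing) count drops the unpaired hit. Requires
  watertightness, which is checked.
* Rigid registration is Kabsch/SVD with reflection correction; collinear
  point sets are rejected (rotation underdetermined).
* Section loops are ordered by descending area; consumers select by
  centroid proximity to the landing-zone midpoint, so end-cap or
  second-lobe loops are never confused with the target section.
* Default problem sizes in tests and the acceptance script (25-phantom
  localization cohort, 13-case study, n = 2000 ICC / n = 5000
  Bland-Altman simulations) give sampling error comfortably below the
  asserted tolerances while keeping the full suite under a minute.

## Known limitations

* The localization rule assumes the annotated diameter endpoints are at
  comparable beam depth; strongly oblique (non-tangential) annotations
  violate this and degrade the plane estimate.
* The cross-product landing plane is one formalization; interactive
  clinical tools may use centerline-orthogonal planes instead.
* Whether the projection-parallel diameter is measured in projection
  space or on the MPR is ambiguous in practice; the projection-space
  definition is implemented.
* DICOM positioner sign conventions vary by vendor in practice; the
  standard convention is assumed and isolated in the geometry module.
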