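# Methods

## Measurement model

All measurement happens in a single plane: the subject stands with their
medial line in the plane of a vertical checkerboard sheet, and every
quantity of interest (height, silhouette half-widths) is an in-plane
distance. The world frame puts the board's top-left inner corner at the
origin, X rightwards, Y downwards, z = 0 on the plane, all lengths in mm.
Image coordinates are raster pixels (origin top-left, y down, sub-pixel
floats, points may fall outside the frame).

**Calibration back-end.** A pinhole camera with radial terms (k1, k2, k3)
and tangential terms (p1, p2). Forward projection distorts in normalized
coordinates and then applies the intrinsics; undistortion inverts the
model by fixed-point iteration on normalized coordinates (tolerance
1e-10, ≤50 iterations — identical to the standard practice in mainstream
vision libraries, and verified by round-trip to <1e-6 px for |k1| ≤ 0.3,
|k2| ≤ 0.1). Plane poses are obtained by Hartley-normalized DLT
homography estimation followed by the Zhang-style decomposition
H ~ K[r1 r2 t] with SVD re-orthonormalization. Intrinsic calibration
implements only the linear closed-form solution on ≥3 distinct board
orientations; distortion coefficients are accepted as inputs rather than
estimated (the synthetic generator knows them, and nonlinear bundle
adjustment is out of scope). Back-projection inverts the plane-to-image
homography, so projecting and back-projecting a plane point is the
identity to float precision; an edge-on (singular) viewing geometry and
rays parallel to the plane raise errors.

**Reference back-end.** Works on the *original, distorted* photo by
design: the sheet's four corners are annotated, the top/bottom (left/
right) edge lines are extrapolated, and a vertical (horizontal) pixel
distance is scaled by the mm/px ratio of the sheet evaluated at the
position of the measured segment. For an oblique segment the sheet height
is evaluated at the midpoint abscissa and the width at the midpoint
ordinate — the symmetric choice among the possible readings of
"at the position at which the distance is measured" — and the metric
length is the root-sum-square of the two converted components. On a
fronto-parallel, distortion-free view this is exact; under tilt it
carries a perspective bias that shrinks to zero as the camera approaches
perpendicularity (asserted as a monotone sweep in the tests).

## Estimators

* Linear-distance height: perpendicular distance from the head landmark
  to the floor line through the sheet's bottom corners (computed in world
  coordinates for the calibration back-end, in pixels then converted for
  the reference back-end).
* Bounding-box height: `(d_AC + d_BD)/2`. In pixel space the two sides of
  the axis-aligned box are equal; both are still converted and averaged
  because the sheet scale differs slightly between the two abscissae.
* Arm radius: half the distance between the two arm-edge markers; MUAC
  follows from the circle / ellipse (Ramanujan first approximation) /
  ellipse+rectangle models, or from the regression below.

Degenerate inputs (missing landmarks, inverted boxes, non-positive or
non-finite results) raise immediately so evaluation tables can never
contain silently invalid rows.

## Regression and evaluation

For each non-empty view subset S (31 in total) the estimator
`Σ_{i∈S} w_i f_i + b` is fitted by ordinary least squares with intercept
(numpy lstsq; a rank-deficient design falls back to the minimum-norm
solution with a warning — no regularization). Views photographed twice
per session (views 2–4, once per arm side) contribute the mean of the two
photos to height features; MUAC units are single arms and take each
view's radius from the photo in which that arm is unobstructed. The three
capture sessions are pooled into one fit and serve as the N = 3 repeats
for MAD/TEM.

Leave-one-out cross-validation holds out *all* rows of one unit
(participant, or participant×arm), so a unit's manual reference never
influences its own prediction; this is asserted both by a leakage test
and by equivalence with a naive refit-per-fold oracle.

Metrics follow the standard anthropometric definitions: per-unit MAD and
MAPD against the mean of the manual repeats; TEM as the pooled
within-unit standard deviation of repeated estimates (implemented for a
constant repeat count, the study design; unequal counts raise); and
R = 1 − TEM²/s² with s the sample standard deviation (ddof = 1) of all
pooled estimates, clamped to [0, 1]. Adequacy is the two-sided band
|TEM_photo − TEM_manual| ≤ 2.8·TEM_manual, and R > 0.95 (strict) counts
as acceptable. The "optimal" flag marks the smallest mean MAD per method
block, ties broken towards fewer views then lexicographically.

## Synthetic generator

The generator is the package's stand-in for the (undeposited) study
photographs and defines the conditions every statistical test runs under:

* 31 participants × 3 sessions × 8 photos = 744 annotations; views 1 and
  5 show both arms, views 2–4 are taken once per arm side.
* Heights ~ N(1706.5, 89.1²) mm truncated to [1450, 1950]; per-arm MUAC
  targets ~ N(292, 38²) mm truncated to [200, 400] with a ±5 mm left/right
  asymmetry.
* Board: 7×10 squares of 90 mm on an 840×1186 mm sheet whose bottom edge
  rests on the floor; subject's medial line 755 mm right of the board
  origin. Camera distances 3390/3250/3120 mm (±100 mm per participant),
  height 1125 ± 30 mm, aimed near the scene centre with ±50 mm jitter;
  intrinsics fx = fy = 3240 px at 4000×3000 px (a compact camera with a
  ~5 mm lens on a 1/2.3" sensor), distortion k1 = −0.05, k2 = 0.01 and
  small tangential terms.
* Arm cross-sections are ellipses with axis ratio U[1.0, 1.5] and
  orientation U[−π/2, π/2] ("unknown humeral rotation"); the silhouette
  half-width seen from angle θ is the support function
  √(a² sin²(θ−azimuth) + b² cos²(θ−azimuth)). True MUAC is the
  adaptive-quadrature perimeter of the ellipse (relative tolerance
  ~1e-12), which also serves as the independent oracle for the
  closed-form models.
* View angles are the ideal 0°/45°/90°/135°/180° plus ±3° uniform jitter.
* Two systematic, view-dependent imperfections are modelled because the
  method exists to correct them: the feet protrude towards the camera by
  `F·|cos θ|` (F ~ N(120, 20²) mm), putting the bounding-box bottom edge
  below the floor line; and the subject stands slightly off the board
  plane towards the camera when repositioning for a view (defaults
  20–40 mm by view, ±10 mm per photo), inflating every subject-borne
  distance by roughly offset/distance (~1%, i.e. 15–20 mm of height).
  Misalignment of this kind is the recognised dominant error source of
  free-standing multi-view capture.
* Annotation noise is i.i.d. N(0, 2²) px per coordinate; simulated manual
  repeats are truth + N(0, 2.24²) mm for height and + N(0, 3.76²) mm for
  MUAC, matching the reliability of careful manual measurement, three
  repeats per unit.

The *exact* annotations use the idealized in-plane geometry (no pixel
noise, no plane offset), so the calibration back-end reproduces ground
truth to <1e-6 mm on every photo — the geometric closure test. The noisy
annotations carry all imperfections. All randomness flows from one seeded
`numpy` generator; a fixed config reproduces a bundle bit-for-bit.

What the generator does **not** emulate: articulated posture and sway,
non-elliptical arm cross-sections, clothing, perspective foreshortening of
the body's depth extent beyond the single offset parameter, annotation
biases that correlate across landmarks, and lens effects beyond the
5-coefficient model. Passing tests therefore demonstrate the pipeline's
correctness and the *structure* of the method's behaviour (regression
beats fixed shape models and raw baselines; calibration beats the
reference object), not clinical accuracy on real photographs.

## Problem sizes and numerical choices

The default test and acceptance runs use the full study-scale bundle
(31 participants, 744 photos) — small enough that the complete
view-combination sweep for all methods and both back-ends finishes in a
few seconds. The multi-seed robustness check uses 20 independent bundles.
Tolerances: geometric closure 1e-6 mm; undistortion fixed point 1e-10;
metric oracles 1e-10; LOOCV-vs-oracle 1e-9; Ramanujan-vs-quadrature 0.1%
for axis ratios ≤ 3. Homography/DLT estimation uses Hartley normalization
for conditioning; rank checks raise on degenerate correspondence sets and
on calibration views that do not span distinct orientations.

## Design choices on genuinely open points

* The per-view feature of a twice-photographed view is the mean of the
  two photos (rather than separate left/right features), keeping one
  column per view as the regression is specified.
* The reference back-end converts `d_AC` and `d_BD` to mm *before*
  averaging (identical result in the axis-aligned case, where the two
  pixel lengths coincide).
* `s` in the reliability coefficient uses all pooled estimates, not
  per-unit means.
* The three capture distances are pooled into a single regression fit,
  giving each unit exactly three repeated estimates per view subset —
  the repeat count the TEM formula assumes.
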