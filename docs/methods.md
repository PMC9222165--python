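# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `grafhip`, in the order the pipeline runs.

## Coordinate convention

All modules share one image frame: origin at the top-left pixel, columns
(x) increasing with depth into the tissue, rows (y) increasing caudally;
the near field is the left edge, so a well-aligned ilium is a near-vertical
bright band.  Boxes are 0-based and half-open, `[x_min, x_max) × [y_min,
y_max)`.  Pixel centers carry integer coordinates.

## Detection post-processing

Any callable `image -> list[Detection]` can act as the detector; the
pipeline depends only on the detection schema (structure, box, confidence in
[0, 1]; external detectors must normalize logits before entry).  Two steps
follow:

* **Per-class filtering** keeps the single highest-confidence box per
  structure.  Ties are broken by larger box area, then first occurrence —
  a deterministic rule that makes the operation idempotent.
* **Layout validation** (rules R1–R4 in `detection.py`) encodes the coronal
  Graf-plane arrangement using box centers only.  The clinical sources
  state *that* positions are checked but not *how*; R1–R4 are this
  package's concretization and are deliberately weak (center comparisons,
  no margins) so that plausible detector jitter does not invalidate a
  usable frame.  In static mode a violation only warns, because the
  operator vouched for the plane; in dynamic mode the frame's score is
  zeroed, because an implausible layout means the confidences cannot be
  trusted.

The bundled `reference_detect` is a geometric heuristic for phantom-like
images (maximum-entropy threshold, morphological opening, connected
components; the ilium is the most elongated near-vertical component and the
blobs are classified by their column offset from the caudal ilium tip).  It
exists so the pipeline can run without any trained model; it is not a
stand-in for detector quality on clinical data.

## Frame scoring

The frame score and ilium sub-score are

    S = λ₁·S_lower_limb + λ₂·S_labrum + λ₃·S_bony_rim + λ₄·S_ilium
    S_ilium = λ₅·S_conf + λ₆·S_hw + λ₇·S_angle,  S_angle = 1 − |θ|/10

with defaults λ₁=3, λ₂=λ₃=1, λ₅=0.2, λ₆=0.3, λ₇=0.5.  λ₄ has no published
value; the default is 1, symmetric with λ₂/λ₃, on the grounds that the
ilium's extra importance is already expressed inside S_ilium.  All weights
are configurable (`ScoringWeights`, CLI/TOML keys `lam1`–`lam7`).

* S_angle is **not clamped** below zero — negativity is the intended penalty
  for a tilted ilium — and S_hw is **not normalized**, because scores are
  only ever compared between frames of one video.
* θ is estimated from second-order image moments of the ilium region after
  expanding the box by 10% per side (the published procedure says only that
  the box is "first expanded"; 0.1 is this package's choice, configurable
  as `margin_fraction`).  The region median is subtracted (clipped at zero)
  before the moments are taken: raw moments over a bright uniform
  background would pull the principal axis toward the box's own long axis
  and mask the band's tilt.  The median is a robust background estimate
  because the band occupies well under half of the expanded box.
* The principal-axis angle uses the half-angle form with a two-argument
  arctangent, θ_axis = ½·atan2(2b, a−c), then is reported as the deviation
  of the major axis from the image vertical wrapped to (−90°, 90°],
  positive when the top leans deeper.  Regions isotropic to 1e-12 return 0.
* Exact score ties between frames resolve to the earliest frame.  If no
  frame scores above zero the video has no usable plane and selection
  raises — no diagnosis should be made.

## Angle measurement

* **Segmentation**: each box's local histogram is thresholded at the Kapur
  maximum-entropy level — the exhaustive maximizer over all thresholds that
  leave both classes non-empty of the summed Shannon entropies of the
  normalized background (≤ t) and foreground (> t) distributions; smallest
  t on ties; foreground is strictly above t.  Only the largest 8-connected
  component is kept, suppressing speckle islands.  Constant boxes are
  errors, not empty masks.
* **Baseline**: per mask row, the minimum-column (most superficial) pixel;
  a total-least-squares line through these edge pixels, translated
  perpendicular toward the superficial side until every edge point lies on
  or deep to it (a tangent, as Graf requires, rather than a regression
  line).  Masks spanning fewer than 5 rows are rejected.
* **Landmarks**: lower-limb point and labrum center are mask centroids;
  the bony-rim point is the minimum-column rim pixel (most cranial on
  ties); the bony-roof point is the tangent point from the lower-limb
  point to the contour of the caudal half of the ilium mask united with
  the rim mask.  The tangent construction picks the contour point p with
  cross(p − pivot, q − pivot) ≥ 0 for every contour point q (the deep,
  larger-column side), breaking collinear ties by distance from the pivot;
  it is implemented via the convex hull and verified in tests against an
  O(n²) all-pairs check.  These operationalizations replace the
  unspecified "gradient information and clinical prior knowledge" of
  clinical practice with reproducible mask geometry.
* **Angles** are acute line–line angles, arccos|d₁·d₂| ∈ [0°, 90°].  This
  is adequate for the type I/II scope (β < 90°) and is a known limitation
  for decentered hips, where β is conventionally measured as a directed
  angle that may exceed 90°.
* **Classification**: type I iff α ≥ boundary, boundary 60° by default and
  inclusive to type I (Graf defines type I as α ≥ 60°).  Hips with α near
  the boundary (58–62°) are intrinsically at risk of misclassification
  from ~1° measurement error; the boundary is configurable.

Missing structures abort measurement with an error naming the structure —
in particular the lower limb, without which no diagnosis should be made.

## The phantom

The generator renders the standard-plane geometry analytically before
drawing pixels: the baseline is the superficial edge of the ilium band; the
lower-limb center is placed at distance 0.22·min(H,W) from the band's
caudal tip along the direction making exactly α with the baseline; the
bony-rim blob sits just deep of the tip, strictly on the deep side of the
bony roof line (so the roof tangent provably touches the tip); the labrum
center is placed so the rim-to-labrum line makes exactly β with the
baseline.  Ground-truth landmarks, boxes and angles are therefore exact
(float precision), and any recovery error measured downstream belongs to
the measurement pipeline, not the data.

Defaults: 256×256 px, background 25, structure contrast 170 gray levels,
band width 8 px, blob radii 4–6 px (all scaled with image size), no noise,
no curvature.  Curvature bows the band toward the deep side only, which
leaves the superficial tangent — and hence the true angles — unchanged
while degrading the shape scores.  Speckle is approximated by additive
zero-mean Gaussian noise clipped to [0, 255]; attenuation, shadowing and
realistic speckle statistics are out of scope, so passing tests demonstrate
the correctness of the geometry and scoring logic, not clinical-grade
robustness.

**Sweep videos** render one frame per tilt-trajectory entry.  Frames off
the standard plane carry obliquity-distorted apparent angles, α + 0.4·tilt
and β + 0.3·tilt (deg/deg, clipped to valid ranges): an oblique section
through the acetabulum genuinely changes the apparent roof angles, and this
linear model is the phantom's minimal representation of that effect — it is
what makes selecting a tilted frame costly, as it is clinically.  The
`make_sweep_video` convenience adds a conspicuity profile in which blob
visibility is lowest at the standard plane and rises toward the sweep ends
(plus uniform jitter): detector confidence tracks structure conspicuity,
not plane quality, so a confidence-sum frame selector is pulled off-plane
while the shape-aware score is not.  This is the phantom analogue of the
motivating failure mode of confidence-only selection.

The designated best frame of a video is the earliest frame minimizing
|tilt| among frames with all four structures visible.

## Agreement statistics

Differences are method − reference.  SD uses the sample (n−1) denominator
throughout, matching Bland–Altman convention; limits of agreement are mean
± 1.96·SD.  The ICC form is ICC(2,1) — two-way random effects, absolute
agreement, single measures — the standard choice for method-vs-rater
agreement; it is computed from the mean-squares decomposition with the
F-based confidence interval of McGraw & Wong (1996), and defined as 1 for
zero-variance data.  Cohen's κ uses marginal-product expected agreement and
is defined as 1 when both raters are constant and identical.  ICC and κ are
implemented in-package and cross-checked in the tests against pingouin and
scikit-learn respectively.

## Problem sizes in the test suite

The suite verifies: moment computation against a naive double loop (100
random regions, 1e-9 relative); orientation recovery on rendered bars at
±{0,7,15,30}° within 1°; Kapur thresholds against exhaustive search on 100
random histograms; tangent points against the O(n²) one-sided check on 50
random star-shaped contours; angle recovery over the α ∈ {50…75} × β ∈
{40,55,70} phantom grid (MAE α ≤ 2°, β ≤ 2.5° noise-free with true boxes;
MAE α ≤ 3° at noise σ=5 with the heuristic detector); plane selection over
20 seeded sweeps (≥ 95% agreement with the designated best frame, and lower
α MAE than the confidence-sum baseline); ICC against an independent
implementation to 1e-6 on 20 datasets and parameter recovery within ±0.05
at n = 1000.  These sizes keep the full suite under a minute on one CPU
while leaving each estimate's sampling error well below its tolerance.

## Known limitations

* Binary type I/II only; Graf subtypes and D/III/IV morphologies (and the
  age information their refinement needs) are out of scope.
* Landmark localization uses mask geometry, not sub-pixel edge refinement;
  recovery error is dominated by ~1 px discretization of the tangent point
  and rim pixel, i.e. ~1° at the phantom's 256-px scale.
* The phantom's simplicity means detector-facing results (IoU, confidence
  behavior) say nothing about performance of a real detector on clinical
  images; the detector contract exists precisely so a trained model can be
  plugged in and evaluated with the same downstream code.
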