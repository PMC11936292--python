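# Methods

## Measurement model

The pipeline treats a frontal periocular photograph as a 512 × 512
analysis frame (top-left origin, x right, y down) with a 6-class label
raster: 0 background, 1 eyelid, 2 white area (exposed sclera), 3
caruncle, 4 iris, 5 pupil.  Everything downstream is boolean mask algebra
over this raster plus two detected circles, so the whole measurement is
deterministic: the same frame and configuration always produce the same
metrics, which is why the repeatability ICC of two identical runs is
exactly 1.

Assumptions: the eye is photographed frontally (pupil and iris are
modelled as concentric circles, not ellipses); the palpebral fissure is
spanned by a single smooth upper and lower lid curve between the two
commissures; the iris is the largest circular structure in the frame.
Off-axis gaze, specular highlights and eyelash clutter are out of scope —
for real photographs the segmentation is expected to come from an
external trained model through the pass-through backend.

## Stages

**Segmentation.**  The reference backend assigns each pixel to the class
whose configured intensity band contains it (band edges halfway between
the sorted class intensities), then removes connected components smaller
than 16 px (8-connectivity) and re-labels them from the modal label of
their resolved neighbours.  A minimum-size rule is used instead of
keeping only the largest component per class because the white area
legitimately splits into a medial and a lateral part on either side of
the iris.  This backend is scoped to synthetic scenes with well-separated
intensities; it makes no claim about real photographs.

**Edge detection.**  Canny in five stages: Gaussian smoothing
(σ = 1.4 px), 3 × 3 Sobel gradients, non-maximum suppression along the
gradient direction quantized to 45°, double thresholding at fractions of
the maximum suppressed magnitude (t_high = 0.20, t_low = 0.10), and
hysteresis keeping weak pixels 8-connected to strong ones.  Plateau ties
in the suppression are broken by comparing strictly against the
positive-direction neighbour and non-strictly against the negative one,
so a symmetric two-column step response keeps exactly one column.

**Circle detection.**  For each candidate radius (1 px steps) every edge
pixel votes at a = x − r cos θ, b = y − r sin θ with θ in 1° steps over
[0°, 360°).  Peaks are extracted in descending vote order (ties: smaller
radius, then row-major center), suppressing candidates within
`min_center_distance` of an accepted center; candidates whose center is
within 5 px *and* radius within 5 px of an accepted circle are also
suppressed, so a concentric search (`min_center_distance = 0`) can return
both the pupil and the iris without returning ±1 px ghosts of the same
circle.  By default detection runs on the class-boundary raster of the
mask (pixels 4-adjacent to another class): pupil boundary for the pupil,
outer boundary of iris ∪ pupil for the iris, with the radius search
narrowed to [d/4 − 2, d/2 + 3] px where d is the class region's
bounding-box extent (full-range search remains available through
`hough_circles`).  If the mask route fails and a raw image is available,
Canny on the image is used as a fallback.  Among admissible pairs
(pupil radius < iris radius, center separation ≤ 5 px) the pair with the
highest summed votes wins.

**Lid arcs and the whole-eye area.**  Lid curves are quadratic Béziers
whose control point lies on the perpendicular bisector of the commissure
chord.  In chord coordinates (u along, v outward-normal) any such curve
is v(t) = 2t(1 − t)·s, so: the apex (t = ½) sits halfway between chord
midpoint and control point, and the minimal displacement clearing a point
set has the closed form s = max v / (2t(1 − t)).  The analyzer estimates
the chord endpoints as the extreme-x pixels of the exposed region (median
y at that column).  Because those endpoints can be one or two pixels
inside the true commissures, the pointwise clearance ratio is
ill-conditioned near t = 0 and t = 1; the arc displacement is therefore
recovered by least squares over the exposed rim (which lies on the lid
curve itself), while the detected iris circle — sampled analytically on
its rim, restricted to t ∈ [0.03, 0.97] — contributes a hard clearance
constraint where the full disk protrudes past the lids.  The whole-eye
area is the region between the two arcs, filled column-wise with both
boundary rows included; generator and analyzer share this rasterization
so their area conventions agree exactly.

**Metrics.**  Areas are counts of true pixels; no sub-pixel weighting.
CER = 100·|cornea|/|full iris|; MWR/LWR split the white area at the
vertical line through the detected pupil center, pixels exactly on the
line counting as medial (medial = image-left for left eyes, image-right
for right eyes); their common denominator is |white| + |cornea|;
EER = 100·|exposure|/|whole|.  The exposure area excludes the caruncle by
default (`include_caruncle` flips this); the whole-area mask always
contains the caruncle region since it lies between the lids.
mm calibration: mm/px = 11.5 / (2·iris radius), treating the detected
iris diameter as the inter-limbal distance; 11.5 mm is the conventional
adult white-to-white diameter and is configurable.

## Synthetic scenes and what they do (not) show

The generator renders the same geometric family the analyzer assumes:
two quadratic Bézier lid arcs through the commissures (apex-controlled),
concentric iris/pupil disks clipped to the aperture (iris pixels under a
lid are labelled eyelid), a caruncle disk at the medial corner extended
to fill the aperture tip (canthal tissue; this also avoids degenerate
1–2 px white slivers), and flat per-class gray levels
(30/70/220/160/110/15) with optional Gaussian noise (default σ = 4 gray
levels, i.e. ≈ 7σ separation between adjacent class levels).  Ground
truth carries the exact label raster, the true circles, and analytic
pixel counts including the whole-eye area obtained by applying the same
minimal-clearance arc construction to the true geometry.  Randomized
scenes (`random_scene_params`) vary iris size (14–19% of the frame),
pupil size (30–50% of iris), lid droop from ~⅓-iris occlusion to fully
clear, and commissure placement.

Simulated cohorts draw per-eye pre/post EER values from the
severity-stratified normal distributions of a real surgical cohort
(mild, n = 51: 65.45 ± 6.96 → 74.87 ± 8.06%; moderate-to-severe, n = 49:
51.98 ± 7.11 → 75.87 ± 7.47%), truncated to [0, 100] by resampling (not
clipping) to avoid boundary point mass.  Pre and post values are drawn
independently — the published group summaries carry no pre/post
correlation — so simulated paired-t magnitudes are not comparable to the
published ones, while group means, improvement rates and agreement
statistics are.  The "manual" method adds zero-mean observer jitter
(default σ = 1.75 percentage points, back-derived from published
AI-vs-manual limits of agreement of −3.07/+3.80); the second automated
run is an exact copy of the first.

Passing tests on these scenes demonstrate correctness of the mask
algebra, circle voting, arc reconstruction and statistics on geometry
that satisfies the model's assumptions.  They do not validate the
segmentation of real photographs (textured skin, lashes, gradients,
brown irises), which enters only through the external-mask contract.

## Statistical conventions

ICC is single-measure, computed from the two-way mean-square
decomposition; models: one-way random ICC(1,1), two-way random absolute
agreement ICC(A,1) (default, the standard choice for method agreement),
and two-way mixed consistency ICC(C,1).  Confidence intervals follow
McGraw & Wong (Satterthwaite degrees of freedom for ICC(A,1)), matching
SPSS and pingouin.  Interpretation bands: ≥ 0.8 excellent, 0.6–0.8
substantial, 0.41–0.6 moderate, else poor.  Identical rater columns give
ICC exactly 1 with a degenerate CI of [1, 1].  Bland–Altman reports
bias = mean(a − b) and bias ± 1.96·sd (sample sd, n − 1), with the
difference direction fixed as first-minus-second argument.  Improvement
rate is 100·(post − pre)/pre on group means, reported to two decimals.
The one-way ANOVA compares pooled EER across methods; the two-way ANOVA
is fixed-effects severity × phase with interaction, using type-II sums
of squares for the mildly unbalanced 51/49 design.  p-values are
formatted to three decimals with a "< .001" floor.  Degenerate inputs
have fixed conventions: zero-variance paired differences give t = 0
(all-zero) or ±∞; all-identical ANOVA responses give F = 0, p = 1.

## Problem sizes

Sweep-style tests use 256 px frames (100-seed bound sweeps, mask-set
invariants) and 512 px frames where published-scale fidelity matters
(repeatability over 20 scenes, ground-truth EER recovery over 10 seeds
at < 1 percentage point error; a 30-scene sweep gives mean absolute
error ≈ 0.33 points).  Monte-Carlo calibrations use 2000 replicates for
the paired-t type-I rate and 300 for the two-way ANOVA null.

## Known limitations

- Circles only: elliptical projection under off-axis gaze is not
  modelled, and no specular-highlight handling exists.
- The reference segmenter is a synthetic-scene oracle, not a general
  segmenter; real-photo accuracy is entirely that of the external model.
- The whole-eye reconstruction assumes a near-horizontal commissure
  chord (each lid arc function-like in x); strongly tilted crops should
  be rotated upstream.
- Metrics are 2-D pixel counts; three-dimensional globe curvature is
  ignored.
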