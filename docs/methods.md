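# Methods

`fazmorph` measures the foveal avascular zone (FAZ) of 2-D en-face
OCT-angiography frames and evaluates the orientation of its maximum
diameter as a screening classifier for diabetic retinopathy (DR).  Because
no patient images ship with the package, a synthetic-angiogram simulator
generates cohorts whose ground truth reproduces the group statistics of a
published 54-eye case–control OCT-A study (25 healthy eyes, 29 DR eyes;
both the superficial and the deep capillary plexus).  This note records the
models, the defaults, and the design decisions behind both halves.

## 1. Morphometry

### Segmentation

An en-face frame is a grayscale flow map (0 = no de-correlation signal).
Vessels are binarised at a configurable threshold (default 100 on the 8-bit
scale) and morphologically closed with a disk of radius 2 px.  The closing
radius bridges sub-capillary speckle but is deliberately smaller than a
true arcade gap, so pathology is preserved.  The FAZ is the avascular
4-connected component containing the frame-centre pixel.  Three guards
reject degenerate frames:

* centre pixel on a vessel → off-centre fixation, eye excluded;
* component touching the frame border → FAZ not fully imaged (this also
  catches empty frames);
* component covering more than 50 % of the frame → implausible mask.

The boundary is extracted as a sub-pixel marching-squares contour after
2× bilinear upsampling and Gaussian smoothing (σ = 2.5 px at the original
scale).  Smoothing matters: the direction of the maximum chord of a convex
region is ill-conditioned (the width function is flat near its maximum), so
half-grid quantisation of a raw binary contour leaves several degrees of
wobble on the measured angle; the smoothed contour brings this to ≈1.5–2°
while biasing diameters by less than 0.4 %.

### Diameters and the angle

Every reported diameter is a **Feret extent** — the width of the boundary's
projection onto a direction — rather than a through-centroid chord.  Feret
extents remain well defined for the concave, gap-broken FAZ shapes of DR
and coincide with the intuitive "longest line" a human grader draws:

* maximum diameter: maximum Feret diameter, computed by rotating calipers
  on the convex hull of the boundary (antipodal-pair sweep; verified in the
  tests against an O(n²) all-pairs oracle to 10⁻⁹ px);
* horizontal / vertical diameter: Feret extent at 0° / 90°;
* perpendicular diameter: Feret extent at (maximum angle + 90°).

Angles live in [0, 180), 0° = image horizontal, counter-clockwise positive
after flipping the image y-axis (pixel rows grow downward).  Among chords
tied for the maximum length the smallest angle wins, which makes results
deterministic on symmetric masks (a square yields 45°, not 135°).

Pixel lengths convert to micrometres by exact multiplication with the scan's
pixel pitch (6.579 μm/px for a 2 mm scan sampled 304 × 304; the scale is a
parameter because instruments also offer 3 mm scans).

### Angle typicality

An angle within 15° (inclusive) of the horizontal or vertical axis is
*typical*, everything else *atypical*; distances are taken modulo 180°, so
165° is typical.  Whether the clinical rule's "±15°" was inclusive is not
documented anywhere; inclusivity is this package's documented convention.
An atypical angle is the positive test for DR.

## 2. Synthetic cohorts

### Geometry of one eye

The FAZ of an eye/layer is an ellipse (semi-axes a ≥ b, orientation θ).
Healthy eyes keep a closed perifoveal capillary arcade; DR eyes receive 1–3
arcade gaps of 15–35° angular width each, peripheral capillary dropout
(5–25 % of mesh segments), and occasional signal-void shadow artifacts.

### Matching the published group statistics

The published statistics per (group × layer) are the mean ± SD of the
horizontal and of the maximum FAZ diameter, plus the fraction of eyes with
a typical angle.  A three-parameter ellipse cannot reproduce all four
diameter moments and the orientation law simultaneously, so the generator
is built around two exact constraints and one calibrated one:

1. **Horizontal diameter**: drawn from a normal with the configured
   mean/SD, truncated at zero (truncation shifts these means by ≤ 0.3 %,
   a documented small bias).
2. **Orientation**: exact stratification — ⌊typical_fraction · n⌉ eyes per
   cell draw θ uniformly from [−15°, 15°] ∪ [75°, 105°] (mod 180), the rest
   uniformly from the complement.  The published typicality proportions are
   therefore reproduced exactly at the study's n, every seed.  No
   orientation distribution for atypical eyes is published;
   uniform-on-complement is an assumption.
3. **Maximum diameter**: the major axis is a = h / (2 g(θ; q)) with
   g(θ; q) = √(cos²θ + q² sin²θ) the normalised horizontal extent of an
   aspect-q ellipse.  The per-cell aspect ratio q solves
   E[1/g(θ; q)] = mean_max / E[h] under the stratified orientation law
   (numerically, by quadrature and bisection), so the maximum-diameter
   group mean matches its configured value.  The maximum-diameter SD is
   then implied by the geometry (within ~10 % of the published SDs).

Calibrated aspect ratios for the reference parameters: 0.75 (control
superficial), 0.82 (control deep), 0.58 (DR superficial), 0.65 (DR deep) —
DR FAZs are more eccentric, which is what the published horizontal/maximum
ratios imply.

### Cohort-exact sampling

By default the horizontal-diameter quantiles of each cell are drawn by
randomized Latin hypercube: one uniform draw per quantile stratum of the
truncated normal, assigned to eyes by their latent size rank.  Each draw is
still marginally the configured truncated normal (within-cohort SDs are
preserved), but the cohort mean reproduces the configured mean to ≈ 1 % at
n = 29 — the same exact-reproduction philosophy as the orientation
stratification, and the reason a 10-seed average of simulated cohorts can
be compared against the published group means at a 3 % tolerance at all
(under iid sampling that band is only ≈ 1.4 standard errors of the cohort
mean, so a comparison would fail a fifth of the time by luck).  Plain iid
sampling remains available (`CohortParams.sampling = "iid"`).

The two plexus layers of one eye share a latent size factor (rank coupling,
`layer_corr` = 0.8, realised inter-layer size correlation ≈ 0.6), since
both belong to the same retina.

### Visual acuity

BCVA (ETDRS letters) is linear in the eye's FAZ size with Gaussian noise:
`letters = 96 − 0.015 · mean(max diameter of the two layers) + N(0, 8)`,
clipped to [0, 100].  The slope sign follows the clinical direction (larger
FAZ → fewer letters); published rank correlations for these data are
inconsistent between text and figures (0.43 vs 0.53 etc.) and even in sign
convention, so only the magnitude of Spearman's rho is exercised (the
defaults land |rho| ≈ 0.4–0.7 at n = 54).  Snellen fractions convert to
letters by the standard chart relation `85 + 50·log₁₀(fraction)`.

### Rendering

A frame is rendered at 304 × 304 px.  The scan width is chosen per eye as
the smallest of 2/3/4/6 mm that holds the FAZ with ≥ 10 % margin —
mirroring the 2 mm vs 3 mm protocol choice an operator makes; measured
micrometre values are scale-invariant.  The image is composed of:

* the **arcade**: a 2-px capillary ring hugging the ellipse boundary
  (pixels within 2 px Euclidean distance outside the ellipse);
* the **mesh**: Delaunay edges of a jittered lattice (spacing 55 μm, a
  realistic inter-capillary distance) drawn at 1–2 px thickness, clipped
  to stay outside the arcade band, plus a dense ring of lattice sites just
  outside the arcade so the mesh faces adjacent to the FAZ are shallow;
* **gaps** (DR): the arcade band is erased over each gap's angular sector,
  so the avascular region grows through the gap into the shallow adjacent
  faces — strictly larger area, but only a ≈ 0.5 % mean inflation of the
  measured diameters, because the ground-truth ellipse already represents
  the enlarged FAZ that a grader would measure;
* **dropout** (DR): a fraction of mesh edges away from the arcade
  (protection zone ≈ 8 px) is deleted;
* **shadows** (DR, rate 0.25): a signal-void disc of 80–200 μm radius
  placed clear of the arcade — shadowing from overlying hemorrhage or
  edema obscures flow signal, but a grader would not trace an artifact
  void as FAZ, so it never merges with the measured region;
* intensities: background speckle U(0, 40), vessels U(170, 255) — the wide
  plateau makes segmentation threshold-robust, matching binarised clinical
  reading.

Rendering is deterministic given the eye's render seed; seeds derive from
the cohort master seed by a documented `SeedSequence.spawn` order (one
child for sampling, then one per eye × layer).

### What the simulator does not emulate

SSADA de-correlation physics, flow directionality, projection artifacts,
3-D structure, motion artifacts, microaneurysms, vessel calibre
distributions, and the segmentation-plane errors of real instruments.
Passing tests therefore demonstrate that the measurement and statistics
pipeline is correct and unbiased on images with known ground truth — not
that it would segment real pathology-laden frames robustly.

## 3. Grader simulation and agreement

Two masked graders are simulated by adding zero-truncated Gaussian noise to
each diameter and wrapped Gaussian noise to the angle; the maximum diameter
is re-asserted as the largest of the grader's four readings.  The default
diameter noise SD of 140 μm is calibrated so that ICC(2,1) over a pooled
54-eye layer lands near the clinically reported 0.857: with a between-eye
SD of ≈ 343 μm (both groups pooled), ICC = 343²/(343² + 140²) ≈ 0.857.
The default angle noise SD is 5°, which yields near-perfect typicality
kappa, consistent with the reported 0.889.

ICC(2,1) follows Shrout–Fleiss: two-way random effects, single measure,
absolute agreement, `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`,
with the F = MSR/MSE p-value; it is tested against an independent ANOVA
oracle and against pingouin's ICC(A,1).  Cohen's kappa uses the
marginal-product chance correction with the large-sample normal p.

## 4. Diagnostics and cohort statistics

The 2×2 table crosses group (DR/control) against angle class
(atypical/typical); sensitivity = atypical DR eyes / DR eyes, specificity =
typical control eyes / control eyes.  Confidence intervals are exact
Clopper–Pearson binomial intervals (beta-quantile form).  Association uses
Pearson's chi-square without continuity correction (Yates available as an
option).  When a published table must be rebuilt from printed percentages,
counts are the rounded products and are asserted to round-trip to the
printed percentages at one decimal.

Group comparisons use the Mann–Whitney U test with midrank ties: exact
enumeration when both groups have ≤ 8 tie-free observations, otherwise the
tie-corrected normal approximation without continuity correction (the
convention of the clinical statistics packages this mirrors).  Spearman's
rho uses midranks with the t-approximation p.  The Shapiro–Wilk test acts
as the parametric/non-parametric gate at α = 0.05 and its decision is
logged.  Eyes are treated as independent observations — deliberately
mirroring the clinical analyses modelled here, which compare 29 eyes of 15
patients against 25 eyes of 22 patients without clustering adjustment; no
multiple-testing correction is applied, for the same reason.  Both are
documented limitations.

## 5. Problem sizes and tolerances

The test suite and the acceptance script run the full render-and-measure
pipeline over 10 cohorts of 54 eyes per layer (≈ 1100 frames), enumerate
geometry oracles over 200 random masks, and simulate 100 cohorts for the
power check — sizes chosen so the whole battery completes in a few minutes
on one CPU while keeping Monte-Carlo error well below the tolerances
asserted (3 % on group means, 1° on angle consistency, 10⁻⁹ px on the
calipers/brute-force equivalence, 10⁻¹⁰ on agreement statistics).

## 6. Known limitations

* The rendered avascular region is bounded by discrete pixels; diameters
  carry ≈ ±0.5 % discretisation noise per eye and the maximum-Feret angle
  ≈ 1.5–2° of wobble, so a small net drift (≈ 1–2 eyes per 25) from
  typical to atypical is expected for eyes drawn near the ±15° class
  boundary.
* Published CI bounds for sensitivity/specificity could not be reproduced
  to the last printed digit by any standard interval (Clopper–Pearson
  matches to ≈ 0.05–0.2 percentage points on upper bounds and ≤ 0.04 on
  lower); the package reports true Clopper–Pearson intervals.
* The maximum-diameter SD per cell is implied by the ellipse geometry
  rather than configured independently; it differs from the published SDs
  by up to ~10 %.
* Control BCVA variance is larger than the published control SD (one
  global noise term serves both groups).
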