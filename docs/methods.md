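# Methods

## Color models and their dialects

All four transforms start from 8-bit sRGB and are computed per pixel
in double precision; nothing is re-quantized before averaging.

* **RGB** is reported on the native 0–255 scale.
* **HSV** uses the hexcone model: V = max(r,g,b), S = (max−min)/max
  (0 when max = 0), and the piecewise hue formula scaled to [0, 1)
  with 1.0 wrapped to 0.  Achromatic pixels get H = 0 by convention
  so region averages stay deterministic; the mathematical hue is
  undefined there.
* **CIE L\*a\*b\*** assumes sRGB gamma and the D65 white point — the
  default dialect of mainstream conversion routines.  The white point
  is taken as the image of sRGB white under the sRGB→XYZ matrix, so
  (255, 255, 255) maps to exactly L\* = 100, a\* = b\* = 0.  The CIE
  f(t) function uses the cube root above (6/29)³ and the linear
  segment below it.
* **YCbCr** uses BT.601 *studio-swing* coefficients, fixed by the
  nominal ranges 16–235 (Y) and 16–240 (Cb, Cr); full-swing
  JPEG-style YCbCr is deliberately not offered.

No ICC profile handling, chromatic adaptation, or camera calibration
is attempted: the acquisition protocol this mirrors controlled
illumination at the device (200 ± 10 lux), which is what makes raw
colorimetry meaningful.

## ROI reduction

A capture is reduced to one 12-vector by converting every pixel
inside a circular ROI and averaging each parameter.  Conventions:

* Pixel coordinates are 0-based; a pixel's location is its integer
  index; membership is Euclidean distance ≤ radius.  The center is
  ((W−1)/2, (H−1)/2), which makes the mask symmetric under 180°
  rotation.
* The design radius is 300 px at the device resolution of
  1624 × 1212 px over 1 cm², i.e. a ~3.7 mm-radius disc of skin.  For
  smaller images the radius shrinks to the largest inscribed disc (a
  strict mode raises instead), which lets tests run on small rasters.
* Averaging is convert-then-average.  For nonlinear models the order
  matters and a regression test pins it.
* Hue is averaged arithmetically, matching a matrix mean of the
  converted image.  This is statistically improper for circular data
  near the red wraparound (H ≈ 0 ≡ 1); skin hues sit at ~0.09–0.14,
  far from the seam, so the bias is negligible here — flagged, not
  corrected.
* No pixel exclusion (saturation, hair, specularities) is applied.

## Statistical procedures

Subjects are the repeated unit.  The four site measurements per
breast are averaged into one value per subject × breast × time before
any test; a site-level pairing mode exists for the dose correlation.

* **Two-way repeated-measures ANOVA** (group × time, both within
  subject): sums of squares partitioned with subject, subject×group,
  subject×time and subject×group×time error strata.  For each
  multi-level effect, Mauchly's test runs on the covariance of its
  orthonormal (Helmert) contrast scores — collapsed over the other
  factor for main effects, Kronecker contrasts for the interaction.
  Greenhouse–Geisser ε (from the eigenvalues of that covariance)
  scales the degrees of freedom *only* when Mauchly rejects at 0.05;
  a singular contrast covariance (too few subjects) is treated as a
  violation so the conservative correction applies.  The group factor
  has two levels, hence one contrast and trivially satisfied
  sphericity.  With a single group the procedure degenerates to the
  one-way RM-ANOVA and equals the squared paired t test at two time
  levels.
* **Wilcoxon signed-rank** (irradiated vs control, per parameter and
  time point): zero differences discarded, midranks of |d|, statistic
  = min of the signed-rank sums; exact sign-flip p for ≤ 15 tie-free
  pairs, otherwise normal approximation with tie and continuity
  corrections (both via scipy).  Significance is judged at the
  Bonferroni level α/m; m defaults to 3, the divisor that yields the
  conventional 0.0167 (which post-baseline comparisons it covers is a
  protocol choice; m is configurable).
* **Spearman correlation**: midranks, rho = Pearson correlation of
  rank vectors.  The p-value uses exact enumeration of all n!
  pairings for n ≤ 8 and the t approximation
  t = rho·√((n−2)/(1−rho²)) otherwise — the behavior of mainstream
  statistics packages at the study's n = 20.  Note the t
  approximation is slightly anti-conservative: its measured exact
  null rejection rate at n = 20 and α = 0.05 is 0.0509, so a
  long-run ~5.1% of null dose-correlation cells will clear the 0.05
  reporting mask.
* **Dose correlation table**: per parameter and post-baseline time
  point, Spearman of the patient's mean skin dose against the
  site-averaged parameter; entries with p ≥ 0.05 are masked in the
  report.  RTOG-grade correlations return NaN with a note when the
  cohort is grade-constant (the expected outcome for an all-grade-1
  cohort) instead of erroring.

## The synthetic cohort generator

No public image set exists for this design, so the generator
produces cohorts with the statistical structure the analysis assumes
and known ground truth.  Per patient: a baseline skin tone drawn in
L\*a\*b\*; per site, constant small tone offsets; per image, a uniform
base color, converted to sRGB through the inverse L\*a\*b\* path, plus
i.i.d. Gaussian channel noise (SD 2.0 of 255), clipped to [0, 255].
Pixels stay floating point so that at zero noise the extraction
recovers the constructed color to machine precision (a round-trip
test uses this).

Erythema is additive in a\* — physiologically, erythema is a redness
shift: the irradiated breast gains
`dose_slope_a · dose · time_profile[t]` in a\*, plus fraction 0.38 of
that shift in b\* and minus fraction 0.11 in L\*.  With the defaults
(`dose_slope_a` = 0.03 per cGy, `time_profile` = (0, 0.36, 0.72, 1))
and typical first-fraction skin doses of ~190–280 cGy this
reproduces the reported magnitudes of a mild clinical cohort: a\*
rising from ≈ −1 to ≈ +6.5, R from ≈ 189 to ≈ 200, S from ≈ 0.26 to
≈ 0.33, with monotone trends R↑ G↓ B↓ H↓ S↑ V↑ L\*↓ a\*↑ b\*↑ Y↓ Cb↓
Cr↑ on the irradiated breast.  The control breast receives only a
small symmetric per-time drift (SD 0.3 Lab units), so paired
comparisons are null when the dose effect is switched off.

Skin doses are drawn per site as uniform positions inside
site-specific sub-intervals of the clinical range (default
186.7–284.0 cGy, the observed span): the inner site's sub-interval
sits lowest and upper/lower highest, mimicking tangential-field
dosimetry, and the four sites share a patient-level component
(weight 0.75) reproducing the uniformly-high/uniformly-low patients
seen in measured tables (patient-mean SD ≈ 11–15 cGy).  A degenerate
interval collapses every dose to its single value.

Baseline tone ranges (L\* 71.8–72.2, a\* −1.4 to −0.6, b\* 19.5–20.5)
were set from a sensitivity analysis of each parameter's Jacobian
with respect to (L\*, a\*, b\*) so that the dose-driven signal in each
erythema-linked parameter (R, S, V, a\*, Cr) is at least comparable
to the between-patient baseline spread, making dose-response
recovery identifiable at n = 20.  This deliberately models a
tone-homogeneous cohort: real populations have far larger baseline
variance (reported between-patient SDs are 3–10× these), plus skin
texture, hair, specular highlights and registration error that the
generator does not attempt.  Passing recovery tests therefore
demonstrates that the *pipeline* recovers a dose effect of clinical
magnitude under controlled conditions, not that the method attains
this sensitivity on real photographs.

RTOG grades are produced by thresholding the patient's final a\*
shift (grade 1 above 3.0, else 0) and carried as metadata only; the
defaults give an all-grade-1 cohort, matching mild clinical series.

Reproducibility: one master seed expands into per-image substreams
keyed by (patient, breast, site, time point), so any subset of a
cohort regenerates identically.

## Problem sizes and numerical choices

* Default synthetic images are 128 × 128 (ROI radius auto-shrunk to
  63.5 px); the native 1624 × 1212 size is available via
  `image_size`.  Test fixtures use 16–32 px images; the null-cohort
  simulations in the acceptance checks use 24 × 24 images, 200 seeded
  cohorts of 20 patients, and the type-I calibrations use 2,000
  replicates at 20 subjects.
* Dose-table means are reported to 0.1 cGy; re-derivation tests use a
  ±0.05 rounding tolerance.
* Color conversions are validated to 1e-9 against independently coded
  scalar oracles; the Lab and HSV round trips hold to 1e-9.
* Ties in the dose-table site extremes increment every tied site
  (deterministic and conservative; the packaged table has no ties).
* Degenerate inputs: all-zero paired differences and constant
  correlation vectors raise at the stats layer; the report tables
  convert constant-vector correlations to NaN entries so one
  degenerate column cannot abort a report.

## Known limitations

* Arithmetic hue averaging near the red wraparound (see above).
* The t-approximation Spearman p at n = 20 is mildly
  anti-conservative (size ≈ 0.051 at the 0.05 level); exact
  enumeration is used only up to n = 8 (n! growth).
* The generator emulates color statistics, not skin appearance; no
  desquamation or grade ≥ 2 reactions are modeled.
* The ANOVA requires a complete design (listwise by construction);
  missing cells are reported, not imputed.
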