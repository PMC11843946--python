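# Methods

`leafcolor` implements a desk-scale version of an RGB-imaging workflow for
monitoring green-leaved and anthocyanin-rich leafy vegetables: single leaves
photographed on a matte white stage are segmented, their color summarized as
12 mean features in three color spaces, 22 vegetation indices are derived
(including the redness-based contrast indices SREx = R − G − B and
TREx = 2R − G − B), leaf pigments are quantified from spectrophotometric
absorbances, and index–pigment–SPAD relations are summarized by trendline
fitting and elbow detection.

## Color features

Per-pixel conversions, then averaging (not conversion of the mean RGB):

* **HSV** by the standard hexcone formulas, hue in **degrees on [0, 360)**.
  The degree convention is load-bearing: DGCI = [1 + H/60 − S − V]/3 divides
  hue by 60, which presumes a 0–360 hue circle. Achromatic pixels report
  H = 0. The inverse conversion is implemented as well and is exact on 8-bit
  inputs, which pins down the convention in tests.
* **CIE L\*a\*b\*** under the D65 illuminant and 2° observer with standard
  sRGB decompanding (via `skimage.color.rgb2lab`). The upstream imaging
  protocol fixes lighting and exposure, so no further color management is
  attempted (no ICC profiles, no white-balance correction).
* **Chromatic rgb** fractions r = R/(R+G+B) etc. A black pixel has no
  chromaticity; it is excluded from the fraction averages and counted in a
  quality field rather than raising.

Hue is averaged circularly (vector mean); everything else arithmetically
over the leaf mask.

## Segmentation

The acquisition rig guarantees a bright, nearly achromatic background, so
background is classified as *low saturation AND high value*: S below an Otsu
threshold computed on the saturation channel, intersected with V > 0.65.
The complement is cleaned by 3×3 morphological closing (2 iterations) and
hole filling, and the largest connected component is kept. Components
smaller than `min_pixels` (default 5000) are rejected by name with their
pixel count. All thresholds are exposed in `SegmentationConfig`. Shadows and
glare are not modeled (the rig eliminates them), and leaf midribs are *not*
excluded from masks — midrib avoidance applies to SPAD probing, which is an
input here, not to imaging.

If the whole image has constant saturation (no Otsu split exists) the
classifier degrades to "anything not bright is leaf".

## Vegetation indices

All 22 derived indices are computed from the per-leaf **mean** features.
Raw-channel indices (Intensity, GMR, ExG, R±G±B combinations, SREx, TREx)
use the 0–255 scale; NDI, WI, ExR, ExB use chromatic fractions; DGCI uses
(H°, S, V). Identities used in testing: TREx = (R−G) + (R−B) and
SREx = TREx − R.

Two conventions deserve note:

* **ExR/ExB.** Published tabulations of the excess-red/excess-blue pair are
  not consistent; this package uses the original literature semantics
  ExR = 1.4r − g and ExB = 1.4b − g. A `table1_literal` switch swaps the two
  assignments for comparison with tabulations that print them the other way
  around.
* **NDI** retains the +0.01 denominator stabilizer of its published form.

A vanishing denominator (e.g. VARI when G + R − B = 0, WI when r = g) yields
a flagged undefined value with a reason string; batch CSV output leaves the
cell empty and lists reasons in a parallel column, so degenerate leaves never
abort a run.

## Pigment quantification

With FW the fresh weight (g) and Vol the extract volume (ml):

* Chl (mg/g FW) = (18.71 A647 + 7.15 A663) · Vol / (1000 · FW)
* Car (mg/g FW) = (1000 A470 − 1822.85 A647 + 411.31 A663) · Vol / (198 · 1000 · FW)
* Anthocyanin: corrected absorbance A530 − 0.25 A657 (pheophytin
  correction), converted to mg/ml against a cyanidin-3-O-glucoside standard
  curve and scaled by Vol/FW.

The standard curve is ordinary least squares with a free intercept by
default; `through_origin=True` forces the line through zero. Negative
contents (possible with noisy absorbances) are flagged, never clipped, so
the pipeline stays auditable. Ratios Anth/Chl and Car/Chl are undefined when
Chl = 0 and flagged accordingly.

## Trendline fitting and model selection

Five families, matching spreadsheet trendlines: linear, quadratic (direct
least squares), logarithmic (least squares in ln x), exponential and power
(least squares on ln y — the linearization spreadsheets use). R² is
reported in the space where residuals were minimized and `fit_space` records
which space that was; an optional nonlinear refinement pass
(`refine=True`) polishes exponential/power estimates in the original space.
`best_fit` returns the admissible family with maximal R², breaking ties
(within 1e-9) toward fewer coefficients; families whose domain the data
violate (x ≤ 0 for log/power, y ≤ 0 for exp/power) are skipped with a log
note. Constant-y input defines R² = 0 with a degeneracy flag rather than
leaving it undefined. Undefined/missing pairs are deleted pairwise with the
retained count reported.

## Elbow detection (Extremum Distance Estimator)

A chord is drawn from the first to the last point and signed vertical
deviations d_i from the chord are examined:

* `ede_sigmoid` — midpoint of the abscissas of min(d) and max(d); for
  S-shaped data whose deviations change sign.
* `ede_knee` (default) — abscissa of max |d|; for one-signed
  convex/concave data, the "elbow" of a saturating trend, which is the
  relevant case for greenness-redness indices declining against Anth/Chl.

`analyze_relation(..., elbow=True)` locates the elbow on the **fitted**
curve evaluated on a 512-point uniform grid over the observed x-range, not
on the raw scatter; 512 is a fixed documented choice giving ~0.2% of the
x-range as resolution. Useful closed form: for y = a·ln x + b over
[x₁, xₙ] the chord extremum sits at x* = (xₙ − x₁)/ln(xₙ/x₁), independent
of a and b.

## Synthetic data

The generator exists to make every stage testable against known truth; it
is a statistical emulator, not a radiative-transfer or growth model.

**Images.** A rotated (optionally lobed) ellipse of requested pixel area is
rasterized exactly (the polygon mask *is* the ground truth), painted with a
base color plus i.i.d. Gaussian channel noise, on a near-white background
(250 ± 3 per channel) so segmentation is non-trivially exercised. Fixed seed
gives byte-identical images.

**Study tables.** Default n = 320 in three anthocyanin classes
(high/medium/low = 100/100/120) with class-specific pigment ranges
(Chl 0.06–2.3, Car 0.03–0.38, Anth 0.001–3.42 mg/g FW across classes).
Generating relations: SPAD = 40·Chl^0.55 + noise (power, range ≈ 6–62);
Car linear in Chl; G/R = a·ln(Anth/Chl) + b + noise with a = −0.17 and b
chosen so G/R = 1 at the knee; mean R linear in the noiseless SPAD signal;
G = R·(G/R); B chosen so TREx = 2R − G − B is an exact linear-in-SPAD signal
plus its own noise. Every form is exactly representable by one of the five
trendline families, so the zero-noise dataset fits with R² = 1.

Two deliberate design choices:

* The Anth/Chl covariate is laid out on a deterministic per-class
  log-spaced design (randomness enters through response noise and the
  conditional Chl draw). Because the EDE elbow of a logarithmic curve
  depends only on the x-range, the generator *solves the upper end of the
  Anth/Chl range from the configured knee* (default 0.2, giving a range of
  ≈ 0.005–1.08); the ground-truth elbow is then exactly the knee parameter
  and is stable across seeds.
* When `gr_target_r2` is set (default 0.85), the G/R noise sd is computed
  from the realized design as sd(signal)·√(1/R² − 1), so the sample R²
  concentrates on the target without per-seed tuning.

What the generator does **not** emulate: venation and midrib structure,
specular highlights and shadows, within-leaf pigment gradients, camera
noise correlated across channels, and any real covariance between Anth and
Chl beyond the class structure. Passing recovery tests therefore shows the
*pipeline* is correct and well-calibrated, not that real leaves satisfy
these functional forms.

## Problem sizes and numerical choices

The test suite runs 50-leaf segmentation batches on 300×400 canvases
(~20,000 px leaves) and 100-seed repetitions of the n = 320 study
experiment; both complete in seconds and are the package's reference
experiment sizes. Tolerances: index oracle agreement at 1e-12; Lab anchors
at 0.05; noiseless fit recovery at 1e-6 relative with R² within 1e-9;
noisy-mean recovery at 3·sd/√n. Ties in model selection break at 1e-9 in
R². Degenerate inputs (black pixels, constant y, zero denominators) are
flagged, not raised, except where a contract is plainly violated (shape
mismatches, nonpositive FW/Vol, non-monotone x for the EDE).

## Known limitations

* Segmentation assumes a single leaf on a near-white background; multi-leaf
  scenes, canopies and illumination correction are out of scope.
* The exponential/power R² is not comparable across fit spaces in a strict
  sense; `fit_space` makes the convention explicit rather than hiding it.
* Lab conversion constants follow the sRGB/D65 standard; a camera with a
  different profile would need external calibration (not provided).
* Anthocyanin quantification depends on a user-supplied standard curve; no
  default curve is shipped because standard concentrations are
  instrument-specific.
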