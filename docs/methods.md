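# Methods

## The problem

A thyroid nodule is delimited from the surrounding parenchyma by a fibrous
collagen capsule. The capsule's texture carries diagnostic signal: in
bright-field images of H&E-stained sections, capsules of benign follicular
adenomas (FA), papillary thyroid carcinomas (PTC) and the rare PTC arising
within a follicular adenoma (PTCFA) differ in brightness, texture regularity
and fiber architecture. `capsuletex` implements a classical
feature-engineering route to that signal: convert RGB tiles to four 8-bit
images, summarize each with four feature families (56 features per tile),
filter features by class separability, and classify tiles with a two-stage
random forest evaluated at the patient level.

## RGB → 8-bit conversion

Four strategies per tile:

* **8b** — round((R + G + B)/3), the unweighted intensity image;
* **8bw** — round(0.299 R + 0.587 G + 0.114 B), perceptual weighting;
* **RED** — the red channel (eosin stains collagen pink/red, so most of the
  capsule contrast lives here);
* **EOSIN** — the eosin channel obtained by color deconvolution.

Color deconvolution uses the Beer–Lambert model. Per channel
OD_c = −log10(I_c / I₀) with background I₀ = 255; the OD vector of a pixel
is a non-negative mixture of unit stain OD vectors, and multiplying by the
inverse stain matrix unmixes the pixel into (hematoxylin, eosin, residual)
concentrations. Default stain vectors are the standard published H&E pair,
hematoxylin ≈ (0.650, 0.704, 0.286) and eosin ≈ (0.072, 0.990, 0.105)
(normalized; residual = their cross product). They are a configuration
input: any lab-calibrated pair can be substituted. The EOSIN image maps the
eosin concentration back through the transmittance law
round(255·10^(−c_e)), so 255 = no eosin and darker = more stain, keeping
the bright-field semantics of the other three strategies.

Numerical conventions: intensities are clamped to ≥ 1 before the log so OD
stays bounded; negative concentrations (pixels outside the stain simplex)
are clamped to 0; all intensity rounding is half-away-from-zero. The
forward model `synthesize_rgb` is the exact inverse of the deconvolution,
so synthesized pixels round-trip within 8-bit quantization (measured
maximum error < 0.01 OD for concentrations in [0.05, 0.8]).

## The 56-feature battery

Per 8-bit image, four families (4 + 5 + 3 + 2 = 14 features; × 4
strategies = 56):

* **Histogram moments** — Mean; sample SD (n−1 denominator); skewness
  m₃/m₂^1.5 and excess kurtosis m₄/m₂² − 3 with population central moments
  (the conventions of ImageJ's Measure command). For 8-bit input the
  moments are computed exactly from the 256-bin histogram. Constant images
  yield (value, 0, 0, 0).
* **GLCM texture** — gray-level co-occurrence matrix at offset distance 1,
  four directions (0°, 45°, 90°, 135°), symmetric, 256 gray levels (no
  requantization); each direction's matrix is normalized before the four
  are averaged. Statistics: ASM = Σp², Contrast = Σ(i−j)²p,
  IDM = Σp/(1+(i−j)²), Entropy = −Σp ln p (natural log, 0·ln 0 := 0), and
  Correlation = Σ(i−μx)(j−μy)p/(σxσy), defined as 0 when σxσy = 0.
* **Local orientation** — per-pixel structure orientation from the 2×2
  structure tensor (Gaussian window σ = 2 px, 3σ kernel cutoff):
  ½·atan2(2J_rc, J_rr − J_cc) over the (row, column) gradient products,
  mapped to (−90°, 90°] with 0° = horizontal structures. Pixels with tensor
  energy below 10⁻⁶ of the image maximum are invalid. Features are the
  plain (non-circular) SD, skewness and excess kurtosis of the valid
  angles; the mean is excluded because it only reflects how the section
  lies on the slide. Fewer than two valid pixels → (0, 0, 0).
* **Binary measures** — Triangle (Zack) thresholding on the 256-bin
  histogram: a line from the histogram peak to the farthest non-empty tail
  bin; the threshold is the bin maximizing perpendicular distance to that
  line (raw counts and bin indices; distance ties take the bin nearest the
  peak; a constant image thresholds at its own value, giving an empty
  foreground). Foreground = pixels *below* the threshold, since stained
  structures are darker than background in bright field. TC-ratio is the
  foreground fraction; FD is the box-counting fractal dimension over box
  sizes 2, 4, 8, … up to min(H, W)/4 on a grid anchored at the origin,
  estimated as the unweighted least-squares slope of log N(s) vs
  log(1/s). Empty masks give FD = 0 by convention.

Every feature is finite by construction; the degenerate conventions above
are what make that hold on pathological inputs.

## Selection

The Fisher score of feature j is
F_j = Σ_k n_k(μ_kj − μ_j)² / Σ_k n_k σ²_kj over classes k, with population
class variances (zero pooled within-class variance scores 0 with a
warning). Features above the mean score over all 56 are retained. Per
feature, a one-way ANOVA across the three classes with step-down Holm
adjustment at α = 0.05 provides the significance assessment; star codes
*, **, ***, **** map to adjusted-p thresholds 0.05, 0.01, 0.001, 0.0001.

## Two-stage random-forest classification

Splits are made at the **patient** level: each class's patients are
randomly partitioned ≈ 60/20/20 % into train/validation/test (at least one
patient per class per set, requiring ≥ 3 patients per class), and every
tile inherits its patient's set. This is the leakage control the whole
evaluation rests on; it is asserted before every fit.

Stage one grows a Gini random forest F (default T = 450 trees,
m = ⌈√p⌉ features tried per node, bootstrap samples of size n, minimum
leaf size 1, no depth cap) on the training tiles with all 56 features and
ranks features by Gini importance — the total impurity decrease
attributable to each feature, averaged over trees and normalized to sum
to 1 (ties rank by ascending feature index). Stage two keeps the top
N = 30 features and grows a second forest F′ on the reduced training data;
F′ classifies the test tiles by majority vote. Per-class precision, recall
and F1 (one-vs-rest, 0/0 := 0) are aggregated as mean ± SD over 10
repeated splits. Internally the feature columns are put into a canonical
name-sorted order before fitting and the selected index set is applied in
ascending order, so predictions do not depend on the caller's column order
and N = p is a strict no-op.

T = 450 and N = 30 follow the validation-chosen operating point of the
procedure this package implements; m, the split fractions and the number
of repeats are not dictated by it, so the defaults above are this
package's own choices and are all configurable. Baselines — KNN (k = 5),
linear and RBF SVM, AdaBoost (100 estimators), each standardized per
training split — run on all 56 features over the same splits; they are
comparison plumbing (scikit-learn at defaults), not the contribution.
The forests themselves are scikit-learn estimators behind this module's
interfaces; the importance definition above is the normative contract and
is tested against planted-signal oracles.

## The synthetic cohort generator

No capsule image data is publicly deposited, so the pipeline ships with a
generator whose defaults define the reference study conditions: 280, 240
and 216 tiles for FA, PTC and PTCFA over 7, 7 and 5 patients (736 tiles,
19 patients). Each tile is a rendered band of fibers:

* `n_waves` fiber systems lay down parallel Gaussian-profile ridges
  (spacing `wavelength`, profile width 0.12 × spacing) at orientations
  jittered around a dominant direction; ridges are displaced sinusoidally
  along the fiber axis (`waviness`) and combine by maximum, giving the
  bimodal dark-fiber-on-bright-background histogram of stained collagen;
* the fiber field f ∈ [0, 1] scales a stain-density field
  g = 0.5 + od_contrast·f, and the pixel is the Beer–Lambert
  transmittance of concentrations (h_od·g, e_od·g) through the same stain
  matrix the deconvolution inverts, plus additive Gaussian noise
  (SD 2 intensity levels) — so stain round trips are exact up to
  quantization and the zero-absorbance limit is a white tile;
* each knob excites one feature family (total OD → Mean; od_contrast →
  SD/Contrast; wavelength, waviness, n_waves → GLCM texture and FD;
  orientation jitter → orientation statistics; eosin fraction → RED and
  EOSIN content), so every family is separately testable;
* each patient carries a log-normal brightness offset (SD 0.05 on the OD
  scale), making patient-level splitting genuinely different from
  tile-level splitting; each tile adds log-normal jitter (SD 0.15) on
  contrast, spacing and waviness plus a ±15° wobble of the dominant
  direction, because regions of interest on a real slide never repeat a
  texture exactly;
* the planted class effects encode the qualitative contrasts the pipeline
  is meant to detect: PTC brightest and FA darkest overall, FA
  eosin-heavy (hence brighter than PTCFA in the red channel), FA waviest
  and most complex (highest FD), PTCFA most compact and regular;
* the planted fiber mask (field above its profile half-maximum) is
  attached to each tile so binarization can be scored against ground
  truth (IoU > 0.7 at default parameters).

Everything is reproducible bit-for-bit from the cohort seed: patient
offsets, per-tile jitters and per-tile render seeds are all drawn from one
generator stream. Remainder tiles (counts not divisible by patients) go to
the lowest-indexed patients, deterministically.

What the generator does *not* emulate: nuclear or cellular morphology,
stain-uptake variation between batches, scanner optics, focus artifacts,
capsule curvature or neighboring-tissue context. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that planted
class differences of realistic magnitude are recoverable — not that real
capsules are classifiable at any particular accuracy. On this synthetic
cohort the planted effects are strong and the two-stage forest saturates
(macro-F1 ≈ 1.0); the reported metrics characterize the pipeline, not
thyroid pathology.

## Problem sizes

The study conditions use 1024-px tiles with nested 512- and 256-px center
crops. Feature extraction costs ≈ 0.7 s per 1024-px tile on one CPU;
desk-scale runs of the full 736-tile cohort therefore render directly at
256 px (one of the three study sizes, ≈ 0.05 s per tile), which is the
size the test suite and the acceptance script use end-to-end. The
`analyze_size` configuration switches the pipeline to the nested-crop
path when tiles are generated at 1024 px.

## Known limitations

* The orientation plugin and the GLCM macro of the original ImageJ
  workflow are not fully specified upstream; the structure-tensor
  orientation and the Haralick-standard GLCM here are documented,
  configurable stand-ins, and numerical parity with the original feature
  values is not claimable (nor is it needed for the pipeline's logic).
* The exact H&E stain-vector preset behind the original deconvolution is
  unknown; the standard published vectors are the default and any pair can
  be configured.
* Non-circular moments on axial orientation data are wrap-sensitive near
  ±90°; the generator keeps dominant directions near 0° so the planted
  orientation contrasts stay in the linear regime, and real capsule
  images with fibers near the wrap point would need circular statistics.
* Box-counting FD uses a single origin-anchored grid (no offset
  averaging), matching basic Fractal-Box-Count behavior; values on small
  masks carry the usual finite-size bias (the depth-5 Sierpinski carpet
  measures ≈ 1.87 against the analytic 1.893).
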