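# Methods

## Problem and data model

The package classifies dried wolfberries into four producing regions from
near-infrared hyperspectral cubes.  A cube is a `rows × cols × bands` raster
of raw sensor counts with a strictly increasing wavelength axis; the default
instrument axis has 256 bands spanning 874–1734 nm (≈3.4 nm spacing) and a
320-pixel frame width.  Raw counts become relative reflectance through the
standard white/dark correction `R = (I_raw − I_dark)/(I_white − I_dark)`,
evaluated element-wise.  A vanishing denominator is a hard error that lists
the offending coordinates: silently produced NaNs would propagate into every
covariance downstream.  Reflectance outside [0, 1] (possible under noise) is
kept and only flagged, because clipping would bias derivative spectra.

Two analysis views share the calibrated cube: *pixel-wise*, where every
foreground pixel spectrum is a data point (used for PCA visualization), and
*object-wise*, where the arithmetic mean spectrum over each berry's pixels
is one sample (used for classification).

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes, not
optics.  Each origin class has a clean endmember spectrum: a smooth, gently
arched baseline (quadratic in wavelength, ≈0.54–0.62 reflectance) minus
Gaussian absorption dips centered at 995, 1200 and 1465 nm — the protein
N–H, C–H stretch and water bands of dried fruit.  Default dip depths are
0.06/0.09/0.14 with widths 22/30/45 nm.  Classes differ only by a small
additive offset (defaults 0, −0.018, +0.014, −0.032) and dip-depth
perturbations (≤0.009), giving the "similar curves, slightly different
level" geometry in which classes overlap in PC score space but remain
clustered.  An `offset_scale` knob multiplies these differences: 0 gives an
exact null (identical classes), large values give well-separated classes
for recovery tests; the default 1 is the study condition.

Scenes place non-overlapping filled ellipses (semi-axes 4–7 px) on a dark
stage of reflectance 0.05 by rejection sampling; placement failure after a
bounded number of attempts is an error rather than an overlap.  Noise has
two parts chosen to reproduce both pixel-level spread and sample-level
variability: i.i.d. Gaussian band noise per pixel (default sd 0.01
reflectance) and a per-object lognormal multiplicative scatter factor
(sd 2 %).  Raw frames are built by inverting the calibration identity with
flat per-line white (92 % of a 12-bit white level) and dark (4 %) frames, so
a noise-free scene calibrates back to the truth cube to machine precision.
One seeded generator drives all randomness: equal seeds give bit-identical
scenes.  A shortcut generator emits object-level sample libraries (the same
endmember + scatter + noise model at mean-spectrum level) without rendering
images, which is what the classification studies use at 300 samples per
class.

What the generator does **not** model: illumination gradients, specular
highlights, berry texture, wavelength-dependent sensor response, or real
biochemical variability.  Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave as expected under the
assumed noise model — not that real berries of these origins are separable
at any particular accuracy.

## Preprocessing

* **Band truncation** keeps the contiguous run from the band nearest the low
  edge through the band nearest the high edge, inclusive; a distance tie
  resolves toward the interior so the run never widens past the request.  On
  the default axis the 972–1609 nm fruit window retains 190 bands.
* **Moving average** (default window 5 bands; unstated in most applied work,
  exposed in config) is a centered boxcar; edge windows shrink to the
  available bands so no padding value is invented.
* **Savitzky–Golay** (default window 9, order 3 — a conventional
  chemometrics choice) uses local least-squares polynomial convolution with
  polynomial-fit extension at the edges; derivatives are divided by the band
  spacing to the derivative order, so second derivatives are per nm².

All transforms are row-wise independent and linear, which the property
tests exercise directly.

## Wavelength selection

Both selection routes share one extremum rule: an interior band strictly
above (below) both immediate neighbours; plateaus are credited to their
leftmost band; the two edge bands are excluded; differences below
1e-9 × max|curve| count as equal so numerically constant curves yield no
spurious extrema.  The PCA route fits a mean-centered (never
variance-scaled) PCA, fixes each loading's sign so its largest-magnitude
entry is positive, and unions the thresholded extrema of the first five
loading curves; the threshold applies to |loading| so peaks and valleys are
symmetric, and an optional top-m cap (default 20, matching the scale of
reported selections) keeps the largest-magnitude extrema because a portable
absolute threshold is not available.  The derivative route applies the same
rule to the grand-mean second-derivative spectrum (default cap 9).  The
defaults reproduce selection-set *sizes* of the reference workflow; exact
published wavelength lists depend on an unpublished threshold and are a
calibration exercise against the original data, not a test target.

## Splitting and models

**Kennard–Stone** runs on the preprocessed full-spectrum vectors with
Euclidean distances, stratified per class (the 200-per-origin outcome of a
2:1 split of 300 implies stratification): seed with the two mutually
farthest points, then repeatedly add the point maximizing the minimum
distance to the chosen set.  Ties break on the smallest row index, making
the split fully deterministic and permutation-stable.

**ELM**: input weights and biases uniform in [−1, 1] from a seeded
generator, logistic-sigmoid hidden layer (the classic choice; tanh
available), output weights `pinv(H) · T` against one-hot targets, argmax
prediction.  The hidden-node search scans h = 1…150 and keeps the smallest
h attaining the minimum training misclassification; the ceiling is
configurable, and selecting the ceiling with nonzero training error raises
a warning because the true optimum may lie beyond it (reported optima in
comparable studies do exceed 150).

**NN-RBF**: exact-design network, one Gaussian unit per calibration sample,
response `exp(−(0.8326·r/s)²)` so that a point at distance r = s responds
0.5 (0.8326 ≈ √ln 2 — "spread" conventions differ between toolboxes, so the
formula is fixed here).  Output weights and bias by linear least squares;
a 1e-8 ridge is applied only if the design is numerically singular, with a
warning.  The spread grid is 0.1–1 in steps of 0.1 plus 1–100 in steps of 1
(a stride-10 coarse option exists for quick runs).

**SVM**: scikit-learn RBF-kernel SVC, one-vs-one, standardized features,
grid over c ∈ [2⁻⁵, 2¹⁰], g ∈ [2⁻¹⁰, 2⁵] in powers of two.

Model selection for the RBF spread and the SVM (c, g) uses stratified
k-fold cross-validation *within the calibration set* (default 5-fold; the
tuning criterion in comparable workflows is often an unnamed "recognition
rate", and cross-validation avoids leaking the prediction set).  Features
are z-scored by calibration statistics for all three models.  Evaluation
reports the confusion matrix, per-class accuracies (percent) and the macro
mean — the unweighted average over classes, which reproduces the "Mean"
arithmetic of per-class accuracy tables exactly.

## Pipeline, determinism, problem sizes

`run_pixelwise` and `run_objectwise` validate a pydantic config, write it
next to their outputs, and serialize every stage product (CSV/JSON, ENVI
cubes for scenes), so a report can be rebuilt from disk and a deleted late
stage re-run to identical results.  Background masking thresholds the mean
reflectance over 1000–1300 nm (default 0.15; berries are several times
brighter than the stage across that window); segmentation is 4-connected
with a 20-pixel minimum object size.

Default study sizes follow the reference conditions: 4 origins × 300
object-wise samples, 2:1 split (200/100 per class).  The test suite and the
acceptance script run the model searches with reduced grids and 3-fold
cross-validation, and the simulation studies at 25–60 samples per class —
sizes chosen so the full suite completes in minutes while every estimate
(accuracy means over 8–20 seeds) remains stable to well under the asserted
margins.  Score-image rendering uses a diverging colormap with per-image
min/max scaling.

A note on the zero-separation null: even with identical class models, a
finite sample of n per class has empirical class means that deviate by
order σ/√n, and calibration and prediction members of a class share that
realization-specific shift.  Flexible learners can exploit it, so measured
null accuracies sit slightly above the 25 % chance level (typically 26–31 %
at n = 60 per class) rather than exactly at it; this is a property of
small-sample simulation, not information leakage.

## Known limitations

* The synthetic classes differ by construction in level and dip depth only;
  real origin differences involve correlated, band-specific chemistry the
  generator does not attempt.
* The exact-design RBF network stores one center per calibration sample and
  scales O(n²) in memory/time; it is meant for hundreds, not millions, of
  samples.
* ENVI I/O covers float BSQ/BIL/BIP with wavelength blocks — the subset the
  pipeline writes — not the full header dialect.
* The CLI exposes composite stages (`simulate`, `pixelwise`, `objectwise`,
  `select`, `report`, `run-all`) rather than one subcommand per micro-stage;
  each stage remains individually callable as a library function, and all
  stage outputs are serialized for resumption.
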