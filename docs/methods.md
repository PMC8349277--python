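# Methods

This note documents the models and procedures implemented in `breastasym`,
the parameters that matter, the synthetic data the test suite runs on, and
the numerical and design choices made where the design was genuinely open.

## Bilateral asymmetry model

The physiological premise is that tumour angiogenesis raises local skin
temperature and perturbs the fine vascular texture of the affected breast,
while the two breasts of a healthy subject show closely mirror-symmetric
thermal patterns. The thermogram pipeline therefore never classifies a
single breast in isolation: it measures the *difference* between matched
left/right texture descriptors, so inter-subject variation in absolute
temperature and global texture cancels and only lateral anomalies remain.

## Segmentation

Input images (8/16-bit rasters or plain-text temperature matrices in °C)
are thresholded with Otsu's criterion — the histogram cut maximizing
between-class variance, computed over `histogram_bins` (default 256) bins
spanning the image min–max range, ties broken toward the lower cut. The
warmer class is kept, cleaned by morphological opening then closing with a
disk of `morph_radius` px (default 3), and reduced to the largest
8-connected component; a component below `min_component_fraction` (default
1%) of the image aborts with a segmentation failure rather than silently
producing a bogus ROI.

The mask is split at the midline of its column span (a mask-centroid split
is available). Per side, the inframammary fold is located as the row of
maximal row-summed absolute horizontal-Sobel response within the lower half
of the body, restricted to the side's column span; the breast ROI is the
side mask above that row, tightly cropped. The right ROI is mirrored
horizontally by default so oriented texture channels correspond between
sides. Because thresholding, morphology and edge projection all commute
with adding a constant to the image, segmentation is intensity-shift
invariant, which the suite checks.

Manual pre-cropping, which a clinical workflow would do by hand, is
replaced by an optional crop rectangle in the configuration for
reproducibility.

## Gabor filter bank and asymmetry signature

Each filter is the real Gabor function

    g(x, y) = 1/(2π σx σy) · exp(−½ (x′²/σx² + y′²/σy²)) · cos(2π f x′),
    x′ = x cos θ + y sin θ,  y′ = −x sin θ + y cos θ,

whose transfer function is a pair of Gaussians at (u, v) = (±f cos θ,
±f sin θ). Envelope spreads follow the −6 dB bandwidth design

    σx = √(ln 2) (2^B + 1) / (√2 π f (2^B − 1)),
    σy = √(ln 2) / (√2 π f tan(Bθ/2)),

with frequency bandwidth B = 1 octave and orientation bandwidth Bθ = 45°;
the default circular envelope sets σy = σx (at f = 0.25 c/px, σx ≈ 2.249 px).
The default bank covers the four half-octave-spaced radial frequencies
{0.25, 0.176, 0.125, 0.088} cycles/pixel — generation by strict octave
halving from f_max is available behind a config flag — and five orientations
{0°, 36°, 72°, 108°, 144°} (O_j = (j−1)·180°/V), i.e. 20 filters. Kernels
are sampled on the integer grid out to `kernel_truncation`·max(σx, σy)
(default 3σ) and made exactly zero-mean by subtracting their own mean, so
constant regions produce zero response.

Before convolution (spatial, reflect padding) the mean over the breast mask
is subtracted from the ROI. Each filter yields one texture energy: the mean
of |response| over masked pixels (`mean-abs`, the default; `sum-abs` skips
the division). Normalizing by mask size keeps energies comparable between
breasts of different area, so area differences cannot masquerade as texture
asymmetry. The classifier input is the signature |E_k(left) − E_k(right)|,
k = 1..20 (a signed variant is available); the absolute form makes the
signature invariant to which side bears the lesion. Only the subtracted
vector is fed to the classifier by default; per-side vectors can be
exported.

## GLCM / Haralick branch

Mammogram ROIs (assumed pre-segmented; lesion contouring is out of scope)
are band-pass denoised by a difference of Gaussians (σ = 1, 2 px), rescaled
to the input range so downstream quantization is stable. Intensities are
linearly quantized to G = 64 levels over the masked min–max range, and the
co-occurrence matrix at displacement d = 1 and θ ∈ {0°, 45°, 90°, 135°} is
accumulated over pairs with both pixels in the mask, symmetrized and
normalized. The 13 classic Haralick statistics are computed with natural
logarithms and 0·log 0 := 0; a zero marginal SD makes the correlation 0
rather than undefined. Orientations are averaged by default (13 features)
or concatenated (52). G, d and θ are conventional defaults, configurable
because the source experiments do not state theirs.

## Classifiers and ensemble fusion

The base classifier is an RBF-SVM at the published operating point C = 2,
γ = 2. It is applied to the raw asymmetry energies deliberately **without**
z-scoring: the energies' natural magnitude (~10⁻³–10⁻¹) keeps
γ‖x − x′‖² in a useful range, whereas standardizing d ≈ 20 features to unit
variance puts typical squared distances near 2d ≈ 40 and collapses
exp(−2‖x − x′‖²) to 0 — the kernel matrix degenerates to the identity, the
SVM memorizes, and test accuracy drops to chance (measured: 0.54
cross-validated standardized vs 1.00 raw on the separable benchmark).
Standardization remains available and is the right choice together with the
variance-scaled kernel width γ = 1/(d·Var), which the mammogram branch uses
because Haralick features span mixed scales (ASM ~10⁻³, sum variance ~10³).

Soft class supports for fusion come from the signed SVM margin through a
unit-slope logistic link, renormalized to sum to 1; the support argmax
always equals the hard decision, and a sample on the boundary gets
(0.5, 0.5).

The ensemble trains L = 3 base SVMs on bootstrap resamples (redrawn until
every class is present) and fuses the L×c decision profile by one of nine
rules. Fixed rules aggregate columns directly (majority vote counts per-row
argmaxes; max/sum/min/average/product aggregate supports; sum and average
always agree on the label). Trainable rules first learn per-class decision
templates T_ω (mean training profile), class priors, and per-classifier
confusion matrices with add-one smoothing:

* decision templates: score_ω = 1 − ‖DP − T_ω‖²_F/(L·c);
* naive Bayes: score_ω ∝ prior_ω · Π_l P(vote_l | ω) from the smoothed
  confusion matrices (smoothing avoids zero products);
* Dempster–Shafer (proximity formulation): Φ_{ω,l} = (1 + ‖T_ω(l,·) −
  DP(l,·)‖²)⁻¹ normalized over ω, per-classifier beliefs
  b_l(ω) = Φ_{ω,l}K / (1 − Φ_{ω,l}(1 − K)) with K = Π_{ν≠ω}(1 − Φ_{ν,l}),
  multiplied over l and normalized.

All rules break ties toward the lowest class index and reduce to the single
classifier's decision at L = 1.

## Experiment protocol and metrics

"Iterations" are repeated stratified random train/test splits (defaults:
6 iterations, 30% test), each drawing its seed from one seed sequence, so a
protocol seed fixes the entire experiment. Per iteration the confusion
matrix (positive class = abnormal or malignant per task) yields
sensitivity, specificity, precision, MCC and F-score as proportions and
accuracy/error rate in percent; any 0/0 is reported as 0 with a degenerate
flag instead of aborting the batch. Aggregation reports mean, *sample*
standard deviation (n − 1 divisor — the convention that reproduces the
published ±3.4370 from its own six accuracies), min and max. The published
tables print an MCC column identical to specificity in every row, which no
confusion matrix consistent with the other columns can produce; the
standard MCC formula is implemented and the discrepancy is not imitated.

## Synthetic data

A thermogram scene (default 128×128 px) is a cool background (baseline
− 8 °C, so Otsu separates the body cleanly) and, inside an elliptical body
centered on the vertical midline, a 33 °C baseline plus a mirror-symmetric
smooth field (Gaussian-filtered noise, amplitude 0.5 °C, scale 16 px), a
mirror-symmetric oriented sinusoidal texture (0.3 °C, 0.06 c/px), an
optional one-sided isotropic Gaussian hot spot of amplitude ΔT and spread
σ, for the malignant regime an added high-frequency oriented micro-texture
(0.25 c/px, amplitude 0.4·ΔT, windowed to the lesion neighbourhood), and
i.i.d. Gaussian pixel noise (default regime 0.2 °C). Mirror symmetry is
exact by construction — the left half is reflected onto the right before
one-sided components are added — so a noiseless lesion-free scene gives a
bitwise-null asymmetry signature, which the suite asserts. Class regimes:
benign ΔT ∈ [0.5, 1.2] °C with a smooth bump only; malignant
ΔT ∈ [1.5, 3.0] °C plus micro-texture. No quantitative lesion ΔT is
established in the literature premise used here; these values follow the
qualitative angiogenesis claim.

A purely smooth Gaussian hot spot is essentially low-pass: at any plausible
σ its spectral content inside the 0.088–0.25 c/px filter band is negligible
(measured signature norm 0.003–0.009 against a 0.0035 noise-asymmetry floor
at 0.2 °C noise), so smooth-bump-only lesions are *not* separable by Gabor
features — a physical property, not an implementation artifact. The lesion
model is therefore amplitude *plus* angiogenic micro-texture, chosen so
both the Gabor and GLCM feature families carry class signal, and the
standard separable benchmark (`default_separable_dataset`: 40 normal vs 40
lesioned scenes at ΔT = 2 °C, σ = 8 px, noise 0.2 °C) uses the full lesion
model (measured signature norm 0.065 ≫ floor; measured mean accuracy 100%
per experiment repetition at this size).

Texture patches for the mammogram branch are quantized checkerboards,
gratings, or Gaussian-smoothed noise fields with controllable correlation
length and contrast; the three class regimes differ in correlation length
(6 / 3 / 1.2 px) and contrast gain (1.0 / 1.3 / 2.0) so GLCM statistics
separate them. Patches of at least 64×64 px are needed for stable GLCM
estimates at G = 64.

What the generator does **not** emulate: Pennes bioheat physics, anatomical
breast shape variability, camera fixed-pattern noise and vignetting,
pose/registration error between sides, and real mammographic parenchyma.
Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline and its discriminative behaviour under the
stated scene model — not clinical performance.

## Numerical choices and degenerate inputs

* Otsu ties go to the lower threshold; constant images raise a
  degenerate-input error.
* Convolution uses reflect (edge-repeating) padding; Gabor statistics are
  masked, so background never contributes.
* GLCM with no valid pixel pair, an empty mask, or a constant masked region
  is rejected or (for quantization) collapses to level 0 deliberately.
* All randomness flows from explicit `numpy` generators seeded per call;
  nothing touches global RNG state. Identical config + seed reproduce every
  artifact byte for byte (asserted by the suite).
* Problem sizes in the suite and the acceptance script — 128×128 scenes,
  80-scene thermo benchmark, 40 64×64 patches, 6–7 split iterations — are
  chosen as the smallest sizes at which the scene model's class separation
  is stable.

## Known limitations

* The split column assumes a roughly upright, centered subject; severe
  rotation would need the crop/registration step a clinical deployment
  would add.
* Benign-regime (smooth bump) lesions are near the Gabor noise floor by
  design; detecting them would require temperature-domain features rather
  than band-pass texture.
* The Bayes combiner conditions on hard votes only; it discards the margin
  information the other trainable rules use.
* Multi-class support stops at the three labels the screening tasks need.
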