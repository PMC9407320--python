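# Methods

## Scene and signal model

A hyperspectral line-scan acquisition of a single fruit is modelled as a
cube `T(r, c, λ)` of raw intensities on a fixed wavelength grid. The
package's canonical grid has 176 bands spanning 397.5–1014 nm (≈3.52 nm
spacing); the quoted acquisition interval of ~3.4 nm is inconsistent with
those endpoints, and the endpoints were kept. Relative reflectance is
obtained per pixel and band from white and dark reference frames,

    R(r, c, λ) = (T(r, c, λ) − T_d(λ)) / (T_w(λ) − T_d(λ)),

with the white−dark difference required strictly positive at every band.
Detector SNR collapses outside 425–1000 nm, so analysis crops to that
window; the sub-regions are Vis 425–780 nm, NIR 781–1000 nm (63 bands on
the canonical grid), and their union.

## Phantom generator

The phantom emulates the features of real fruit scenes that drive each
pipeline stage, with everything seeded:

- **Geometry** — an elliptical fruit (default semi-axes 46 × 38 px in a
  120 × 120 frame) over a dark background (reflectance 0.02); bruises are
  hard discs (default radius 12 px) strictly inside the ellipse.
- **Spectra** — sound tissue follows a smooth curve in (0, 1), the sum of a
  broad NIR Gaussian (center 880 nm, width 320 nm) and a smaller
  green-yellow shoulder (550/80 nm), deliberately gentle across the NIR so
  that bruise-induced structure is localized at its own center wavelength.
- **Bruise** — multiplicative reflectance depression `1 − δ·g(λ)` with a
  Gaussian band g centered at 900 nm (width 120 nm), plus a weaker visible
  browning term (0.3·δ at 560/60 nm). Grade severity is the depth δ:
  0, 0.05, 0.10, 0.16, 0.24 for SOUND and grades I–IV. In cohorts, δ is
  jittered per fruit (SD 0.008, clipped to ±50 %), which is what creates
  adjacent-grade confusion in the classifier.
- **Illumination** — two distinct multiplicative fields. The *lamp field*
  (planar gradient × vignette, slope jittered 0.10–0.25) also multiplies the
  emitted white frame (`white = lamp·1 + dark`), so Eq.-style calibration
  removes it exactly. The *curvature shading* of the fruit surface
  (elliptical dome, rim depth 0.18–0.30) is absent from the flat white
  panel and therefore **survives calibration**, exactly as on real curved
  fruit. This term is load-bearing: it makes overall brightness the first
  principal component of fruit-pixel spectra, leaving bruise contrast to
  PC2, and gives ratio images a genuine illumination term to cancel.
- **Noise** — additive Gaussian per pixel-band, σ = 0.005 inside
  425–1000 nm and 5× that outside, reproducing the low-SNR band edges that
  motivate spectral cropping.

Ground truth (fruit mask, bruise mask, grade, and the shaded noise-free
reflectance cube) accompanies every phantom. What the phantom does **not**
model: radiative transfer, peel texture beyond noise, diffuse bruise edges,
bruise evolution over time, specular highlights. Tests passing on phantoms
therefore demonstrate algorithmic correctness and end-to-end coherence of
the pipeline, not field performance on real fruit.

## PCA and band selection

PCA is fitted on mean-centered fruit-pixel spectra, per sample for score
images (each fruit gets its own PC basis, as per-sample PC imagery implies)
and pooled across a cohort — by streaming covariance accumulation — for the
weight curve that drives band selection. Loadings are sign-fixed so the
largest-magnitude element is positive. Characteristic bands are the region's
interval endpoints plus interior extrema of the (box-smoothed, window 5)
PC2 loading curve with prominence ≥ 10 % of the curve range; the grading
pipeline keeps the single most prominent interior extremum, giving exactly
three wavelengths. On default phantoms this selects ≈781.5, ≈900, and
≈999.9 nm — the analogue of a reduced three-band multispectral system.

## Morphological segmentation and triage

The PC2 score image is binarized by Otsu's threshold within the fruit.
The flow never states where the grayscale image becomes binary; binarization
before morphology was adopted because small-object removal and binary
opening/closing operate on binary images. Polarity is resolved
automatically: the Otsu side occupying the smaller fruit-area fraction is
the bruise (bruises are local anomalies; PC sign is conventional).
Components below 50 px are removed, then opening and closing with a disc of
radius 3 (idempotent by construction); the boundary is the morphological
gradient (disc radius 1) of the cleaned mask. The verdict rule couples the
decision to the noise-removal scale: BRUISED iff the cleaned mask keeps at
least 50 px. A plain-Otsu baseline (no cleanup) shares the result container.
Under this additive-noise model the baseline's failure mode at low contrast
is scattered false positives rather than pure under-segmentation, so the
MSM's advantage is asserted as IoU and precision against truth.

## Ratio images and texture

K_a/b divides the calibrated bands nearest a and b ("original image" is
read as the calibrated band image; any per-pixel factor common to both
bands cancels identically either way, while raw frames would retain the
dark offset). Denominator pixels below 1e-6 × the masked median magnitude
are excluded and counted, never silently dropped. The grading ratio pair is
the first/last characteristic band (≈782/999 nm).

GLCMs are computed over the bruise mask (the retained segmentation result),
restricted to its bounding box: 16 gray levels by min–max binning over
masked pixels (constant regions map to level 1), distance 1, symmetric
pairs with **both** endpoints in the mask, four offsets
(0,1), (−1,1), (−1,0), (−1,−1). Five statistics per direction — energy
Σp², entropy −Σp·log₂p, contrast Σ(i−j)²p, correlation
Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) (0 for degenerate marginals), inverse difference
moment Σp/(1+(i−j)²) — are kept per direction, not averaged. The feature
vector is fixed-order length 24: r_a, r_mid, r_b, mean ratio gray, then
5 × 4 texture values.

## Classifier

The LS-SVM dual problem is a single linear system per class pair,

    [ 0   1ᵀ      ] [ b ]   [ 0 ]
    [ 1   K + I/γ ] [ α ] = [ y ],     f(x) = Σᵢ αᵢ K(xᵢ, x) + b,

whose first row enforces Σαᵢ = 0; the solution is validated by residual
(< 1e-8) and an ill-conditioned system raises with a suggestion to lower γ.
Kernels: RBF K(x, z) = exp(−‖x−z‖²/2σ²) and linear. Multiclass is
one-vs-one with majority vote, ties to the lowest grade in severity order.
Features are standardized with training-set statistics stored in the model
(serialized as versioned JSON).

Splitting uses Kennard–Stone (max–min Euclidean selection, all ties to the
lowest index) applied per class on standardized features with
round(0.75·n_class) training samples each, so every grade appears in both
sets. Hyperparameters are chosen by seeded stratified 5-fold CV on the
training set over γ ∈ 10^{−1..4} and σ ∈ 10^{−1..2} (7 log-spaced values),
ties to the earliest grid entry; fold count is clamped to the smallest
class size.

## Numerical and design choices

- Nearest-band lookup rejects targets more than one grid spacing outside
  the span; equidistant ties go to the lower index.
- Fruit masking without RGB imagery: Otsu on the band nearest 782 nm
  (high-SNR, bruise-insensitive relative to 900 nm), hole filling, largest
  connected component.
- Constant score images yield an empty bruise mask (NORMAL) rather than an
  arbitrary Otsu side.
- ENVI I/O writes BSQ with the array's floating dtype so write→read is
  bit-exact; BSQ/BIL/BIP are accepted on read.
- Default problem sizes — 120 × 120 × 176 phantoms, a 187-fruit grading
  cohort (50/50/47/40 for grades I–IV) and a 40-fruit triage batch — mirror
  the study layout while keeping a full pipeline run at a few minutes on
  one CPU.

## Limitations

Phantom effect sizes (δ ladder, jitter spreads, shading depth) are design
choices, not calibrated to measured fruit; absolute accuracies on phantoms
say nothing quantitative about real cohorts. GLCM level count, distance and
direction handling are conventional defaults; the exact rule behind any
particular triple of published characteristic wavelengths is not claimed to
be reproduced. The LS-SVM solver is dense (O(n³) per pair) and intended for
cohort-scale n, not thousands of samples.
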