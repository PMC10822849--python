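# Methods

This note records the models, conventions and design choices behind
`qusresponse`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## RF simulation model

Frames are synthesized per scan line in the frequency domain. Each
scatterer at depth *d* contributes the transmit pulse spectrum (Gaussian,
centred at 6 MHz, −6 dB power band 3–8 MHz), phase-delayed by the
round-trip time 2*d*/*c* and filtered by

* a Rayleigh `f²` amplitude factor, so backscattered power grows as `f⁴`;
* `sqrt(FF)` with the spherical Gaussian form factor
  `FF(f) = exp(−0.827 k² a²)`, `k = 2πf/c`, `a` the effective scatterer
  radius;
* round-trip attenuation (below);
* a Gaussian lateral beam profile (σ = 0.05 mm, truncated at 3σ) that
  spreads the echo over neighbouring lines and gives frames a realistic
  lateral speckle correlation length.

Scatterer amplitudes scale as `(a/25 µm)³`, so the backscatter prefactor
carries the physical `a⁶` dependence and acoustic-concentration estimates
track number density. A 64-sample guard band absorbs FFT wraparound of
echoes near the window edges. White Gaussian noise is added at a
configurable SNR (default 30 dB; the acquisition electronics are otherwise
not modelled). The model is 2-D and linear: no elevational beam, no
diffraction-, focusing- or nonlinear-propagation effects, no multiple
scattering.

**Attenuation convention.** Throughout the package, an attenuation
coefficient α in dB/(MHz·cm) produces a round-trip *power* loss of
`4 α f d` dB at depth *d* cm, and the reference-phantom normalization
compensates exactly that (`+4 (α_s − α_r) f d` dB). This is the neper-form
round-trip correction of the reference-phantom literature carried over to
the dB scale; forward model and compensation are defined together so the
chain is exactly self-consistent, which the flat-spectrum tests verify.

**Backscatter units.** Simulated backscatter coefficients are relative
(the absolute 1/(sr·cm) calibration requires a physical phantom). ASD
depends only on the BSC's shape and is unaffected; AAC is reported on a
relative dB scale, `10·log10(C) − 60·log10(ASD_µm)`, which rises 3 dB per
doubling of scatterer concentration.

## Spectral estimation

Per analysis block, each scan-line segment is Hann-tapered and transformed
with an FFT zero-padded to the next power of two ≥ 4× the gate length;
magnitude-squared line spectra are averaged arithmetically and converted to
dB (floor −200 dB; floored blocks are flagged invalid rather than fitted).
MBF/SS/SI come from ordinary least squares on the 3–8 MHz band, so
`MBF = SI + SS·6` holds to machine precision by construction. The
form-factor fit is linearized: `ln(BSC/f⁴)` regressed on `k²`; a
non-negative slope means no Gaussian decay is present and the fit *raises*
rather than returning a boundary value. Regression slope noise therefore
censors small-radius media: under fully developed speckle with ~20
independent lateral looks per 2.2 mm block, radii below ≈20 µm flip the
slope sign in an appreciable fraction of blocks. Block failures are
recorded in the validity mask; a frame aborts only when the failure
fraction exceeds a configurable threshold (0.5 by default, 0.75 in
cohort-scale runs, where 20 µm media legitimately fail in ~45% of blocks).

Reference spectra are taken from a simulated homogeneous phantom frame
(0.576 dB/MHz·cm, 1488 m/s) scanned over the same *time* window as the
tissue, averaging all scan lines at the block's axial gate; the small
physical-depth offset introduced by the sound-speed ratio is folded into
the reference spectrum before compensation. A `reference_gating="matched"`
option restricts the reference to the sample block's own lateral gate, in
which case self-normalization is exactly zero block by block.

## Parametric maps and rendering

The sliding window defaults to an explicit 2.2 mm square with 94% overlap
(step 0.132 mm). Ten ultrasonic wavelengths at 6 MHz and 1540 m/s is
≈2.57 mm — the two common prescriptions disagree, and the explicit
millimetre figure wins by default while the 10-λ rule remains available
(`block_side_mm=None`). Cohort-scale studies use 60% overlap: overlap
controls map sampling density, not the per-block estimator, and 94%
produces ~2×10⁴ blocks per frame. Axial = rows, lateral = columns; block
centres are physical millimetres from the transducer face.

Rendering crops the block grid to the ROI bounding box, min–max scales
valid values to [0,1] per image, fills failed in-ROI blocks with the
median of the valid values, zeroes out-of-ROI cells and resizes bilinearly
to 224×224. Two choices deserve emphasis. Scaling precedes resizing so
that out-of-ROI pixels can stay exactly 0 even for negative-valued
parameters such as SS. Failed blocks are inpainted rather than rendered as
holes because fit failures correlate with scatterer radius: zero-holes
would imprint the failure pattern itself on the image and act as a
spurious, artefactual class cue. Per-image min–max scaling means only
*spatial* contrast (core vs margin) survives into the image — a deliberate
choice that removes the colormap as a hidden hyperparameter, at the cost
of absolute parameter levels.

## Frozen backbone

The feature extractor is injected behind a one-method interface
(`forward: (224,224,3) → (7,7,2048)`). The default is a two-stage strided
convolutional network (8×8/stride-8 → 64 channels, 4×4/stride-4 → 2048
channels, ReLU) with He-initialised weights drawn once from a fixed seed
and never updated — a frozen random-projection CNN. Untrained random
convolutional features are a recognised, competitive representation, and a
fixed-seed network makes the whole pipeline bit-reproducible with no
weight artefacts to ship. Inputs are scaled to [−1, 1] inside the
extractor; activations are flattened row-major over (row, column, channel)
to 100,352 values, and per-slice vectors are averaged arithmetically per
patient (averaging raw extracted vectors, before any further processing).

## Selection, balancing, evaluation

The prevalence filter keeps features that are exactly nonzero in ≥90% of
training patients (rectified activations make true zeros common; no
epsilon). ANOVA F-scores are computed on training rows only; constant
features score 0; ties break toward the lower index; k = round(√n) (13 for
174). SMOTE synthesizes minority rows as `x + u·(x_nn − x)`, `u ~ U(0,1)`,
among k = 5 nearest minority neighbours (reduced to minority−1 when
needed), training rows only, originals preserved verbatim. The split is a
stratified 20% holdout by largest-remainder allocation (174 → 35 test, 7
NR / 28 RR); "randomly selected" is interpreted as stratified because a
plain random draw can produce test sets without a usable nonresponder
contingent. The SVM is linear with C = 1 on unstandardized features;
prediction is the sign of the decision function. Filter and k-best are fit
once on the full non-test set (the fold-wise variant is available via
`select_within_fold=True`); cross-validation is an evaluation protocol
here, not a hyperparameter search. Percentages round half-up; balanced
accuracy is the mean of per-class recalls computed before rounding;
zero-denominator metrics are reported as undefined, never as 0.

## Synthetic cohorts: what they show

A cohort draws, per patient, a core scatterer radius and number density
from class-specific normals, an elliptical tumour (≈3.5 × 4 mm semi-axes,
jittered centre) in an 18 mm × 12 mm frame, and 4–7 planes with fresh
speckle per plane. The margin ring (5 mm, built by Euclidean distance
transform) and surrounding tissue are class-independent (20 µm, 8 mm⁻²,
α = 1.0 dB/MHz·cm). The separated condition uses NR cores of 36 µm /
4 mm⁻² vs RR cores of 20 µm / 14 mm⁻²: effect sizes are *stipulated*, not
reproduced from patients — no quantitative description of how responder
classes differ in scatterer statistics is available — and were calibrated
on the simulator so the five maps separate visibly and the end-to-end
protocol reaches ≥90% test balanced accuracy robustly across seeds. The
null condition gives both classes one shared core distribution.

Because the clinical data are confidential, the published 86% balanced
accuracy is *not* a reproducible target; the calibration studies replace
it with two property checks: chance-level (50 ± a few %) mean accuracy on
zero-effect cohorts — evidence that selection and SMOTE do not leak — and
≥90% on strongly separated cohorts — evidence that real class structure
survives the whole chain. The null study runs the selection→SMOTE→SVM
protocol on zero-effect feature tables with backbone-like marginals
(ReLU-censored Gaussians with per-feature means), since the RF→feature
stages are label-blind by construction and 50 full RF cohorts would add
hours of compute without information; the separated arm does run the
complete RF→maps→features→SVM chain on all 174 patients.

## Problem sizes and numerics

Cohort frames are 120 lines × 0.1 mm pitch × 8–26 mm depth (~935 samples);
the separated run uses 4 planes per patient and the SS parameter; the
monotonicity study uses 20 single-class patients (radii 22–38 µm, densities
3–24 mm⁻², three planes each, core-only scoring); ASD noise recovery uses
200 replicates of 5% multiplicative lognormal noise. These sizes keep the
full test suite and the acceptance script at desk scale while leaving every
estimator operating in its working regime. Degenerate inputs (all-zero
blocks, single-class training data, minority class of one, constant
features, empty ROIs) raise typed errors rather than returning numbers.

## Known limitations

* The simulator's speckle statistics are 2-D; absolute BSC levels,
  diffraction and elevational effects are out of scope, so AAC/ASD accuracy
  claims apply to the model, not to any scanner.
* Per-block ASD is noisy near the small-radius end of the band (the
  `ka ≪ 1` regime); medians over many blocks are the intended consumer.
* The frozen random backbone preserves class structure but is not a
  pretrained natural-image network; feature indices have no semantic
  meaning, and selection stability depends on cohort size.
* Patient-specific attenuation is not estimated from the data; a fixed
  tissue value (default 1.0 dB/MHz·cm, configurable) is compensated.
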