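# Methods

This note records the models implemented in `histoct`, the parameters that
matter, the numerical choices made where the design was open, and what the
phantom-based tests do and do not demonstrate.

## Conventions

Pixels are indexed 0-based `(row, col)` with pixel centres at integer
coordinates; this single convention is used by every module, which removes
half-pixel ambiguities between the rigid, elastic and block-matching
stages. Volumes are indexed `(z, y, x)`; physical points are `(x, y, z)` in
micrometres. Intensities are held as floats within `[0, 2^bit_depth − 1]`
and rounded to the native integer type only on write.

## Virtual slicing

`extract_plane` samples the CT volume on a 2D lattice by trilinear
interpolation. The in-plane axes are fixed by convention — `u = n × ẑ`
(normalised; `x̂` when the normal is parallel to `ẑ`), `v = n × u`, then
both rotated by the in-plane angle — so a plane specification in a text
file reproduces the same image everywhere. The slice is a single-sample
plane; averaging over a slab thickness to emulate the ~2 µm physical
section would be a straightforward extension but is not implemented, since
a single sample is the simplest faithful reading of a virtual cut.

## Preprocessing

The moving histology image is reduced to one channel (user-selected channel
or channel average, average rounded half-up) and inverted so that tissue
content is bright in both modalities, which puts the two images' intensity
ramps in the same direction before any spectral or histogram operation.
Both images are downscaled 1/10 by area averaging (block means, output size
floored). Averaging rather than decimation is deliberate: decimation
aliases high-frequency histological texture into the working scale and
destabilises the MI metric.

## Rigid pre-alignment (Fourier–Mellin)

The B-spline model cannot represent a large global rotation except by
grossly distorting the grid, so rotation and translation are corrected
first, spectrally:

1. Each image is mean-subtracted, Hann-windowed, and its FFT magnitude
   taken (translation-invariant). The magnitude is weighted by the classic
   high-pass emphasis `H = (1 − X)(2 − X)`, `X = cos(πξ)cos(πη)`.
2. The magnitudes are resampled to polar coordinates (0.25° angular bins).
   Only radii up to a quarter of the frame enter, with DC-adjacent bins
   dropped: elastic distortion between the modalities decorrelates high
   frequencies first, and including them makes the angular peak fragile.
3. The angular shift between the polar images is found by correlation with
   *softened* spectral whitening (`|F| + mean|F|` in the denominator
   instead of `|F|`). Pure phase correlation is optimal for identical
   content but weights decorrelated frequencies equally; softening trades a
   broader peak for robustness to the residual elastic mismatch. The five
   strongest mutually non-adjacent angular peaks are kept as rotation
   candidates — near-symmetric tissue outlines can demote the true
   rotation to a secondary peak.
4. The magnitude spectrum is symmetric, so each candidate θ is ambiguous
   with θ + 180°. Every candidate (both branches) is completed with a
   translation estimate (phase correlation after de-rotation, subpixel via
   a separable quadratic fit around the argmax) and scored by the mutual
   information between the fixed image and the fully transformed moving
   image. MI, not Pearson correlation, is the tie-breaker because the two
   modalities are related non-linearly.
5. A second estimation pass on the corrected image absorbs the residual,
   with the refinement accepted only if it does not lower the MI score.
   Estimated components below 0.01 px/deg are snapped to zero so that an
   identity pair maps exactly.

Scale is deliberately not estimated: sections and virtual slices share
pixel calibration, and the log-radial axis is left fixed. The rotation
centre is the image centre; any other centre differs only by a translation,
which the translation stage absorbs.

On noise-free phantoms the estimator recovers rotations in (−60°, 60°] and
translations up to 20 % of the frame to well under 1°/1 px (acceptance
script: ~0.2°/0.24 px worst case over 20 trials; ~0.5°/0.3 px with
additive noise σ = 5 grey levels).

## Elastic registration

The deformation is a cubic B-spline free-form deformation: displacements on
a uniform control-point lattice (origin −s, `floor((dim−1)/s)+4` points per
axis so the cubic support covers the domain), interpolated by the tensor
product of centred cubic B-spline kernels. Warping is backward
(`out(x) = moving(x + D(x))`) with bilinear intensity sampling and a fill
value outside the domain.

Two MI estimators are used on purpose:

* the **exact** 32-bin joint-histogram MI (bits; linear edges over each
  image's min..max) for all evaluation, scoring and reporting, and
* a **Parzen-windowed** MI inside the optimiser: the fixed intensity is
  hard-binned, the moving intensity distributed over four neighbouring bins
  with a cubic B-spline window, making the joint density — and the metric —
  differentiable in the moving intensities. Its bin edges clamp to the
  1st–99th intensity percentiles so hot CT pixels cannot stretch the
  histogram.

The analytic gradient chains ∂MI/∂(moving intensity) through the moving
image's spatial gradient (sampled at the warped positions) into the basis
matrices of the lattice, giving the gradient with respect to every control
point in two small matrix products. The optimiser is an adaptive-gain
ascent: steps normalised to the gradient's max component, gain
`step₀/(1 + t/τ)` with `(step₀, τ) = (2 px, 20)`, 60 iterations per level.
It is deterministic — full-image sampling, no stochastic subsampling — so
identical inputs give bit-identical fields; the `seed` parameter exists for
interface completeness.

Registration runs coarse-to-fine over 3 levels (additional 4×/2×/1× on top
of the global 1/10 downscale), control spacing halving per level down to
16 px at the working scale (8 px in the cohort experiment, whose working
images are only 40 px wide). Between levels the field is re-fitted to the
finer lattice by separable least squares, which is exact when the coarser
field already lies in the refined spline space. Every iterate is scored
with the exact MI and the best-scoring field — the zero field included — is
returned, so the result can never have lower MI than the unregistered pair.
Pixels at the fill value in both images (paraffin background) are excluded
from the exact metric. No bending-energy penalty is applied by default; a
weight hook exists (`bending_weight`) for data where the deformation must
be kept stiffer.

On phantoms warped by known smooth fields (max 8 px, generated on a 48 px
lattice — deliberately coarser than the 16 px registration grid, so
recovery is never a same-basis identity) the mean endpoint error is
~0.5 px, against a 1.5 px design target.

The full-resolution deformation is obtained by scaling spacing, origin and
displacement vectors by the downscale factor and is applied to each colour
channel independently before re-merging.

## Displacement Index

Block matching tiles the fixed image (anchor at the origin, stride
`block · (1 − overlap)`, partial edge blocks dropped) and, for each block,
exhaustively searches integer offsets within a radius (default
`block/4`) for the offset maximising the MI between the fixed block and
the shifted moving block; ties prefer the smallest displacement magnitude.
Block MI is computed on globally binned intensities (equal-width bins over
each full image's range) so that the MI weights of different blocks are
comparable. Blocks whose fixed tile is >90 % background are excluded; the
background band is derived from the image border (median ± 3 SD) and only
engages when the border is substantially flatter than the interior, i.e.
when a background frame actually exists. MI values are floored at 1e−6
before inversion, since the DI weight 1/MI is undefined at zero.

DI is the inverse-MI-weighted mean displacement length. It is zero for a
self-match, invariant to block order and to rescaling all MI values, and
linear in a uniform scaling of the displacements. Because a CT slice and a
stained section never show identical content, the DI of a perfectly
registered real pair is positive: low-information blocks (uniform tissue,
background remnants) carry the *largest* weights, which is the metric's
intent — a registration is only as trustworthy as its least-informative
region. Displacements are integer-valued; no subpixel refinement is
applied in the DI.

Before/after comparisons use the classical pooled-variance unpaired
two-tailed t-test, reported as mean ± SD (n). Two zero-variance groups
with equal means return p = 1 by convention.

In the cohort experiment (15 phantom pairs, 400×400 px, rotation 10°,
translation (15, −10) px, elastic up to 12 px, noise σ = 2) the DI is
measured with 100 px blocks at 50 % overlap and a 25 px search radius —
the same block-to-image ratio as 500 px blocks on a ~2000 px frame. DI
falls from ≈20 to ≈1.6 on every pair (t-test p ≈ 1e−24).

## Tissue classification

Registered pairs yield a 4-feature image (CT grey, histology R, G, B).
Features are z-scored over the valid-pixel mask before EM — full-covariance
EM is scale-invariant in exact arithmetic, but mixing 16-bit CT and 8-bit
colour scales is numerically fragile; a zero-variance feature keeps scale 1
so standardisation stays invertible. The mixture (default K = 6, full
covariances, 1e−6 diagonal regularisation floor) is fitted by EM with
k-means++ seeding; three seeded initialisations are run and the best final
log-likelihood kept, since a single unlucky seeding can merge two clusters.
EM is driven one iteration at a time so the total log-likelihood trace is
recorded and its monotonicity asserted on every fit; a collapsing component
(weight < 1e−6) is re-seeded once per run. Everything is deterministic
given the seed.

Posteriors follow from Bayes' rule per pixel and sum to one on the mask;
mix coefficients are reported as percentages, sorted descending. The
mapping from components to tissue names is supplied by the observer, not
inferred: component identity is biological knowledge the model does not
have.

On a synthetic 6-component, well-separated 4D mixture (n = 10⁵) the fitted
mix coefficients land within ±0.002 of truth and means within 0.04 SD
after Hungarian matching. On a phantom whose particle class is visible
only in the CT channel, 4D classification reaches ~90 % pixel accuracy
versus ~75 % for histology-only 3D features — the quantitative version of
the claim that the combined data enables classifications the section alone
cannot support.

## Phantoms

The generator emulates the content of a stained tumour section and its CT
counterpart: a blobby tissue silhouette, curved fibre strands, fat-like
voids, vessel lumina, and particle clusters that are bright in CT but
rendered indistinguishably from the surrounding tissue in histology.
Crucially, both modalities share one smooth multiplicative density texture
(plus weaker modality-specific texture and independent pixel noise):
real tissue's fine structure is visible to both imaging physics, and that
shared structure is precisely what makes mutual information informative.
Histology palettes mimic Masson trichrome (red cytoplasm, blue collagen,
pale voids) or DAB-brown IHC.

The ground-truth deformation is a rigid transform plus a random B-spline
field on a 48–120 px lattice (always coarser than the registration grid),
rescaled to a stated maximum displacement. The moving histology image is
produced by warping with the *inverse* field (computed by fixed-point
iteration), so the stored truth field is exactly what an ideal registration
should output, enabling direct endpoint-error scoring. Same seed, same
bytes; cohorts derive per-pair seeds from a base seed.

Default study conditions used by the tests: rigid sweep over θ ∈ (−60°,
60°] and |t| ≤ 20 % of a 200 px frame (20 phantoms, noise 0 and σ = 5);
elastic recovery with 8 px fields on 128 px images (10 phantoms); a 15-pair
cohort at 400 px as above. Problem sizes are phantom-scale by design — the
block size, search radius and image sizes scale the published workflow's
geometry down proportionally so the whole suite runs in minutes.

What the phantoms do **not** capture: photorealistic staining variation,
tearing and folding (topology-breaking deformations), partial-section
loss, out-of-plane (curved-slice) mismatch between the physical section
and any single plane of the volume, and CT reconstruction artefacts.
Passing on phantoms therefore demonstrates the correctness of the
estimators under their stated models, not performance on every pathology
slide.

## Other numerical choices

* Otsu: threshold maximises between-class variance on the integer
  histogram; smallest threshold among maximisers (determinism); mask is
  strictly-above; constant images are rejected. On a phantom whose CT
  histogram is dominated by the paraffin/tissue split, a two-class Otsu
  separates tissue from background rather than particles — on real
  particle-laden SRµCT data the radiopaque particles dominate the upper
  mode. The segmentation is exposed as its own operation so a
  region-of-interest or pre-masking step can precede it.
* Rigid resampling snaps source coordinates within 1e−9 of an integer to
  that integer, so lattice-preserving motions (90° turns, integer shifts)
  are exact.
* Alpha channels in input files are dropped with a logged warning; the
  pipeline is defined on 1- and 3-channel images.
* Parameter files are flat `key = value` text; unknown keys are rejected
  by name, malformed lines by line number. This dialect is the package's
  own: adopting an external registration tool's parameter dialect would
  promise semantics this implementation does not have.

## Known limitations

* 2D only: the virtual slice is chosen by explicit plane parameters; no
  automatic 2D–3D slice search and no curved-plane fitting.
* No scale/shear in the rigid stage (by design).
* The elastic optimiser is first-order; very large deformations (beyond
  the pyramid's capture range, roughly the coarsest control spacing) need
  a better initial plane or rigid fit.
* No model-order selection for the mixture (K is user-set) and no spatial
  regularisation of the class labels.
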