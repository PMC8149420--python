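# histoct

**Elastic co-registration of 2D histology with microCT virtual slices, plus
the downstream analyses that registration enables.**

X-ray microCT of paraffin-embedded tissue ("virtual histology") shows 3D
morphology at micrometre resolution but lacks the molecular specificity of
classical (immuno-)histochemistry. Overlaying a stained physical section
onto the matching virtual slice of the CT volume combines both — but
sectioning and staining deform the tissue non-uniformly, so a rigid overlay
is never good enough. `histoct` implements the complete matching workflow
for people who need that overlay: imaging scientists and pathologists
working with correlative CT/histology data.

## What it does

1. **Virtual slicing** — extract an oblique plane from a CT volume by
   trilinear interpolation (`core_imaging.extract_plane`).
2. **Rigid pre-alignment** — estimate global rotation and translation of
   the histology ("moving") image with respect to the CT virtual slice
   ("fixed") by the Fourier–Mellin method: rotation from phase correlation
   of polar-resampled magnitude spectra, translation from phase correlation
   after de-rotation (`rigid_prealign`).
3. **Elastic registration** — model the residual deformation as a cubic
   B-spline free-form deformation `T(x) = x + D(x)` on a control-point
   lattice and maximise the mutual information

   `MI(F, M∘T) = Σ p(f,m) log₂ [ p(f,m) / (p(f) p(m)) ]`

   over a 32-bin joint histogram, coarse-to-fine, at 1/10 of the original
   resolution. The recovered deformation is rescaled and applied to every
   colour channel of the full-resolution moving image
   (`elastic_registration`).
4. **Quality control** — the Displacement Index (DI), an inverse-MI-weighted
   mean block displacement from block matching (default blocks of 500 px at
   50 % overlap):

   `DI = (1/G) Σᵢ |dᵢ| · MIᵢ⁻¹,  G = Σᵢ MIᵢ⁻¹`

   Lower DI means better alignment; 0 is a perfect (same-content) match
   (`registration_quality`, with the before/after unpaired two-tailed
   t-test).
5. **Nanoparticle segmentation** — Otsu thresholding of the radiopaque
   particles in CT and pseudo-colour fusion into the registered histology
   (`core_imaging.otsu_threshold`, `fuse_overlay`).
6. **Tissue classification** — after registration each pixel carries a 4D
   feature vector (CT grey + histology R, G, B); a 6-component Gaussian
   mixture fitted by EM yields per-class posterior probability maps and mix
   coefficients interpretable as tissue fractions (`tissue_classification`).
7. **Phantoms** — a seeded generator of multimodal phantom pairs with known
   rigid + elastic ground truth and per-pixel class labels, used as the
   test bed throughout (`phantom_fixtures`).

## Worked example

Generate a phantom pair (a CT-like slice and an MTS-stained-histology-like
image of the same tissue, misaligned by a known rotation of 8°, translation
(6, −4) px and a smooth elastic field), register it, and measure the
improvement:

```bash
histoct phantom --preset mts-tumour --seed 3 --out-dir phantom
printf 'downscale_factor = 10\npyramid_levels = 3\ngrid_spacing_px = 8\niterations_per_level = 60\n' > params.txt
histoct register phantom/ct.tif phantom/histology.png --params params.txt --channel g --out-dir reg
histoct di phantom/ct.tif phantom/histology.png   --block-size 64 --search-radius 16 --out-dir di_before
histoct di phantom/ct.tif reg/transformed.tif     --block-size 64 --search-radius 16 --out-dir di_after
histoct classify phantom/ct.tif reg/transformed.tif -k 6 --seed 0 --out-dir cls
```

Output:

```
rigid: rotation 8.38 deg, translation (6.372433290300623, -3.9408832551153807)
elastic MI 1.8019 -> 1.8384 bits
DI = 10.8729 over 42 blocks
DI = 2.2635 over 42 blocks
component 1: 46.2%
component 0: 30.7%
component 3: 8.3%
component 4: 6.0%
component 2: 5.8%
component 5: 3.0%
```

Reading the numbers: the Fourier–Mellin stage recovers the planted rigid
misalignment (8°, (6, −4) px) to a fraction of a degree/pixel; the elastic
stage then raises the mutual information of the pair. The Displacement
Index drops from 10.9 (unregistered) to 2.3 (registered) — blocks of the
registered pair match at near-zero offsets. The mixture classifier's mix
coefficients are the estimated pixel fractions of the six tissue classes,
largest first (here dominated by the tumour-tissue and background
components). Each command writes a JSON run manifest (inputs, parameter
values, content hashes, timings) from which `histoct rerun` reproduces the
run bit-identically.

## Layout

```
src/histoct/
  core_imaging.py          image/volume model, I/O, preprocessing, Otsu, composites
  bspline.py               cubic B-spline displacement fields
  rigid_prealign.py        Fourier–Mellin rotation + translation
  elastic_registration.py  MI-driven B-spline registration and the full pipeline
  registration_quality.py  block matching, Displacement Index, statistics
  tissue_classification.py 4D GMM/EM classification
  phantom_fixtures.py      seeded ground-truth phantom generator
  cli.py                   `histoct` command-line frontend
docs/methods.md            models, parameters, design decisions, limitations
```
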