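# Methods

This note documents the models behind `hsifuse`, the parameter choices
that matter, what the synthetic phantom does and does not emulate, and the
numerical decisions a maintainer should know about.

## Processing model

All data are `(y, x, λ)` datacubes on a top-left-origin, 0-based pixel
grid, stored as float32.  The processing matrix applied per modality is:

| step | NIR | MIR | RGB | fused |
|---|---|---|---|---|
| reference correction | ✓ | – | – | – |
| spike removal | ✓ | – | – | – |
| vignette correction | – | ✓ | ✓ | – |
| background masking | ✓ | ✓ | ✓ | ✓ |
| min–max normalization | per spectrum | per band | per spectrum | per band |
| SPA band selection (k = 20) | ✓ | – | – | – |
| layer registration (ORB) | – | ✓ | – | – |
| resize to MIR grid | ✓ | – | ✓ | – |
| ECC alignment to MIR | ✓ | – | ✓ | – |
| spectral concatenation | – | – | – | ✓ |
| mini-batch k-means (k = 9) | ✓ | ✓ | ✓ | ✓ |

Order is fixed: radiometric preprocessing on the native grid, then resize,
then registration, then fusion.  The MIR grid is the reference because it
is the finest.

### Reference correction

`R(λ) = I(λ)/I₀(λ)` with a wavelength-matched, strictly positive reference
spectrum.  Converts raw NIR counts (which carry the lamp/detector
spectrum) to relative reflectance.

### Spike removal

Per pixel spectrum: modified Z-scores `Z = 0.6745·(d − median d)/MAD(d)`
of the first-difference series `d` flag a band when either adjacent
difference exceeds the threshold in magnitude; flagged bands are replaced
by the mean of the non-flagged intensities in a centered window (width 13,
shrunk at the spectrum edges).  Defaults: threshold 0.125, window 13.

Numerical decisions: where `MAD = 0`, scores are ±∞ away from the median
and 0 at it, so isolated impulses on flat spectra are still caught while
fully constant spectra pass through bit-unchanged.  If a replacement
window contains no non-flagged value, the window median is used (robust to
the impulse itself).

A threshold of 0.125 is far below the conventional 3.5 for modified
Z-scores: on smooth, noisy spectra it flags the majority of bands, so the
step acts as a robust spectral smoother that also removes impulses.  That
is acceptable for clustering (the same operator is applied to every pixel)
but callers who want surgical despiking should raise the threshold; it is
exposed everywhere (API and workflow YAML).

### Vignette correction

Per band: illumination field `F = G_σ * I` (Gaussian blur, reflect
boundary), corrected image `I′ = I·mean(F)/(F + ε)`.  The `mean(F)` factor
preserves the global intensity scale; with `ε = 0` the spatial mean of
each band is preserved to within 1%.  Modality defaults σ = 10 px (MIR),
σ = 100 px (RGB), ε = 5.

Two caveats, both inherent to self-estimated flat-fielding.  First, the
correction genuinely flattens only fields that vary on scales larger than
σ; on a flat image under a broad radial dip (field scale ≳ 6σ) it restores
a coefficient of variation < 0.02.  Second, on specimen images with a dark
background the blurred field tracks the foreground layout as much as the
illumination, so with data in [0, 1] and ε = 5 the denominator is
ε-dominated and the step reduces to a gentle, nearly linear rescale.  The
pipeline therefore treats vignetting as a mild artifact (the phantom
injects 10% radial falloff) rather than something to be removed
aggressively; the per-pixel multiplicative residual cancels in the
per-spectrum-normalized modalities.

### Background masking

Otsu's threshold on the panchromatic projection (per-pixel band mean);
pixels below it are background.  Spectra are never modified — the mask is
metadata that downstream steps (SPA, clustering, silhouette, SCC) use to
restrict themselves to foreground.  Degenerate histograms produce a
warning and an empty mask instead of an error.

### Min–max normalization

`(v − min)/(max − min)` per pixel spectrum or per band image; constant
vectors map to zeros; idempotent.  NIR and RGB use per-spectrum scaling:
it removes the multiplicative per-pixel factors (vignette residual,
micro-texture) and, for RGB, keeps each pixel's channel contrast well
above the noise floor — per-band scaling would compress the brightest
tissue class onto a near-constant normalized spectrum whose per-pixel
correlations are noise-driven.  MIR uses per-band scaling because a
3-point per-spectrum normalization would destroy most of its class
contrast (only one degree of freedom survives).  Post-merge normalization
is per band, aligning the ranges of heterogeneous sensors without
rescaling spectral shape within a pixel.

### SPA band selection

Greedy successive projection on the foreground pixel × band matrix:
initialize with the maximal-norm band column; at each step project all
unselected columns onto the orthogonal complement of the span of the
selected ones (incremental Gram–Schmidt with running squared residual
norms) and take the maximal residual norm, ties to the lowest band index.
The residual-norm sequence is non-increasing by construction.  NIR default
k = 20.

### Registration

*Layer registration* (area-scanned MIR): ORB keypoints per band, matched
to a reference band by Hamming distance with cross-check and a 0.75 ratio
test, euclidean transform by RANSAC (inlier threshold 2 px, seeded).
Bands are presmoothed (σ = 1 px) before detection and the FAST threshold
is kept low (0.01): inter-band class contrast can differ or invert, and
the corners shared across bands (tissue silhouette, micro-texture) are
low-contrast.  Fewer than 8 inliers is an error naming the band, or an
identity fallback when configured.

*Cross-modal alignment*: the enhanced correlation coefficient
ρ(p) = ⟨ī_r, ī_w(p)⟩/(‖ī_r‖·‖ī_w(p)‖) between zero-mean panchromatic
projections is maximized by forward-additive Gauss–Newton-type updates
(the λ-scaled error formulation) over a 3-level pyramid, warping with
bilinear interpolation and restricting every inner product to the pixels
the current warp keeps in the field of view.  Default model euclidean
(thermal drift and stage shifts are rigid-dominant); translation and
affine available.  Convergence: parameter update norm < 1e-6 or 200
iterations per level.  The iteration keeps the best-ρ parameters, stops
after 12 iterations without improvement, and declares divergence only
after 10 consecutive iterations more than 0.01 below the best ρ — near
its plateau the update direction can jitter without that being failure.
One transform per cube: the panchromatic projection drives the alignment
and all bands are warped with the result.

Transforms are 2×3 matrices mapping reference (x, y) to moving-image
coordinates — exactly the inverse map a backward-warping resampler needs —
serialized to JSON with model and final score.

### Fusion

Registered cubes are concatenated along the spectral axis in canonical
NIR, MIR, RGB order; per-band min–max normalization harmonizes sensor
scales; the fused background mask is the logical OR of the inputs'.
Because the physical NIR/MIR/RGB wavelength ranges overlap numerically,
the fused axis is a strictly increasing integer index 0..B−1 where every
band retains its (modality, original wavelength nm) pair — lossless
bookkeeping rather than a physical axis.

### Segmentation and metrics

Mini-batch k-means (scikit-learn behind the module surface): k-means++
initialization, uniform mini-batches (default 1024) with per-center
learning rates, an update budget of 300 batches, 10 restarts, mandatory
seed.  Final labels and inertia come from one full nearest-center pass;
background pixels are labeled −1.  Defaults k = 9 (the number of
annotated tissue classes), Euclidean distance throughout.

Mean silhouette `s = (b − a)/max(a, b)` is computed exactly (vectorized
pairwise distances, singletons score 0) and equals the O(n²) textbook
definition; above 5000 points a seeded uniform subsample is scored
because the metric is quadratic.  SCC is the mean per-pixel Pearson r
between original and fused spectra over foreground pixels, skipping (and
counting) zero-variance spectra; it is invariant to per-spectrum affine
intensity maps.  Mutual information uses a 64-bin equal-width joint
histogram of min–max-scaled panchromatic images, natural log; arguments
are canonically ordered internally so symmetry holds exactly, not just
analytically.  ARI excludes background positions pairwise.

## The phantom

The generator emulates the acquisition geometry of a three-modality scan
of one tissue section at a configurable scale (default 0.2: reference
grid 320×400 standing for 1600×2000 at 10 µm).  Nine classes — three
grey-matter blobs, four elongated white-matter tracts, two CSF cavities —
on a dark background, with per-class spectral signatures built from the
compartments' absorption logic (water features strong for grey/CSF, CH
lipid features for white matter).  Degradations, all recorded in the
ground truth: per-modality downsampling (NIR ≈ grid/7.6, RGB ≈ grid/1.6),
rigid misalignment of NIR and RGB (uniform in ±8 px, ±3°), per-band MIR
layer shifts (±3 px), a 10% radial vignette on MIR and RGB, 5%
multiplicative micro-texture shared across modalities, impulse spikes on
0.2% of NIR samples at ≥ 20× the signal, additive Gaussian noise
(σ = 0.01 on the reflectance scale) and a smooth lamp spectrum
multiplying the raw NIR counts.

Class-modality visibility is engineered so the value of fusion is a
construction property, not an accident: the two CSF classes share one NIR
signature, the first two grey classes share one MIR signature, and RGB
colors are constant per compartment.  Only the fused cube can separate
all 9 classes; each single modality tops out lower.  The signature tables
live in `phantom_constants.py` and are versioned so tests stay stable.

What the phantom does **not** emulate: anatomically realistic geometry,
optical physics (scattering, specularity, chromatic aberration),
non-rigid distortion, detector-specific noise models, or stitching
artifacts.  Passing tests therefore demonstrate that the pipeline's
operations are correct and composable under known, realistic-magnitude
degradations — not that the defaults are optimal for any particular
instrument.

Geometry convention: a modality image samples the reference scene through
`A = M_mis ∘ S`, where `S` is pixel-center grid scaling (matching bilinear
resize) and `M_mis` a rigid misalignment in reference coordinates; the
alignment a pipeline should recover is `M_mis⁻¹`, and recovery error is
reported as the residual of their composition at the image center.

## Problem sizes

The test-suite and acceptance runs use the scale-0.2 phantom (320×400
reference grid, 42×53×260 NIR, 200×250×3 RGB) — large enough that every
stage (SPA on ~1000 foreground spectra, ECC over 128k pixels, k-means over
~27k fused spectra) runs in its realistic regime while a full pipeline
completes in seconds.  Structural tests use scale 0.05.

## Known limitations

* ECC assumes a mostly shared structural layout across modalities; with
  strong region-wise contrast inversion the global optimum can be biased
  by a fraction of a pixel relative to ground truth.
* Cross-band ORB matching degrades when bands share little structure;
  the identity fallback is off by default so such failures are loud.
* Vignette self-estimation cannot separate illumination from specimen
  layout on dark-background images (see above); treat the step as a mild
  radiometric adjustment there.
* The despiking default (0.125) is a smoother in practice; see above.
* Mini-batch k-means is a local optimizer; with the mandatory seed results
  are reproducible, but k must be chosen by the user (no model selection).
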