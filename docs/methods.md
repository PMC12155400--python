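# Methods

This note documents the models, parameter choices and numerical conventions
behind `cytoiex`, and what the synthetic benchmark does and does not show.

## Synthetic nucleus scenes

The generator emulates two cytological populations on an H&E-like field.
Class presets (means ± dispersions used as truncated-normal parameters,
cut at ±4 sd and at each quantity's validity range):

| quantity | pathological | normal |
|---|---|---|
| nuclear area (px²) | 3737.5 ± 280 | 2093.3 ± 60 |
| circularity 4πA/P² | 0.6750 ± 0.04 | 0.8933 ± 0.02 |
| chromatin entropy (bits) | 4.3875 ± 0.23 | 2.8567 ± 0.06 |
| N/C ratio | 0.7075 ± 0.05 | 0.4833 ± 0.03 |
| hematoxylin depth (OD) | 1.0 | 0.7 |

The N/C dispersions are not part of the reference cytology and were set to
follow the same relative-dispersion pattern as the other features.  Stain
depths are a rendering choice within the typical nuclear hematoxylin OD
range, ordered so the malignant-type class is the more hyperchromatic.

**Shape.** Nuclei are star-convex radial-harmonic contours
ρ(θ) = R·(1 + a·Σ_{k=2..6} w_k cos(kθ + φ_k)) with per-nucleus random
harmonic weights and phases.  Because measured circularity depends on the
perimeter estimator and rasterization, the amplitude `a` is read off a
per-profile calibration curve: rasterized circularity is measured on a
12-point amplitude grid in [0, 0.97], made monotone by running minimum, and
inverted by interpolation.  Profiles whose reachable range misses a low
target are redrawn (deterministically from the same stream, up to 10 times).
After amplitude selection, R is rescaled until the pixel-count area is
within 2% of target.  Rasterization exploits star-convexity (pixel inside
iff its radius ≤ ρ at its polar angle), which is exact for this family and
fast.  The perimeter estimator throughout the package is the Crofton
4-direction formula, which is near-unbiased on disks (measured disk
circularity ≈ 1.005–1.01).

**Texture.** Chromatin texture is i.i.d. per pixel from a one-parameter
geometric-like family p_i ∝ exp(−λ(255−i)/255), with λ found by binary
search so the *distribution's* Shannon entropy equals the target exactly.
Mass sits at the high-value end, which the renderer maps to high absorbance
(dark chromatin).  No spatial correlation is imposed by default: the entropy
descriptor depends only on the marginal histogram, so spatial clumping would
add realism without changing the measured quantity.  The plug-in entropy of
a finite sample is biased low by roughly (K−1)/(2N ln 2) bits (≈ 0.05 bits
at 3700 px over 256 levels), well inside the class dispersions.

**Rendering.** Absorbance mixes additively in optical density along the
standard published H&E stain vectors (hematoxylin for nuclei, scaled by the
texture; a flat 0.25 OD eosin for the cytoplasm ellipse, whose scale is
bisected so the whole-cell area matches the target N/C ratio), then
intensity follows Beer–Lambert I = 256·10^(−OD) − 1 with additive Gaussian
sensor noise (sd 2 levels) and an effectively near-white background.
Placement is rejection sampling on cell bounding circles with a 3 px margin
and 1000 attempts per nucleus; exhaustion raises an explicit canvas-too-small
error.  Identical (preset, n, canvas, seed) give bit-identical scenes.

**What the benchmark does not emulate:** tissue architecture, overlapping
cells and conglomerates, stain variability between slides and scanners,
out-of-focus blur, spatially structured chromatin, and mitotic figures.
Passing the synthetic benchmark shows the pipeline's operators are correct
and mutually consistent at realistic signal levels — not that its accuracy
transfers to clinical material.

## Segmentation

Optical density is −log10((I+1)/256) per channel; stain amounts come from
projecting OD onto the inverse of the fixed H&E stain matrix with negative
projections clipped.  Hyperchromatic pixels exceed mean + 2σ of the
hematoxylin channel over the whole image (a tissue-only statistics flag is
available; whole-image is the default reading).  Cleanup is opening then
closing with a radius-2 disk — erosions treat the outside of the frame as
foreground so border objects stay border-touching and are excluded by the
border rule rather than silently eroded inward — followed by 8-connected
labeling, exclusion of components below 500 px² (≥ 500 is kept) and of
border-touching components.

Within each candidate region the hematoxylin channel is Gaussian-presmoothed
(σ = 2 px) and thresholded by a 51 px local mean with a +0.02 OD strictness
offset.  The presmoothing is required because chromatin texture is
high-frequency relative to the nucleus scale; without it an adaptive
threshold shreds the mask.  Watershed seeds are maxima of the (lightly
smoothed) Euclidean distance transform that stand out by at least 5 px of
EDT height, with maxima closer than 10 px merged into one seed — the
prominence condition stops lobulated single nuclei from being split while
genuinely overlapping nuclei, whose EDT saddle is deep, still separate.
Masks failing solidity ≥ 0.6 (area / convex-hull area) or eccentricity
≤ 0.98 are discarded; morphological Chan–Vese refinement (10 iterations) is
available but off by default, and no result depends on it.  Nuclei of
roughly 40–80 px diameter motivated the window and seed-distance defaults.

## Features

22 numeric columns cover the 21 canonical descriptors (the major and minor
axis lengths share one descriptor slot).  Conventions where a choice had to
be made: solidity is area over convex-hull area and "convex area" is the raw
hull area in px² (the filterable, dimensionally meaningful reading); extent
uses the axis-aligned bounding box; GLCM uses 32 gray levels, distance 1,
the four standard angles averaged, symmetric and normalized, with
co-occurring pairs restricted to mask-interior pixels (out-of-mask pixels
are coded as a sentinel level that is dropped before normalization);
correlation of a constant patch is 1 by the limit convention; entropy uses
the raw 256 levels; histogram modality uses 32 bins smoothed by a 3-bin
moving average, peaks requiring prominence ≥ 5% of the pixel count and
valleys counted strictly between consecutive peaks.  Texture is computed on
an intensity image reconstructed from the hematoxylin OD channel by
inverting the OD convention (a luminance option exists), so absorbance-type
descriptors keep their physical meaning.

Normalization is per feature: Shapiro–Wilk p ≥ 0.05 selects z-scoring with
training statistics, otherwise a rank transform to (rank − 0.5)/n mapped to
[0, 1], with new values interpolated into the stored sorted training sample
(clamped at the ends).  Constant columns map to 0 and are flagged.

## Information-extreme training

The training matrix is binarized against tolerance fields centered on the
normal class's feature means (the normal class is the natural reference
state); the per-feature field scale δ_H,i is the observed training range,
floored at 1e−9 so a constant column degrades to an uninformative bit rather
than aborting.  The criterion is the modified Kullback measure given in the
README with regularizer 10⁻² (r = 2); its printed form contains an undefined
count in the final factor, and this implementation adopts the standard
correct-minus-error reading |n_min − (K1+K2)|, with the criterion function
kept pluggable.  The measure is floored at 0 (beyond n_min total errors a
container carries no information), which keeps the normalized criterion in
[0, 1] across the whole radius sweep.

The radius sweep is exhaustive over d = 0..N within the working domain
(both error rates < 0.5) with the additional constraint
d < d(x*_own, x*_rival) so a container cannot swallow the rival center.
Ties break toward the smaller radius (tighter container, fewer false
alarms).  The outer δ grid is 0.01..0.99 in steps of 0.02, scored by the
class-mean normalized criterion with inseparable classes scoring 0; δ ties
also break low.  If every δ leaves both working domains empty, training
fails loudly with the sweep trace attached.

Decision rules: μ_m = 1 − d/d*_m, largest positive μ wins, exact positive
ties go to the malignant class (recall-prioritizing), and all-non-positive μ
yields the explicit *unclassified* outcome.  A zero-radius container admits
only its reference vector.  Under the default policy, unclassified cells
score as normal predictions in the metrics (a rejected cell is a missed
detection, not a false alarm); an exclude policy is available.

A bits-per-feature option (concentric tolerance sub-fields of widths
δ·j/b) generalizes the encoding beyond one bit per feature; the default is
1 and nothing in the package's validation depends on larger codes.

## Problem sizes and determinism

The end-to-end benchmark uses ten mixed scenes of 20 nuclei on a 1024²
canvas (≈ 200 cells), split 100 train / 76 test; parameter-recovery
measurements use 300 nuclei per class.  These sizes put standard errors
comfortably inside the class dispersions while keeping a full run in tens of
seconds on one CPU.  All randomness flows through seeded numpy generators;
fixed seeds give bit-identical scenes, feature tables, models and reports.

## Known limitations

- The synthetic benchmark's separability is governed by the preset gap; the
  near-ceiling classification metrics on it are a correctness check, not a
  clinical performance claim.
- The hyperchromasia threshold assumes nuclei are a minority of the image;
  on fields dominated by tumor the mean + 2σ statistic shifts and the
  tissue-only flag becomes necessary.
- One-bit-per-feature Hamming codes cap container radii at the feature
  count; richer codes are exposed but unvalidated.
- Only the flat two-class alphabet is implemented; hierarchical class trees
  and spatial (inter-cell) features are out of scope.
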