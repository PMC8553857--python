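# Methods

This note documents the conventions, parameter defaults and numerical
choices behind `vesselniche`, and what validation on synthetic phantoms
does and does not establish.

## Coordinate and voxel conventions

Arrays are stored `(z, y, x)`; every public coordinate, spacing and extent
is `(x, y, z)` in micrometres. Voxel `(k, j, i)` has its centre at
`((i+0.5)·sx, (j+0.5)·sy, (k+0.5)·sz)`, so a volume occupies the half-open
box `[origin, origin + shape·spacing)`. Volumes of interest are half-open
(a point on the lower face is inside, on the upper face outside);
cylindrical VOIs are axis-aligned and unbounded along their axis, matching
the practice of letting the VOI span the full tissue thickness. Default
light-sheet spacing is 1.3 × 1.3 × 2.5 μm; μCT voxels are 9 μm isotropic.

## Synthetic phantoms

The generator emulates the tissue architecture the analysis assumes, not
the optics of any particular instrument.

**Vessels** are piecewise-linear centrelines with a constant radius,
rendered as open-ended cylinders per segment plus spheres at interior
joints. End caps are deliberately omitted so a straight tube has volume
exactly πr²L, which makes voxel-counting accuracy measurable against a
closed form. Point-to-surface distances (used for planted cells and as
ground truth) are computed analytically against the same shape, including
the flat end disks. Three z-layers hold the phenotypes: a dura-analog
(bottom 15 %), a marrow-analog (70 %), and a periosteum-analog (top 15 %).
Arteriole-type CD31ʰⁱEmcn⁻ tubes run inside the outer layers (radius
6–9 μm), CD31ˡᵒEmcnʰⁱ sinusoid-type tubes in the marrow (5–8 μm), and
dual-positive CD31ʰⁱEmcnʰⁱ tubes cross all layers like transcortical
canals (4–6.5 μm). Distinct tubes are kept at least 4 μm apart
(surface-to-surface, rejection sampling): vessels do not interpenetrate in
tissue, and the gap keeps distinct tubes from fusing into one connected
component at either analysis resolution.

**Intensities.** Channels are rendered at 5× the default downstream
threshold for "hi" expression and 0.5× for "lo", with "−" at zero. The
signal-to-background ratios of real stains were never printed; these
factors are a convention that makes phenotype ground truth unambiguous
under default thresholds, and both are configurable.

**Cells** are anisotropic Gaussian blobs (σ = diameter/4) at the
pre-measured marker sizes. Placement follows a distance law to a target
phenotype — exponential(scale), uniform(0, max), or touching — drawn
distance first, position second: a candidate position at the drawn
distance from a random surface point is accepted only if its exact
analytic distance to the nearest target tube agrees within 0.1 μm and it
lies inside the scene, so the recorded `true_distance_um` follows the law
by construction. A configurable fraction of cells is instead uniform in
the volume. The defaults used in validation (exponential, scale 5 μm,
fraction_background 0) plant the association the 5 μm proximity statistic
is designed to detect.

**Noise** is optional: Gaussian PSF blur, constant background, Poisson
shot noise at a configurable gain, and additive Gaussian read noise. The
all-zero noise model reproduces the clean raster bit-for-bit, which is
what the determinism and recovery tests rely on. The phantoms do not
model light-sheet stripe artifacts, scattering, depth-dependent
attenuation, or tiling shading; passing recovery tests therefore
demonstrates correctness of the measurement chain, not robustness to
every real-world degradation.

**RNG.** One integer seed feeds named, independently-spawned streams for
vessels, cells and noise, so adding cells never perturbs vessel geometry.

## Segmentation

* **Background subtraction** is a Gaussian high-pass: the background is a
  Gaussian blur with σ = radius/2 per axis (converted to voxels), and the
  output is clipped at zero. The original tool's local-background
  algorithm at the published 10 μm radius is proprietary; the tests hold
  this surrogate to the same behaviour as an explicit morphological
  rolling-ball oracle on blobs and ramps. A radius smaller than one voxel
  on any axis is rejected.
* **Vessel surfaces** are 26-connected components of the thresholded,
  background-subtracted volume; objects under the 10⁴ μm³ volume filter
  (voxel count × voxel volume) are removed. Thresholds were "optimized per
  experimental group" in the original workflow without printed values, so
  the default is per-channel Otsu with a scalar config override.
* **Split objects** re-segments each component by seeded watershed on the
  negated interior (anisotropic) distance map. Seeds are distance-map
  local maxima separated by at least the 10 μm seeding diameter in
  physical distance; ties are broken by response then by ascending
  (x, y, z), so the result is fully deterministic. The children partition
  the parent voxel set exactly. Elongated tubes are intentionally
  subdivided into segments — classification and volume summaries operate
  per piece and re-aggregate.
* **Spot detection** is a single-scale anisotropic Laplacian-of-Gaussian
  with σ per axis set from the marker's lateral/axial diameters and the
  voxel spacing, local-maximum selection, and suppression of duplicate
  maxima within one lateral radius (keeping the stronger). The published
  workflow's proprietary spot-quality score is replaced by the LoG
  response; the default threshold (10 % of the maximum response) is
  calibrated on clean synthetic renders.
* **Down-sampling** by the integer factor (published: 2) takes the block
  mean for intensities and the block mode for labels (background wins
  ties, then the lowest id), so instance identities survive the
  resolution change; spacing scales by the factor.

## Phenotype classification

For each CD31 object, `f` = fraction of its voxels inside the Emcn mask:
the object is CD31ʰⁱEmcnʰⁱ when `f ≥ colocalization_fraction` (and
`f > 0`), else CD31ʰⁱEmcn⁻. For each Emcn object, `g` = fraction inside
the CD31 mask: co-localized objects are dropped as the Emcn face of a
dual-positive vessel already counted from the CD31 side; the rest are
CD31ˡᵒEmcnʰⁱ. "Presence" of co-localized signal was never defined
quantitatively in the original workflow; the fraction rule (default 0.05)
is this package's convention — robust to single-voxel noise, monotone in
the threshold, and degrading exactly to any-voxel overlap at 0. Dim
CD31ˡᵒEmcnˡᵒ sinusoids are excluded implicitly: objects exist only where a
channel segments at all. Dropped objects are retained in the per-object
table (phenotype `"dropped"`) for auditability but never counted in
volumes.

## Distances

`anisotropic_edt` is the exact Euclidean distance transform with per-axis
physical sampling; tests hold it to brute-force minimum distances at
float precision.

Cell-to-vessel distances are measured to the **surface** of the
classified masks, sub-voxel. A binary mask determines its object's
surface only to within half a voxel: the voxel-centre lattice lies inside
the true surface and the union of voxel boxes circumscribes it. The
reported distance is the midpoint of the exact distances to these two
brackets (candidate nearest voxels come from the EDT feature transform),
which halves the worst-case quantization error and is empirically
unbiased on tube phantoms (mean error < 0.05 μm at 1.3/2.5 μm spacing,
versus ~ +0.5 μm for sampling the centre-to-centre distance map).
A cell whose centre lies inside the mask is touching: exactly 0 μm,
with interior distances clamped rather than signed. A phenotype absent
from the volume yields `inf`, and such cells are excluded from that
phenotype's denominators; cells outside the volume are flagged and
excluded everywhere.

Phenotypes are classified on the 2×-down-sampled grid (as published), but
distance maps are built at full acquisition resolution: each full-res
object inherits the volume-weighted majority phenotype of its split
pieces (ids survive the block-mode down-sampling). A 5 μm axial voxel at
the down-sampled grid would otherwise add avoidable quantization bias to
a sub-voxel quantity.

The exponential affinity scale is recovered by maximum likelihood — the
sample mean of finite nearest distances, with touching cells contributing
zero.

## μCT morphometry

Bone is `data ≥ threshold` with only the largest 26-connected component
kept (speckle removal); the fixed threshold is scanner-calibration
specific, was never printed, and is therefore a required input with no
default. "Shrink wrap" is re-implemented as morphological closing
(configurable ball radius, default 10 voxels, recorded in the output)
plus interior hole filling, intersected with the initial box VOI; BV is
the bone mask inside the resulting TV. Surface area comes from a
marching-cubes iso-surface after a 1-voxel Gaussian pre-smoothing of the
binary mask — raw binary marching cubes overestimates sphere SA by ~8 %,
the smoothed mesh is within 5 %. The published VOI dimensions ship as
named presets (`ct_parietal` 4.95 × 3.6 × 0.9 mm, `ct_frontal`
3.6 × 3.6 × 0.45 mm, reduced knockout-cohort variants, the 1 mm defect
cylinder, and the defect/systemic light-sheet VOIs). Re-slicing to the
transverse plane is an explicit axis permutation, not registration. The
defect/contralateral ratio uses the raw threshold mask inside each 1 mm
cylinder — no largest-component filter, since newly formed bone in a
defect is legitimately fragmented.

## Optics

The light sheet is modelled as a Gaussian beam: waist radius
w₀ = λ/(π·NA), full width at the waist 2·w₀ (1/e² convention — FWHM
differs by √(2 ln 2)/√2 ≈ 0.589), Rayleigh range x_R = π·w₀²/λ, and width
2·w₀·√(1 + (x/x_R)²) at lateral offset x. At NA 0.154 the waist widths
are 2.32 μm (561 nm) and 3.25 μm (785 nm). The published edge-of-tile
width figure cannot be reproduced from the stated NA and wavelengths
under this standard divergence formula with any obvious tile half-width;
the offset formula is exposed but no claim is made for that figure.

## Tile fusion

Alignment is translation-only (light-sheet stages are
translation-accurate; the original workflow aligned tiles manually in
x–y). Each tile is registered to the already-fused canvas by masked phase
correlation seeded at its nominal stage offset, with the correction
bounded to ±10 % of the tile size; failures fall back to the nominal
offset with a logged warning rather than aborting. Overlaps are blended
by separable linear feathering, which is exactly conservative for
constant images and avoids seam steps that would bias background
subtraction. Multi-acquisition fusion with per-side illumination
correction is out of scope.

## Problem sizes used in validation

The validation suite runs entirely on phantoms chosen to exercise every
code path at desk scale: classification and affinity-recovery scenes of
400 × 400 × 200 μm (≈ 7.6 M voxels at acquisition spacing) with ~30 tubes
and 2,000 cells; 200 random ≤32³ masks for distance-transform exactness;
spheres of 20-voxel radius for the morphometry closed forms. These sizes
are the package's validation conditions; the pipeline itself streams
per-object and is limited only by memory for the label volumes.

## Known limitations

* Phenotyping is per object (hi/lo per channel); continuous intensity
  gradients along a vessel are not modelled.
* The co-localization fraction, channel thresholds, spot threshold and
  synthetic intensity ratios are declared conventions, not measured
  values; all are configurable.
* Distance statistics are descriptive; spatial point-process null models
  (Ripley's K, CSR tests), bootstrap intervals and group-level inference
  are out of scope — exported CSVs are intended for downstream
  statistical software.
* The phantom generator does not simulate vascular growth, stripe
  artifacts or refractive distortions; robustness to those must be
  established on real data.
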