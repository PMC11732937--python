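# Methods

## The problem

Coronary CT angiography overestimates stenosis wherever dense calcium is
present: limited spatial resolution spreads the high-attenuation signal into
neighbouring voxels (blooming / partial-volume effect), hiding the
contrast-filled lumen. Two-scan subtraction addresses this by acquiring a
precontrast and a postcontrast scan, registering the first onto the second,
and removing voxels recognized as calcium while keeping voxels whose
post-minus-pre difference shows contrast medium. In postmortem work the
heart does not beat, so the method's usual failure mode — cardiac motion
between the two scans — is absent, which makes the approach particularly
attractive for forensic angiography of explanted hearts.

`calcisub` implements this pipeline end to end and validates it on a digital
phantom that mimics a physical test object: two polyvinyl-chloride tubes of
2.2 mm inner diameter in a gelatin block, one tube carrying a simulated
calcified lesion, the lumen filled with saline (precontrast) or with an
oil-based contrast agent adjusted to about 450 HU (postcontrast).

## Pipeline

1. **Registration** (`registration`). The precontrast volume is the moving
   image, the postcontrast volume the fixed image, so the subtracted
   angiogram lives on the contrast-enhanced grid. Rigid alignment uses
   Mattes mutual information (64 bins, full sampling — fully deterministic)
   with a 3-level multi-resolution pyramid (shrink 4/2/1, smoothing 1/0.5/0
   mm) and a regular-step gradient-descent optimizer started at identity.
   MI is required because the lumen changes by ~450 HU between the scans,
   which violates mono-modal metric assumptions; an alternative
   `masked_correlation` metric (correlation over fixed-image voxels
   >= 150 HU) anchors on calcium and walls. Metric values are interpolated
   with B-splines: linear interpolation biases the optimum toward
   grid-aligned translations by ~0.1 mm, which is the same order as the
   accuracy we need. An optional demons-style non-rigid refinement
   (Gaussian-regularized update and total field, sigmas 1.0 / 1.5 mm,
   displacement capped at 5 mm, 300 iterations or RMS change < 1e-4)
   handles residual local mismatch; the recovered field is checked for
   positive Jacobian determinant (no folding).

2. **Subtraction** (`subtraction`). On the aligned precontrast volume,
   voxels >= 200 HU are subtraction targets; the mask is dilated by a
   1-voxel ball to catch the blooming rim just below threshold. Inside the
   mask, a voxel with (post - pre) >= 100 HU is "contrasted" and keeps that
   difference (the calcium contribution is stripped; set `retain="post"` to
   keep the raw postcontrast value instead); all other masked voxels become
   0 HU, the soft-tissue baseline the diameter measurement is defined
   against. Outside the mask the postcontrast volume passes through
   bit-exactly. The 100 HU contrast threshold sits well above the 10 HU
   noise floor and well below the ~450 HU nominal contrast.

3. **Quantification** (`quantify`). Lumen diameter is the full width at
   half maximum of the profile curve above a 0 HU baseline: CT values are
   sampled by trilinear interpolation along a line through the lumen center
   (step = min in-plane spacing / 4), the half level is set midway between
   baseline and peak, and the two crossings bracketing the peak are located
   by linear interpolation between samples. The measurement is repeated on
   six consecutive axial slices and averaged; the per-slice standard
   deviation is reported. `min_peak_hu` optionally requires the peak to
   reach contrast-level attenuation, so an occluded segment (a soft-plaque
   plug at wall HU) reads as "no lumen" rather than as a spurious width —
   the contrast-defect readout. Agatston scores follow the standard rule
   (8-connected in-plane lesions >= 130 HU and >= 1 mm², area x HU-band
   weight 1-4) with each slice scaled by `thickness / 3 mm`, since the
   score is defined on 3 mm slices and the pipeline's native slices are
   0.625 mm; this volume-score-style scaling is a documented variant, not
   the literal thick-slice protocol. Reformats: per-ray maximum intensity
   projections, and curved planar reformation with rotation-minimizing
   frames (double-reflection method) so cross-sections do not spin around
   the centerline.

4. **Reliability** (`reliability`). ICC(A,1) — absolute agreement, single
   measurement — from the two-way ANOVA mean squares, with the F-based
   Satterthwaite confidence interval. The two-way *mixed* (intra-observer)
   and two-way *random* (inter-observer) models share this estimator and
   interval in the absolute-agreement single-score case. Classification:
   poor < 0.50, moderate 0.50-0.74, good 0.75-0.89, excellent >= 0.90, with
   half-open bands so 0.899 is "good" and 0.90 "excellent".

## The phantom generator

`phantom.rasterize` renders a declarative `PhantomSpec` (tubes,
calcifications, stenoses, material HUs) onto an isotropic high-resolution
grid, 0.05 mm by default. Every voxel's HU is the partial-volume mixture of
the materials overlapping it, estimated with 4^3 supersampling (straight
axis-aligned tubes use a fast path that is exact along the tube axis away
from feature boundaries). Stenoses shrink the lumen concentrically by a
residual *area* fraction (diameter scales with its square root); occlusions
(fraction 0) are rendered as a soft-plaque plug at wall HU, not as calcium.
A `PhantomGroundTruth` is emitted alongside: centerline samples, true
diameters, patency labels and the calcified-voxel mask.

`emulate_reconstruction` is an image-domain model of FOV and kernel: an
isotropic in-plane Gaussian PSF (FWHM 1.2 mm for the soft-tissue kernel,
0.6 mm for bone — configurable modelling choices that reproduce the
resolution *ordering*, not measured scanner MTFs), exact area-averaged
downsampling to pixel spacing `fov / matrix` (matrix 512 assumed) and
0.625 mm slices, then i.i.d. Gaussian noise (sd 10 HU) from an explicit
seed. There is no projection-domain physics: no beam hardening, scatter,
spiral sampling or iterative-reconstruction modelling.

Consequences worth knowing:

* Because pre and post phases are rasterized on one grid and the blur is
  linear, a perfectly registered post-minus-pre difference cancels calcium
  exactly, so the over-subtraction of the calcified segment is far smaller
  here (~0.1 mm) than in physical scans (~0.9 mm at the softest setting).
  The four-condition comparison therefore validates the *ordering* —
  the (non-calcified − calcified) diameter gap shrinks as resolution
  improves — not its physical magnitude. Passing tests show the pipeline's
  logic and geometry are right; they do not calibrate a scanner.
* The non-calcified tube reads ~0.05-0.08 mm above 2.2 mm because the
  80 HU tube wall lifts the profile shoulders slightly; this is a property
  of FWHM-above-0 applied to walled tubes, visible in real measurements
  too.

## Default parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `threshold_hu` | 200 | precontrast HU at/above which a voxel is calcium |
| `contrast_delta_hu` | 100 | minimum post−pre difference for a contrasted voxel |
| `mask_dilation_voxels` | 1 | ball dilation catching the blooming rim |
| `fill_hu` | 0 | replacement for removed calcium |
| inner diameter | 2.2 mm | simulated vessel lumen |
| wall thickness / HU | 0.8 mm / 80 | tube wall (unreported physically; declared) |
| calcification HU | 900 | collar attenuation (well above threshold) |
| lumen HU pre / post | 0 / 450 | saline vs oil-based contrast |
| FOV / matrix | 120 or 100 mm / 512 | pixel 0.234 or 0.195 mm |
| slice thickness | 0.625 mm | axial spacing of reconstructions |
| PSF FWHM | 1.2 / 0.6 mm | soft-tissue vs bone kernel |
| noise sd | 10 HU | reconstruction noise |

## Numerical choices and edge cases

* One geometry convention everywhere: voxel axes (slice, row, column),
  world frame LPS in mm, 0-based indices, direction matrices proper
  (det +1). Files whose natural reading order is left-handed in this
  convention are canonicalized by flipping the slice axis.
* Out-of-field resampling fills with −1024 HU (air); `misalign` fills with
  the phantom background (0 HU) instead so a simulated inter-scan shift
  does not hand the registration an artificial air rim to lock onto.
* Area-averaged downsampling integrates the piecewise-constant input over
  incommensurate output cells via cumulative sums — exact, not an
  approximate zoom.
* FWHM: a profile with no supra-baseline sample returns "no lumen"
  (distinct from zero); with several disjoint supra-baseline regions the
  one containing the global peak is measured, and a warning is issued only
  if a competing region also reaches the half level (noise blips just
  above 0 HU are not reported). A peak truncated at the profile end uses
  the end position as its crossing.
* ICC of a constant table is returned flagged as undefined rather than
  raising; CI bounds are clipped to [−1, value] / [value, 1].
* All stochastic steps (noise, random misalignments, simulations) take
  explicit seeds; identical seeds give bit-identical volumes.

## Problem sizes

Default study conditions: phantom extent 24 x 10 x 14 mm rasterized at
0.05 mm (480 x 200 x 280 voxels), four reconstructions of ~38 x 51 x 71
voxels, six measured slices per tube. The test suite exercises the same
pipeline at a 0.1-0.15 mm raster, which preserves every qualitative
property at a fraction of the cost; the acceptance script uses the full
0.05 mm setting.

## Known limitations

* Image-domain reconstruction emulation only; blooming magnitudes are not
  scanner-calibrated (see above).
* Demons non-rigid registration assumes matching intensities; applied
  directly to a pre/post pair it will also try to "deform away" the
  contrast difference. In the pipeline it is optional and intended for
  same-phase or post-subtraction refinement; real misregistration artifacts
  (e.g. catheter repositioning between scans) are noted but not modelled.
* No automatic vessel segmentation or centerline tracking: measurement
  sites come from ground truth (phantom) or the caller (real data).
* Partial-arc calcifications are supported on straight tubes only.
* DICOM is read-only; NIfTI is the interchange format.
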