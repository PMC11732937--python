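# calcisub

Calcium-subtraction coronary CT angiography toolkit for postmortem /
ex-situ studies: register a precontrast scan to its contrast-enhanced
counterpart, remove calcified voxels while retaining contrast signal, and
quantify the lumen — with a built-in digital vessel phantom for end-to-end
validation.

## Why

Dense coronary calcification makes CT angiography overestimate stenosis:
blooming and partial-volume artifacts spread the calcium signal across the
lumen. The two-scan subtraction remedy — scan once with saline, once with
contrast, register, and subtract the voxels recognized as calcium — works
especially well after death, when cardiac motion is gone. This package
implements that workflow for researchers in forensic and postmortem imaging
and validates it in silico.

## The method in brief

Given precontrast volume $P$ (moving) and postcontrast volume $C$ (fixed),
both in HU:

1. estimate a rigid transform $T$ (optionally refined by a non-rigid field
   $u$) maximizing mutual information, and resample $P$ onto $C$'s grid;
2. build the calcium mask $M = \{x : P(T(x)) \ge 200\ \mathrm{HU}\}$,
   dilated by one voxel;
3. output
   $S(x) = C(x)$ outside $M$;
   $S(x) = C(x) - P(T(x))$ where the difference $\ge 100$ HU (contrast
   behind calcium); $S(x) = 0$ HU otherwise (calcium removed);
4. measure lumen diameter as the full width at half maximum of the profile
   curve above a 0 HU baseline, averaged over six consecutive slices;
   Agatston scores, MIP and curved-planar reformats, and ICC
   observer-agreement statistics round out the analysis.

The phantom module renders two 2.2 mm inner-diameter tubes (one with a
900 HU calcified collar) in gelatin, with saline (0 HU) or contrast
(450 HU) lumen, and emulates four reconstruction conditions —
FOV 120/100 mm x soft-tissue/bone kernel — as a kernel-dependent in-plane
PSF, area-averaged downsampling to 0.625 mm slices, and 10 HU noise. See
`docs/methods.md` for assumptions and limitations.

## Worked example

`examples/02_subtraction_pipeline.py` misaligns the precontrast phantom by
~1 mm / 1°, reconstructs both phases (FOV 100 mm + bone kernel), then runs
registration, subtraction and measurement:

```
registration converged: True (102 iterations)
  threshold_hu: 200.0
  contrast_delta_hu: 100.0
  mask_dilation_voxels: 1
  ...
  n_retained_contrasted: 329
  n_filled: 8001
non-calcified tube: 2.26 +/- 0.02 mm
calcified tube:     2.28 +/- 0.01 mm
```

Both tubes read close to the true 2.2 mm inner diameter: the collar was
removed (8001 voxels filled) and the contrast behind it retained (329
voxels). The slight overestimate comes from the 80 HU tube wall lifting the
profile shoulders.

The full four-condition experiment
(`python -m calcisub.cli experiment --out run/ --seed 1`, or
`calcisub experiment` once installed; library call
`calcisub.run_phantom_experiment(seed=1)`) prints, at the production
0.05 mm raster:

```
                      condition  noncalc_mean_mm  calc_mean_mm  difference_mm
FOV 120 mm + soft tissue kernel         2.297454      2.199819       0.097634
       FOV 120 mm + bone kernel         2.249905      2.294326      -0.044421
FOV 100 mm + soft tissue kernel         2.294139      2.255205       0.038934
       FOV 100 mm + bone kernel         2.262025      2.266010      -0.003985
```

The non-calcified diameter stays near 2.2 mm under every condition, and the
(non-calcified − calcified) gap — the over-subtraction caused by calcium
blooming — is largest under FOV 120 mm + soft-tissue kernel and vanishes
under FOV 100 mm + bone kernel, the resolution ordering that motivates
reconstructing with a narrow FOV and sharp kernel before subtracting.
(With a perfectly linear, perfectly registered emulation the gap's
magnitude is much smaller than on a physical scanner; the ordering is the
validated content.)

Other entry points: `examples/01…05` cover phantom generation, profile
measurement, Agatston/reformats and ICC; the `calcisub` CLI exposes each
stage (`phantom`, `reconstruct`, `register`, `subtract`, `measure`,
`agatston`, `reformat`, `icc`, `experiment`, `pipeline`) on NIfTI files
with JSON provenance sidecars.

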