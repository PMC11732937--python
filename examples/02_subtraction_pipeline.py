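"""Full calcium-subtraction pipeline on a deliberately misaligned scan pair.

The precontrast volume is shifted by a known rigid transform before
reconstruction, as happens between two physical scans. The pipeline then
recovers the alignment (mutual-information rigid registration), thresholds
calcium at 200 HU on the aligned precontrast image, and removes it while
keeping voxels whose post-pre difference shows contrast medium.
"""

import numpy as np

import calcisub as cs

spec = cs.default_phantom_spec()
pre, _ = cs.rasterize(spec, "pre", raster_mm=0.15)
post, _ = cs.rasterize(spec, "post", raster_mm=0.15)

# a ~1 mm / 1 deg inter-scan misalignment
center = pre.index_to_world((np.array(pre.shape) - 1) / 2)
shift = cs.RigidTransform.from_euler_deg((1.0, 0, 0), (0.8, -0.5, 0.3), center)
pre = cs.misalign(pre, shift)

cond = cs.ReconstructionCondition(100.0, 512, "bone")
pre_rc = cs.emulate_reconstruction(pre, cond, seed=2)
post_rc = cs.emulate_reconstruction(post, cond, seed=3)

result = cs.run_subtraction_pipeline(pre_rc, post_rc)
report = result.registration_reports[0]
print(f"registration converged: {report.converged} ({report.iterations} iterations)")
for key, val in result.provenance().items():
    print(f"  {key}: {val}")

noncalc, calc = cs.measure_tubes(result.volume, spec)
print(f"non-calcified tube: {noncalc.mean_mm:.2f} +/- {noncalc.sd_mm:.2f} mm")
print(f"calcified tube:     {calc.mean_mm:.2f} +/- {calc.sd_mm:.2f} mm")
# Both should read close to the true 2.2 mm: the collar is removed and the
# contrast signal behind it retained.
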