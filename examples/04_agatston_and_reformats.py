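"""Agatston calcium scoring and image reformats (MIP, curved planar).

The Agatston score sums, over slices, lesion area times an HU-band weight
(1-4 for peaks in [130,200)/[200,300)/[300,400)/>=400), scaled to the 3 mm
slice thickness the score is defined on.
"""

import numpy as np

import calcisub as cs
from calcisub.quantify import Centerline

spec = cs.default_phantom_spec()
pre, _ = cs.rasterize(spec, "pre", raster_mm=0.15)
cond = cs.ReconstructionCondition(100.0, 512, "bone")
pre_rc = cs.emulate_reconstruction(pre, cond, seed=4)

score = cs.agatston_score(pre_rc)
print(f"Agatston score of the calcified collar: {score.total:.0f} "
      f"({len(score.lesions)} slice-lesions, peak weight "
      f"{max(l.weight for l in score.lesions)})")

mip = cs.mip_projection(pre_rc, axis=1)
print(f"MIP along rows: {mip.shape} image, max {mip.max():.0f} HU")

cl = Centerline(spec.tubes[1].point_at(np.linspace(2.0, 22.0, 21)))
cpr = cs.curved_planar_reformat(pre_rc, cl, plane_half_width_mm=3.0, step_mm=0.25)
print(f"CPR: {cpr.longitudinal.shape} longitudinal image, "
      f"{cpr.cross_sections.shape[0]} cross-sections, truncated={cpr.truncated}")
# the calcified collar shows as a bright band in the CPR of tube 1
band = cpr.longitudinal.max(axis=1)
print(f"collar spans stations {np.flatnonzero(band > 500).min()}-"
      f"{np.flatnonzero(band > 500).max()} of {len(band)}")
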