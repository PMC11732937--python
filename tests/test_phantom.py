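"""Phantom rasterization, reconstruction emulation and misalignment."""

from __future__ import annotations

import numpy as np
import pytest

import calcisub as cs
from calcisub.phantom import ResolutionError


class TestDefaultSpec:
    def test_matches_physical_phantom(self, default_spec):
        assert len(default_spec.tubes) == 2
        assert default_spec.tubes[0].inner_diameter_mm == 2.2
        assert default_spec.tubes[1].inner_diameter_mm == 2.2
        assert default_spec.lumen_hu_pre == 0.0  # saline ~ water
        assert default_spec.lumen_hu_post == 450.0
        assert default_spec.background_hu == 0.0
        assert len(default_spec.calcifications) == 1
        assert default_spec.calcifications[0].hu > 200.0  # above the mask threshold

    def test_json_round_trip(self, default_spec):
        back = cs.PhantomSpec.from_json(default_spec.to_json())
        assert back.to_json() == default_spec.to_json()

    def test_validation(self):
        with pytest.raises(ValueError):
            cs.Tube(centerline=[[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            cs.Stenosis(tube=0, axial_range_mm=(0, 1), residual_lumen_fraction=1.5)


class TestRasterize:
    def test_lumen_voxel_exact_hu(self, phantom_pair):
        _, post, _ = phantom_pair
        spec = cs.default_phantom_spec()
        center = spec.tubes[0].point_at(6.0)
        idx = np.round(post.world_to_index(center)).astype(int)
        assert post.voxels[tuple(idx)] == pytest.approx(450.0, abs=1e-4)

    def test_no_tubes_uniform_background(self):
        spec = cs.PhantomSpec(tubes=(), calcifications=(), stenoses=(),
                              background_hu=12.0, extent_mm=(4, 4, 4))
        vol, _ = cs.rasterize(spec, "pre", 0.2)
        assert np.allclose(vol.voxels, 12.0)

    def test_lumen_area_matches_analytic_circle(self):
        # wall-less tube: every voxel HU is 450 x (lumen fraction), so the
        # integrated HU over a slice divided by 450 is the lumen area
        spec = cs.PhantomSpec(
            tubes=(cs.Tube([[0, 0, 0], [2, 0, 0]], wall_thickness_mm=0.0),),
            extent_mm=(2.0, 6.0, 6.0),
        )
        vol, _ = cs.rasterize(spec, "post", 0.05)
        mid = vol.voxels[vol.shape[0] // 2].astype(np.float64)
        area = mid.sum() / 450.0 * 0.05**2
        assert area == pytest.approx(np.pi * 1.1**2, rel=0.02)

    def test_partial_volume_converges_with_resolution(self):
        spec = cs.PhantomSpec(
            tubes=(cs.Tube([[0, 0, 0], [1.6, 0, 0]]),), extent_mm=(1.6, 6.0, 6.0)
        )
        errs = []
        for raster in (0.2, 0.1, 0.05):
            vol, _ = cs.rasterize(spec, "post", raster)
            r = np.hypot(
                *np.meshgrid(
                    *(np.arange(s) * raster - e / 2 + raster / 2
                      for s, e in zip(vol.shape[1:], spec.extent_mm[1:])),
                    indexing="ij",
                )
            )
            lumen = vol.voxels[vol.shape[0] // 2][r < 1.1 - raster]
            errs.append(abs(lumen.mean() - 450.0))
        assert errs[0] >= errs[-1]
        assert errs[-1] < 1.0

    def test_too_coarse_raster_rejected(self, default_spec):
        with pytest.raises(ResolutionError):
            cs.rasterize(default_spec, "pre", 0.5)

    def test_ground_truth_consistent(self, phantom_pair):
        pre, _, gt = phantom_pair
        spec = cs.default_phantom_spec()
        assert np.allclose(gt.true_diameter_mm[0], 2.2)
        assert all(p == "patent" for p in gt.patency[0])
        # calcium mask sits on tube 1 only, within the collar's axial range
        zs = np.where(gt.calcium_mask.voxels.any(axis=(1, 2)))[0]
        z_mm = (zs + 0.5) * 0.1
        lo, hi = spec.calcifications[0].axial_range_mm
        assert z_mm.min() >= lo - 0.2 and z_mm.max() <= hi + 0.2

    def test_stenosis_and_occlusion_rendered(self):
        spec = cs.PhantomSpec(
            tubes=(cs.Tube([[0, 0, 0], [12, 0, 0]]),),
            stenoses=(
                cs.Stenosis(0, (4.0, 6.0), 0.25),
                cs.Stenosis(0, (8.0, 10.0), 0.0),
            ),
            extent_mm=(12, 6, 6),
        )
        vol, gt = cs.rasterize(spec, "post", 0.1)
        c = vol.world_to_index([0, 0, 0])[1:]
        patent = vol.voxels[int(2 / 0.1), int(c[0]), int(c[1])]
        sten = vol.voxels[int(5 / 0.1), int(c[0]), int(c[1])]
        occl = vol.voxels[int(9 / 0.1), int(c[0]), int(c[1])]
        assert patent == pytest.approx(450, abs=1)
        assert sten == pytest.approx(450, abs=1)  # residual lumen still contrasted
        assert occl == pytest.approx(80, abs=1)  # plug at wall HU
        labels = {s: lab for s, lab in zip(gt.arc_lengths[0], gt.patency[0])}
        assert labels[min(labels, key=lambda s: abs(s - 2))] == "patent"
        assert labels[min(labels, key=lambda s: abs(s - 5))] == "stenotic"
        assert labels[min(labels, key=lambda s: abs(s - 9))] == "occluded"


class TestCurvedRasterization:
    def test_quarter_circle_tube_renders(self):
        theta = np.linspace(0, np.pi / 2, 25)
        r = 5.0
        pts = np.stack([2.5 + r * np.sin(theta), np.zeros_like(theta),
                        2.0 - r * np.cos(theta)], axis=-1)
        spec = cs.PhantomSpec(
            tubes=(cs.Tube(pts, wall_thickness_mm=0.6),), extent_mm=(10, 4, 10)
        )
        vol, gt = cs.rasterize(spec, "post", 0.15, supersample=3)
        # centerline voxels are pure lumen
        mids = gt.centerlines[0][5:-5:10]
        for p in mids:
            idx = np.round(vol.world_to_index(p)).astype(int)
            assert vol.voxels[tuple(idx)] == pytest.approx(450, abs=2)


class TestEmulateReconstruction:
    def test_fov_sets_pixel_spacing(self, phantom_pair):
        pre, _, _ = phantom_pair
        cond = cs.ReconstructionCondition(100.0, 512, "bone")
        out = cs.emulate_reconstruction(pre, cond, 0)
        assert out.spacing[1] == pytest.approx(100.0 / 512)  # 0.1953125 mm
        assert out.spacing[0] == pytest.approx(0.625)

    def test_same_seed_bit_identical(self, phantom_pair):
        pre, _, _ = phantom_pair
        cond = cs.ReconstructionCondition(120.0, 512, "soft_tissue")
        a = cs.emulate_reconstruction(pre, cond, 7)
        b = cs.emulate_reconstruction(pre, cond, 7)
        assert np.array_equal(a.voxels, b.voxels)
        c = cs.emulate_reconstruction(pre, cond, 8)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_degenerate_blur_equals_area_average(self):
        rngv = np.random.default_rng(3)
        v = cs.Volume(rngv.normal(0, 50, (8, 8, 8)), spacing=(0.5, 0.5, 0.5))
        cond = cs.ReconstructionCondition(
            fov_mm=512.0, matrix=512, kernel="bone", slice_thickness_mm=1.0,
            noise_sd_hu=0.0, psf_fwhm_mm=0.0,
        )
        out = cs.emulate_reconstruction(v, cond, 0)
        # target cells are exactly 2x2x2 input cells -> plain block means
        expect = v.voxels.reshape(4, 2, 4, 2, 4, 2).mean(axis=(1, 3, 5))
        assert np.allclose(out.voxels, expect, atol=1e-6)

    def test_target_finer_than_input_rejected(self):
        v = cs.Volume(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ResolutionError):
            cs.emulate_reconstruction(
                v, cs.ReconstructionCondition(100.0, 512, "bone"), 0
            )

    def test_mean_preserved_without_noise(self, phantom_pair):
        pre, _, _ = phantom_pair
        cond = cs.ReconstructionCondition(100.0, 512, "bone", noise_sd_hu=0.0)
        out = cs.emulate_reconstruction(pre, cond, 0)
        # blur + area averaging conserve the integral away from edges
        assert out.voxels.mean() == pytest.approx(pre.voxels.mean(), abs=1.0)


class TestMisalign:
    def test_identity_transform_is_noop(self, phantom_pair):
        pre, _, _ = phantom_pair
        t = cs.RigidTransform.identity()
        out = cs.misalign(pre, t)
        assert np.allclose(out.voxels, pre.voxels, atol=1e-3)

    def test_translation_shifts_content(self, phantom_pair):
        pre, _, _ = phantom_pair
        t = cs.RigidTransform(np.eye(3), translation=(0.0, 1.0, 0.0), center=(0, 0, 0))
        out = cs.misalign(pre, t)
        # content at x in output came from x + 1 mm along row axis:
        # ground-truth tube center appears shifted by -1 mm
        spec = cs.default_phantom_spec()
        c = spec.tubes[0].point_at(6.0)
        shifted = c - np.array([0, 1.0, 0])
        idx = np.round(out.world_to_index(shifted)).astype(int)
        assert out.voxels[tuple(idx)] == pytest.approx(0.0, abs=1e-3)  # pre lumen
        idx_wall = np.round(
            out.world_to_index(shifted + [0, 0, spec.tubes[0].lumen_radius_mm + 0.4])
        ).astype(int)
        assert out.voxels[tuple(idx_wall)] == pytest.approx(80.0, abs=5)

    def test_seeded_random_transform_reproducible(self, phantom_pair):
        pre, _, _ = phantom_pair
        a = cs.misalign(pre, seed=5)
        b = cs.misalign(pre, seed=5)
        assert np.array_equal(a.voxels, b.voxels)
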