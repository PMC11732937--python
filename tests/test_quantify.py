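"""Profile curves, FWHM diameters, Agatston scoring and reformats."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import calcisub as cs
from calcisub.quantify import Centerline, GeometryError, ProfileCurve


def _profile(values, step=0.1):
    return ProfileCurve(np.arange(len(values)) * step, np.asarray(values, float))


def _rect_profile(width_mm, height, step=0.01, pad_mm=2.0):
    n_pad = int(pad_mm / step)
    n_in = int(width_mm / step)
    vals = np.concatenate([np.zeros(n_pad), np.full(n_in, height), np.zeros(n_pad)])
    return _profile(vals, step)


class TestProfileCurve:
    def test_constant_volume_flat_profile(self):
        v = cs.Volume(np.full((8, 8, 8), 450.0), spacing=(1, 1, 1))
        p = cs.profile_curve(v, [2, 2, 1], [2, 2, 6])
        assert np.allclose(p.values, 450.0)

    def test_linear_ramp_sampled_exactly(self):
        shape = (4, 4, 40)
        ramp = np.broadcast_to(np.arange(shape[2]) * 2.5, shape).copy()
        v = cs.Volume(ramp, spacing=(1, 1, 0.5))
        a, b = np.array([2, 2, 3.0]), np.array([2, 2, 15.0])
        p = cs.profile_curve(v, a, b, step_mm=0.05)
        # HU = 5 * world_mm along axis 2 (spacing 0.5, step 2.5/index)
        expect = 5.0 * (3.0 + p.positions)
        assert np.allclose(p.values, expect, rtol=1e-6)

    def test_length_covers_segment(self):
        v = cs.Volume(np.zeros((8, 8, 8)), spacing=(1, 1, 1))
        p = cs.profile_curve(v, [4, 4, 1], [4, 4, 6], step_mm=0.1)
        assert abs(p.positions[-1] - 5.0) <= 0.1

    def test_outside_volume_rejected(self):
        v = cs.Volume(np.zeros((8, 8, 8)), spacing=(1, 1, 1))
        with pytest.raises(GeometryError):
            cs.profile_curve(v, [4, 4, 0], [4, 4, 20])


class TestFwhmDiameter:
    def test_rectangle_width_exact(self):
        p = _rect_profile(2.2, 450.0)
        assert cs.fwhm_diameter(p) == pytest.approx(2.2, abs=0.011)

    def test_gaussian_fwhm(self):
        sigma = 0.8
        step = sigma / 10
        x = np.arange(0, 12 * sigma, step)
        p = _profile(np.exp(-((x - x.mean()) ** 2) / (2 * sigma**2)) * 450.0, step)
        assert cs.fwhm_diameter(p) == pytest.approx(2.355 * sigma, rel=0.01)

    def test_all_negative_profile_is_no_lumen(self):
        p = _profile(np.full(50, -100.0))
        assert cs.fwhm_diameter(p) is None

    def test_min_peak_requirement(self):
        p = _rect_profile(2.0, 80.0)
        assert cs.fwhm_diameter(p) == pytest.approx(2.0, abs=0.011)
        assert cs.fwhm_diameter(p, min_peak_hu=150.0) is None

    def test_multiple_regions_measures_global_peak(self):
        step = 0.1
        vals = np.zeros(120)
        vals[10:20] = 300.0  # secondary peak above the 225 HU half level
        vals[60:90] = 450.0
        with pytest.warns(UserWarning, match="disjoint"):
            w = cs.fwhm_diameter(_profile(vals, step))
        assert w == pytest.approx(3.0, abs=0.15)

    @settings(deadline=None, derandomize=True)
    @given(
        shift_steps=st.integers(min_value=0, max_value=40),
        scale=st.floats(min_value=0.1, max_value=20.0),
    )
    def test_translation_and_rescale_invariance(self, shift_steps, scale):
        """FWHM is invariant to position along the profile and to positive
        rescaling of the peak (the half level is relative)."""
        step = 0.05
        base = np.zeros(200)
        base[80:124] = 450.0
        w0 = cs.fwhm_diameter(_profile(base, step))
        shifted = np.roll(base, shift_steps)
        assert cs.fwhm_diameter(_profile(shifted, step)) == pytest.approx(w0, abs=1e-9)
        assert cs.fwhm_diameter(_profile(base * scale, step)) == pytest.approx(w0, abs=1e-9)


class TestMeasureLumen:
    def test_recovers_true_diameter_on_clean_raster(self):
        # noiseless, unblurred tube: mean within 2% of 2.2 mm
        spec = cs.PhantomSpec(
            tubes=(cs.Tube([[0, 0, 0], [6, 0, 0]], wall_thickness_mm=0.0),),
            extent_mm=(6.0, 6.0, 6.0),
        )
        vol, _ = cs.rasterize(spec, "post", 0.1)
        m = cs.measure_lumen(vol, [3.0, 0.0, 0.0], [0, 1, 0], half_length_mm=2.5)
        assert m.mean_mm == pytest.approx(2.2, rel=0.02)
        assert m.n_missing == 0

    def test_identical_slices_zero_sd(self):
        vals = np.zeros((8, 40, 40), np.float32)
        vals[:, 15:25, 15:25] = 450.0
        v = cs.Volume(vals, spacing=(1.0, 0.25, 0.25), origin=(0, -5, -5))
        m = cs.measure_lumen(v, [4.0, 0.0, 0.0], [0, 1, 0], half_length_mm=4.0)
        assert m.sd_mm == 0.0


class TestAgatston:
    def test_all_below_threshold_scores_zero(self):
        v = cs.Volume(np.full((4, 16, 16), 100.0), spacing=(3.0, 0.5, 0.5))
        assert cs.agatston_score(v).total == 0.0

    def test_hand_computed_single_lesion(self):
        # one 3 mm slice, one 4 mm^2 lesion peaking at 450 HU: weight 4 -> 16
        vals = np.zeros((1, 16, 16), np.float32)
        vals[0, 4:8, 4:8] = 200.0  # 16 px * 0.5*0.5 mm^2 = 4 mm^2
        vals[0, 5, 5] = 450.0
        v = cs.Volume(vals, spacing=(3.0, 0.5, 0.5))
        res = cs.agatston_score(v)
        assert len(res.lesions) == 1
        assert res.lesions[0].weight == 4
        assert res.total == pytest.approx(16.0)

    def test_small_lesion_excluded(self):
        vals = np.zeros((1, 16, 16), np.float32)
        vals[0, 4, 4:6] = 400.0  # 2 px = 0.5 mm^2 < 1 mm^2 floor
        v = cs.Volume(vals, spacing=(3.0, 0.5, 0.5))
        assert cs.agatston_score(v).total == 0.0

    @pytest.mark.parametrize(
        "peak,weight", [(150.0, 1), (250.0, 2), (350.0, 3), (450.0, 4)]
    )
    def test_weight_bands(self, peak, weight):
        vals = np.zeros((1, 16, 16), np.float32)
        vals[0, 4:8, 4:8] = 131.0
        vals[0, 5, 5] = peak
        v = cs.Volume(vals, spacing=(3.0, 0.5, 0.5))
        assert cs.agatston_score(v).lesions[0].weight == weight

    def test_additive_over_slice_partitions(self, rng):
        vals = rng.uniform(0, 500, (6, 12, 12)).astype(np.float32)
        v = cs.Volume(vals, spacing=(3.0, 0.7, 0.7))
        total = cs.agatston_score(v).total
        parts = sum(
            cs.agatston_score(cs.Volume(vals[i : i + 1], spacing=v.spacing)).total
            for i in range(6)
        )
        assert total == pytest.approx(parts)


class TestMip:
    def test_constant_and_single_voxel(self):
        v = cs.Volume(np.full((4, 4, 4), 7.0), spacing=(1, 1, 1))
        assert np.allclose(cs.mip_projection(v, 0), 7.0)
        arr = np.zeros((5, 6, 7), np.float32)
        arr[2, 3, 4] = 999.0
        v2 = cs.Volume(arr, spacing=(1, 1, 1))
        img = cs.mip_projection(v2, 0)
        assert img[3, 4] == 999.0
        assert img.sum() == 999.0

    def test_matches_brute_force(self, rng):
        arr = rng.normal(0, 100, (8, 8, 8)).astype(np.float32)
        v = cs.Volume(arr, spacing=(1, 1, 1))
        for axis in range(3):
            img = cs.mip_projection(v, axis)
            oracle = np.empty(img.shape, np.float32)
            for i in range(img.shape[0]):
                for j in range(img.shape[1]):
                    rays = {0: arr[:, i, j], 1: arr[i, :, j], 2: arr[i, j, :]}
                    oracle[i, j] = max(rays[axis])
            assert np.array_equal(img, oracle)

    def test_idempotent(self, rng):
        arr = rng.normal(0, 100, (6, 6, 6)).astype(np.float32)
        v = cs.Volume(arr, spacing=(1, 1, 1))
        img = cs.mip_projection(v, 0)
        again = cs.mip_projection(
            cs.Volume(img[None, ...], spacing=(1, 1, 1)), 0
        )
        assert np.array_equal(img, again)


class TestCpr:
    def test_constant_volume_constant_cpr(self):
        v = cs.Volume(np.full((20, 20, 20), 55.0), spacing=(1, 1, 1))
        c = Centerline([[5, 10, 10], [15, 10, 10]])
        res = cs.curved_planar_reformat(v, c, plane_half_width_mm=3.0, step_mm=0.5)
        assert np.allclose(res.longitudinal, 55.0)

    def test_straight_centerline_equals_direct_slicing(self):
        rngv = np.random.default_rng(2)
        arr = rngv.normal(0, 100, (24, 24, 24)).astype(np.float64)
        from scipy.ndimage import gaussian_filter

        arr = gaussian_filter(arr, 2.0)  # smooth so interpolation is benign
        v = cs.Volume(arr, spacing=(1, 1, 1))
        c = Centerline([[6.0, 12.0, 12.0], [18.0, 12.0, 12.0]])
        res = cs.curved_planar_reformat(v, c, plane_half_width_mm=4.0, step_mm=1.0)
        # oracle: direct trilinear sampling of the same world points — for a
        # straight axis-aligned centerline the CPR plane is an orthogonal slice
        from scipy.ndimage import map_coordinates

        for si, s in enumerate(res.stations_mm):
            u_axis = res.frames[si, 1]
            assert abs(u_axis @ [1, 0, 0]) < 1e-9  # orthogonal to the tangent
            pts = np.array(
                [[6.0 + s, 12.0, 12.0] + a * u_axis for a in res.lateral_mm]
            )
            idx = v.world_to_index(pts)
            oracle = map_coordinates(arr, idx.T, order=1)
            got = res.cross_sections[si, :, len(res.lateral_mm) // 2]
            assert np.allclose(got, oracle, atol=1e-6)

    def test_curved_tube_straightens_to_constant_width(self):
        theta = np.linspace(0, np.pi / 2, 25)
        r = 5.0
        pts = np.stack([2.5 + r * np.sin(theta), np.zeros_like(theta),
                        2.0 - r * np.cos(theta)], axis=-1)
        spec = cs.PhantomSpec(
            tubes=(cs.Tube(pts, wall_thickness_mm=0.6),), extent_mm=(10, 4, 10)
        )
        vol, _ = cs.rasterize(spec, "post", 0.15, supersample=3)
        cl = Centerline(pts[3:-3])
        res = cs.curved_planar_reformat(vol, cl, plane_half_width_mm=1.8, step_mm=0.1)
        widths = []
        for si in range(0, len(res.stations_mm), 5):
            row = res.cross_sections[si, :, len(res.lateral_mm) // 2]
            prof = ProfileCurve(
                np.arange(len(row)) * 0.1, row
            )
            w = cs.fwhm_diameter(prof)
            assert w is not None
            widths.append(w)
        widths = np.array(widths)
        assert np.allclose(widths, 2.2, atol=0.2)
        assert widths.std() < 0.08

    def test_leaving_volume_warns_and_truncates(self):
        v = cs.Volume(np.zeros((10, 10, 10)), spacing=(1, 1, 1))
        c = Centerline([[5, 5, 5], [5, 5, 30]])
        with pytest.warns(UserWarning, match="truncated"):
            res = cs.curved_planar_reformat(v, c, plane_half_width_mm=2.0, step_mm=1.0)
        assert res.truncated
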