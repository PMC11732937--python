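"""Digital vessel phantom: synthetic precontrast/postcontrast pairs with ground truth.

The phantom emulates a physical test object built from two infusion tubes of
2.2 mm inner diameter embedded in gelatin (~0 HU), one of them carrying a
high-attenuation calcified collar. The lumen holds saline (~0 HU) in the
precontrast phase and oil-based contrast adjusted to ~450 HU in the
postcontrast phase. Rasterization is partial-volume aware: every voxel's HU
is the supersampled mixture of the materials it spans, which is exactly the
mechanism that produces blooming once the volume is band-limited by a
reconstruction kernel.

Reconstruction emulation is image-domain: an in-plane Gaussian point-spread
function whose FWHM depends on the kernel (sharp "bone" vs smooth
"soft-tissue"), area-averaged downsampling to the FOV-determined pixel grid
and the chosen slice thickness, then i.i.d. Gaussian noise. No
projection-domain effects (beam hardening, scatter) are modelled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .registration import RigidTransform, apply_transform
from .volume import Volume

__all__ = [
    "Tube",
    "Calcification",
    "Stenosis",
    "PhantomSpec",
    "ReconstructionCondition",
    "PhantomGroundTruth",
    "ResolutionError",
    "default_phantom_spec",
    "standard_conditions",
    "rasterize",
    "emulate_reconstruction",
    "misalign",
    "random_rigid_transform",
    "KERNEL_PSF_FWHM_MM",
]

KERNEL_PSF_FWHM_MM = {"soft_tissue": 1.2, "bone": 0.6}
"""Default in-plane PSF full width at half maximum per reconstruction kernel.

These widths are a modelling choice, not scanner measurements: they are set
so that the bone kernel clearly out-resolves the soft-tissue kernel, which
is the property that drives blooming differences between conditions.
"""

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


class ResolutionError(ValueError):
    """Raised when a grid is too coarse (or too fine) for the requested operation."""


# --------------------------------------------------------------------------- #
# spec types
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class Tube:
    """A simulated vessel: a tubular wall around a contrast-filled lumen.

    ``centerline`` is an (N, 3) polyline of world points (mm); N = 2 gives a
    straight tube. Axial positions (for calcifications and stenoses) are
    arc lengths in mm measured from the first centerline point.
    """

    centerline: np.ndarray
    inner_diameter_mm: float = 2.2
    wall_thickness_mm: float = 0.8
    wall_hu: float = 80.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if len(pts) < 2 or np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-9):
            raise ValueError("centerline needs >= 2 distinct points")
        if self.inner_diameter_mm <= 0 or self.wall_thickness_mm < 0:
            raise ValueError("tube dimensions must be positive")
        object.__setattr__(self, "centerline", pts)

    @property
    def lumen_radius_mm(self) -> float:
        return self.inner_diameter_mm / 2.0

    @property
    def outer_radius_mm(self) -> float:
        return self.lumen_radius_mm + self.wall_thickness_mm

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Centerline point(s) at arc length ``s`` mm (linear interpolation)."""
        arcs = self.arc_lengths
        s = np.asarray(s, dtype=float)
        out = np.stack(
            [np.interp(s, arcs, self.centerline[:, k]) for k in range(3)], axis=-1
        )
        return out


@dataclass(frozen=True)
class Calcification:
    """A calcified collar on the outside of a tube wall.

    ``axial_range_mm`` is the (start, stop) arc-length interval; ``arc_deg``
    the angular coverage (0, 360 = full ring); the collar extends radially
    from the outer wall surface by ``radial_thickness_mm``.
    """

    tube: int
    axial_range_mm: tuple[float, float]
    arc_deg: tuple[float, float] = (0.0, 360.0)
    radial_thickness_mm: float = 1.0
    hu: float = 900.0

    def __post_init__(self) -> None:
        if self.axial_range_mm[1] <= self.axial_range_mm[0]:
            raise ValueError("axial range must be increasing")
        if self.radial_thickness_mm <= 0:
            raise ValueError("radial thickness must be positive")


@dataclass(frozen=True)
class Stenosis:
    """Concentric lumen narrowing: residual lumen *area* fraction in [0, 1].

    0 renders an occlusion; the displaced lumen is replaced by soft-plaque
    material at the tube's wall HU.
    """

    tube: int
    axial_range_mm: tuple[float, float]
    residual_lumen_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_lumen_fraction <= 1.0:
            raise ValueError("residual lumen fraction must lie in [0, 1]")
        if self.axial_range_mm[1] <= self.axial_range_mm[0]:
            raise ValueError("axial range must be increasing")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom geometry + material HU assignment."""

    tubes: tuple[Tube, ...]
    calcifications: tuple[Calcification, ...] = ()
    stenoses: tuple[Stenosis, ...] = ()
    lumen_hu_pre: float = 0.0
    lumen_hu_post: float = 450.0
    background_hu: float = 0.0
    extent_mm: tuple[float, float, float] = (24.0, 10.0, 14.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tubes", tuple(self.tubes))
        object.__setattr__(self, "calcifications", tuple(self.calcifications))
        object.__setattr__(self, "stenoses", tuple(self.stenoses))
        if any(e <= 0 for e in self.extent_mm):
            raise ValueError("extents must be positive")
        for c in self.calcifications:
            if not 0 <= c.tube < len(self.tubes):
                raise ValueError(f"calcification references missing tube {c.tube}")
        for s in self.stenoses:
            if not 0 <= s.tube < len(self.tubes):
                raise ValueError(f"stenosis references missing tube {s.tube}")

    def lumen_hu(self, phase: str) -> float:
        if phase not in ("pre", "post"):
            raise ValueError(f"phase must be 'pre' or 'post', got {phase!r}")
        return self.lumen_hu_pre if phase == "pre" else self.lumen_hu_post

    def min_feature_mm(self) -> float:
        feats = []
        for t in self.tubes:
            feats += [t.inner_diameter_mm]
            if t.wall_thickness_mm > 0:
                feats.append(t.wall_thickness_mm)
        feats += [c.radial_thickness_mm for c in self.calcifications]
        for s in self.stenoses:
            if s.residual_lumen_fraction > 0:
                t = self.tubes[s.tube]
                feats.append(t.inner_diameter_mm * np.sqrt(s.residual_lumen_fraction))
        return min(feats) if feats else min(self.extent_mm)

    def to_json(self) -> str:
        d = asdict(self)
        for t in d["tubes"]:
            t["centerline"] = np.asarray(t["centerline"]).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        return cls(
            tubes=tuple(Tube(**t) for t in d["tubes"]),
            calcifications=tuple(
                Calcification(
                    tube=c["tube"],
                    axial_range_mm=tuple(c["axial_range_mm"]),
                    arc_deg=tuple(c.get("arc_deg", (0.0, 360.0))),
                    radial_thickness_mm=c.get("radial_thickness_mm", 1.0),
                    hu=c.get("hu", 900.0),
                )
                for c in d.get("calcifications", ())
            ),
            stenoses=tuple(
                Stenosis(
                    tube=s["tube"],
                    axial_range_mm=tuple(s["axial_range_mm"]),
                    residual_lumen_fraction=s["residual_lumen_fraction"],
                )
                for s in d.get("stenoses", ())
            ),
            lumen_hu_pre=d.get("lumen_hu_pre", 0.0),
            lumen_hu_post=d.get("lumen_hu_post", 450.0),
            background_hu=d.get("background_hu", 0.0),
            extent_mm=tuple(d.get("extent_mm", (24.0, 10.0, 14.0))),
        )


@dataclass(frozen=True)
class ReconstructionCondition:
    """One FOV x kernel reconstruction setting."""

    fov_mm: float = 100.0
    matrix: int = 512
    kernel: str = "bone"
    slice_thickness_mm: float = 0.625
    noise_sd_hu: float = 10.0
    psf_fwhm_mm: float | None = None  # default resolved from kernel

    def __post_init__(self) -> None:
        if self.fov_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("fov and slice thickness must be positive")
        if self.matrix < 32:
            raise ValueError("matrix must be >= 32")
        if self.noise_sd_hu < 0:
            raise ValueError("noise sd must be >= 0")
        if self.kernel not in KERNEL_PSF_FWHM_MM:
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def pixel_spacing_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def resolved_psf_fwhm_mm(self) -> float:
        return (
            self.psf_fwhm_mm
            if self.psf_fwhm_mm is not None
            else KERNEL_PSF_FWHM_MM[self.kernel]
        )

    @property
    def label(self) -> str:
        return f"FOV {self.fov_mm:g} mm + {self.kernel.replace('_', ' ')} kernel"


def standard_conditions(noise_sd_hu: float = 10.0) -> list[ReconstructionCondition]:
    """The four FOV x kernel conditions, in the conventional reporting order."""
    return [
        ReconstructionCondition(120.0, 512, "soft_tissue", noise_sd_hu=noise_sd_hu),
        ReconstructionCondition(120.0, 512, "bone", noise_sd_hu=noise_sd_hu),
        ReconstructionCondition(100.0, 512, "soft_tissue", noise_sd_hu=noise_sd_hu),
        ReconstructionCondition(100.0, 512, "bone", noise_sd_hu=noise_sd_hu),
    ]


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Validation oracle emitted alongside each rasterized volume.

    Per tube: centerline samples (world mm) at each rendered slice, the true
    inner diameter there (stenoses shrink it by sqrt(area fraction)), and a
    patency label in {patent, stenotic, occluded}. ``calcium_mask`` marks
    voxels whose calcified-material fraction exceeds one half, on the
    rendered grid.
    """

    centerlines: tuple[np.ndarray, ...]
    arc_lengths: tuple[np.ndarray, ...]
    true_diameter_mm: tuple[np.ndarray, ...]
    patency: tuple[np.ndarray, ...]
    calcium_mask: Volume
    calcium_fraction: Volume


# --------------------------------------------------------------------------- #
# default phantom
# --------------------------------------------------------------------------- #
def default_phantom_spec() -> PhantomSpec:
    """Two parallel straight tubes (inner diameter 2.2 mm) in a 0 HU background.

    Tube 0 is plain; tube 1 carries a full-ring calcified collar (900 HU,
    1 mm thick, arc length 13-19 mm). Lumen: 0 HU precontrast (saline),
    450 HU postcontrast. Tubes run along the slice axis, 7 mm apart.
    """
    e0 = 24.0
    tube0 = Tube(centerline=[[0.0, 0.0, -3.5], [e0, 0.0, -3.5]])
    tube1 = Tube(centerline=[[0.0, 0.0, 3.5], [e0, 0.0, 3.5]])
    return PhantomSpec(
        tubes=(tube0, tube1),
        calcifications=(Calcification(tube=1, axial_range_mm=(13.0, 19.0)),),
        extent_mm=(e0, 10.0, 14.0),
    )


# --------------------------------------------------------------------------- #
# rasterization
# --------------------------------------------------------------------------- #
def _phantom_grid(extent_mm, raster_mm: float) -> tuple[tuple[int, int, int], np.ndarray]:
    shape = tuple(max(1, int(round(e / raster_mm))) for e in extent_mm)
    # voxel i spans [i*r, (i+1)*r] along axis 0; in-plane axes are centered on 0
    origin = np.array(
        [
            raster_mm / 2.0,
            -extent_mm[1] / 2.0 + raster_mm / 2.0,
            -extent_mm[2] / 2.0 + raster_mm / 2.0,
        ]
    )
    return shape, origin


def _is_axis_aligned(tube: Tube) -> bool:
    pts = tube.centerline
    return len(pts) == 2 and np.allclose(pts[0][1:], pts[1][1:], atol=1e-9) and pts[1][0] > pts[0][0]


def _tube_config_at(spec: PhantomSpec, ti: int, s: float):
    """(residual area fraction, calcification or None) at arc length s of tube ti."""
    frac = 1.0
    for st in spec.stenoses:
        if st.tube == ti and st.axial_range_mm[0] <= s < st.axial_range_mm[1]:
            frac = min(frac, st.residual_lumen_fraction)
    calc = None
    for c in spec.calcifications:
        if c.tube == ti and c.axial_range_mm[0] <= s < c.axial_range_mm[1]:
            calc = c
    return frac, calc


def _paint_cross_section(
    spec: PhantomSpec,
    phase: str,
    r2_maps: list[np.ndarray],
    theta_maps: list[np.ndarray | None],
    config: tuple,
) -> tuple[np.ndarray, np.ndarray]:
    """HU and calcium-indicator maps at supersampled in-plane resolution."""
    hu = np.full(r2_maps[0].shape, spec.background_hu, dtype=np.float32)
    calc_ind = np.zeros(r2_maps[0].shape, dtype=np.float32)
    lumen_hu = spec.lumen_hu(phase)
    for ti, tube in enumerate(spec.tubes):
        frac, calc = config[ti]
        r2 = r2_maps[ti]
        r_lum = tube.lumen_radius_mm
        r_out = tube.outer_radius_mm
        r_eff = r_lum * np.sqrt(frac)
        # wall + displaced-lumen plug
        ring = (r2 >= r_eff**2) & (r2 < r_out**2)
        hu[ring] = tube.wall_hu
        if r_eff > 0:
            hu[r2 < r_eff**2] = lumen_hu
        if calc is not None:
            shell = (r2 >= r_out**2) & (r2 < (r_out + calc.radial_thickness_mm) ** 2)
            if calc.arc_deg != (0.0, 360.0):
                theta = theta_maps[ti]
                lo, hi = np.deg2rad(calc.arc_deg[0]), np.deg2rad(calc.arc_deg[1])
                ang = np.mod(theta - lo, 2 * np.pi)
                shell &= ang <= (hi - lo)
            hu[shell] = calc.hu
            calc_ind[shell] = 1.0
    return hu, calc_ind


def _block_mean(arr: np.ndarray, ss: int) -> np.ndarray:
    ny, nx = arr.shape[0] // ss, arr.shape[1] // ss
    return arr.reshape(ny, ss, nx, ss).mean(axis=(1, 3))


def _rasterize_axis_aligned(
    spec: PhantomSpec, phase: str, raster_mm: float, ss: int
) -> tuple[np.ndarray, np.ndarray]:
    shape, origin = _phantom_grid(spec.extent_mm, raster_mm)
    nz, ny, nx = shape
    sub = raster_mm / ss
    rows = origin[1] - raster_mm / 2.0 + (np.arange(ny * ss) + 0.5) * sub
    cols = origin[2] - raster_mm / 2.0 + (np.arange(nx * ss) + 0.5) * sub

    r2_maps, theta_maps = [], []
    for tube in spec.tubes:
        cy, cx = tube.centerline[0][1], tube.centerline[0][2]
        dr = rows[:, None] - cy
        dc = cols[None, :] - cx
        r2_maps.append(dr**2 + dc**2)
        theta_maps.append(
            np.arctan2(dc, dr)
            if any(c.tube == len(r2_maps) - 1 and c.arc_deg != (0.0, 360.0)
                   for c in spec.calcifications)
            else None
        )

    starts = [t.centerline[0][0] for t in spec.tubes]
    hu_out = np.empty(shape, dtype=np.float32)
    calc_out = np.empty(shape, dtype=np.float32)
    cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(nz):
        z_layers = i * raster_mm + (np.arange(ss) + 0.5) * sub
        hu_acc = calc_acc = None
        layer_cfgs = [
            tuple(_tube_config_at(spec, ti, z - starts[ti]) for ti in range(len(spec.tubes)))
            for z in z_layers
        ]
        if all(cfg == layer_cfgs[0] for cfg in layer_cfgs):
            layer_cfgs = [layer_cfgs[0]]
        for cfg in layer_cfgs:
            if cfg not in cache:
                hu_ss, calc_ss = _paint_cross_section(spec, phase, r2_maps, theta_maps, cfg)
                cache[cfg] = (_block_mean(hu_ss, ss), _block_mean(calc_ss, ss))
            hu2d, calc2d = cache[cfg]
            hu_acc = hu2d if hu_acc is None else hu_acc + hu2d
            calc_acc = calc2d if calc_acc is None else calc_acc + calc2d
        hu_out[i] = hu_acc / len(layer_cfgs)
        calc_out[i] = calc_acc / len(layer_cfgs)
    return hu_out, calc_out


def _rasterize_generic(
    spec: PhantomSpec, phase: str, raster_mm: float, ss: int
) -> tuple[np.ndarray, np.ndarray]:
    for c in spec.calcifications:
        if c.arc_deg != (0.0, 360.0) and not _is_axis_aligned(spec.tubes[c.tube]):
            raise NotImplementedError("partial-arc calcifications require straight tubes")
    shape, origin = _phantom_grid(spec.extent_mm, raster_mm)
    nz, ny, nx = shape
    sub = raster_mm / ss
    ax0 = origin[0] - raster_mm / 2.0 + (np.arange(nz * ss) + 0.5) * sub
    ax1 = origin[1] - raster_mm / 2.0 + (np.arange(ny * ss) + 0.5) * sub
    ax2 = origin[2] - raster_mm / 2.0 + (np.arange(nx * ss) + 0.5) * sub

    hu_out = np.empty(shape, dtype=np.float32)
    calc_out = np.empty(shape, dtype=np.float32)
    lumen_hu = spec.lumen_hu(phase)
    pts_plane = np.stack(
        np.meshgrid(ax1, ax2, indexing="ij"), axis=-1
    ).reshape(-1, 2)  # (ny*ss*nx*ss, 2)

    for i in range(nz):
        hu_slab = np.full((ss, len(pts_plane)), spec.background_hu, dtype=np.float32)
        calc_slab = np.zeros_like(hu_slab)
        for li in range(ss):
            z = ax0[i * ss + li]
            pts = np.concatenate(
                [np.full((len(pts_plane), 1), z), pts_plane], axis=1
            )
            for ti, tube in enumerate(spec.tubes):
                d2, s_arc = _dist_to_polyline(pts, tube.centerline, tube.arc_lengths)
                r_lum, r_out = tube.lumen_radius_mm, tube.outer_radius_mm
                frac = np.ones(len(pts))
                for st in spec.stenoses:
                    if st.tube == ti:
                        in_rng = (s_arc >= st.axial_range_mm[0]) & (s_arc < st.axial_range_mm[1])
                        frac[in_rng] = np.minimum(frac[in_rng], st.residual_lumen_fraction)
                r_eff2 = (r_lum**2) * frac
                ring = (d2 >= r_eff2) & (d2 < r_out**2)
                hu_slab[li][ring] = tube.wall_hu
                hu_slab[li][d2 < r_eff2] = lumen_hu
                for c in spec.calcifications:
                    if c.tube != ti:
                        continue
                    in_rng = (s_arc >= c.axial_range_mm[0]) & (s_arc < c.axial_range_mm[1])
                    shell = (
                        in_rng
                        & (d2 >= r_out**2)
                        & (d2 < (r_out + c.radial_thickness_mm) ** 2)
                    )
                    hu_slab[li][shell] = c.hu
                    calc_slab[li][shell] = 1.0
        hu3d = hu_slab.reshape(ss, ny, ss, nx, ss)
        calc3d = calc_slab.reshape(ss, ny, ss, nx, ss)
        hu_out[i] = hu3d.mean(axis=(0, 2, 4))
        calc_out[i] = calc3d.mean(axis=(0, 2, 4))
    return hu_out, calc_out


def _dist_to_polyline(pts: np.ndarray, line: np.ndarray, arcs: np.ndarray):
    """Squared distance to polyline and arc length of the closest point."""
    best_d2 = np.full(len(pts), np.inf)
    best_s = np.zeros(len(pts))
    for k in range(len(line) - 1):
        p0, p1 = line[k], line[k + 1]
        v = p1 - p0
        L2 = float(v @ v)
        t = np.clip(((pts - p0) @ v) / L2, 0.0, 1.0)
        diff = pts - (p0 + t[:, None] * v)
        d2 = np.einsum("ij,ij->i", diff, diff)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_s[closer] = arcs[k] + t[closer] * np.sqrt(L2)
    return best_d2, best_s


def rasterize(
    spec: PhantomSpec,
    phase: str,
    raster_mm: float = 0.05,
    supersample: int = 4,
) -> tuple[Volume, PhantomGroundTruth]:
    """Render a phantom phase onto an isotropic high-resolution grid.

    Each voxel's HU is the partial-volume mixture of the materials
    overlapping it, estimated by ``supersample``^3 subsampling (straight
    axis-aligned tubes use an exact-in-z fast path). Returns the volume and
    the matching ground truth.
    """
    spec.lumen_hu(phase)  # validates phase
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    if raster_mm > spec.min_feature_mm() / 4.0 + 1e-12:
        raise ResolutionError(
            f"raster {raster_mm} mm coarser than a quarter of the smallest "
            f"feature ({spec.min_feature_mm():.3g} mm)"
        )
    if not spec.tubes:
        shape, origin = _phantom_grid(spec.extent_mm, raster_mm)
        hu = np.full(shape, spec.background_hu, dtype=np.float32)
        calc = np.zeros(shape, dtype=np.float32)
    elif all(_is_axis_aligned(t) for t in spec.tubes):
        hu, calc = _rasterize_axis_aligned(spec, phase, raster_mm, supersample)
    else:
        hu, calc = _rasterize_generic(spec, phase, raster_mm, supersample)

    shape, origin = _phantom_grid(spec.extent_mm, raster_mm)
    vol = Volume(voxels=hu, spacing=np.full(3, raster_mm), origin=origin)
    gt = _ground_truth(spec, vol, calc, raster_mm)
    return vol, gt


def _ground_truth(
    spec: PhantomSpec, vol: Volume, calc_frac: np.ndarray, raster_mm: float
) -> PhantomGroundTruth:
    centerlines, arclens, diams, patency = [], [], [], []
    nz = vol.shape[0]
    z_centers = (np.arange(nz) + 0.5) * raster_mm
    for ti, tube in enumerate(spec.tubes):
        total = tube.arc_lengths[-1]
        if _is_axis_aligned(tube):
            s = z_centers - tube.centerline[0][0]
            s = s[(s >= 0) & (s <= total)]
        else:
            s = np.arange(0.0, total + 1e-9, raster_mm)
        pts = tube.point_at(s)
        d = np.empty(len(s))
        lab = np.empty(len(s), dtype=object)
        for k, sk in enumerate(s):
            frac, _ = _tube_config_at(spec, ti, float(sk))
            d[k] = tube.inner_diameter_mm * np.sqrt(frac)
            lab[k] = "occluded" if frac == 0 else ("stenotic" if frac < 1 else "patent")
        centerlines.append(pts)
        arclens.append(s)
        diams.append(d)
        patency.append(lab)
    return PhantomGroundTruth(
        centerlines=tuple(centerlines),
        arc_lengths=tuple(arclens),
        true_diameter_mm=tuple(diams),
        patency=tuple(patency),
        calcium_mask=vol.with_voxels((calc_frac > 0.5).astype(np.uint8)),
        calcium_fraction=vol.with_voxels(calc_frac),
    )


# --------------------------------------------------------------------------- #
# reconstruction emulation
# --------------------------------------------------------------------------- #
def _area_average_axis(arr: np.ndarray, axis: int, sp: float, dsp: float) -> np.ndarray:
    """Exact area-averaged resampling along one axis.

    Treats the input as piecewise constant over its cells and integrates it
    over the (generally incommensurate) output cells via a cumulative sum.
    """
    arr = np.moveaxis(arr, axis, 0)
    n = arr.shape[0]
    extent = n * sp
    m = max(1, int(np.floor(extent / dsp + 1e-9)))
    cum = np.concatenate(
        [np.zeros((1,) + arr.shape[1:], dtype=np.float64), np.cumsum(arr, axis=0) * sp]
    )
    edges = np.arange(m + 1) * dsp
    t = edges / sp
    i0 = np.clip(np.floor(t).astype(int), 0, n)
    fr = t - i0
    upper = np.clip(i0 + 1, 0, n)
    f_edges = cum[i0] + fr[(...,) + (None,) * (arr.ndim - 1)] * (cum[upper] - cum[i0])
    out = (f_edges[1:] - f_edges[:-1]) / dsp
    return np.moveaxis(out, 0, axis)


def emulate_reconstruction(
    v: Volume, cond: ReconstructionCondition, seed: int
) -> Volume:
    """Band-limit, downsample and add noise to emulate one reconstruction.

    In-plane pixel spacing is ``fov_mm / matrix``; axial spacing is the slice
    thickness. The kernel's in-plane Gaussian PSF is applied on the input
    grid, the volume is downsampled by area averaging, then i.i.d. Gaussian
    noise of sd ``noise_sd_hu`` is added using ``seed``. Deterministic for a
    fixed seed.
    """
    from scipy.ndimage import gaussian_filter

    dsp = np.array(
        [cond.slice_thickness_mm, cond.pixel_spacing_mm, cond.pixel_spacing_mm]
    )
    if np.any(dsp < v.spacing - 1e-12):
        raise ResolutionError(
            f"target spacing {dsp} mm finer than input {v.spacing} mm"
        )
    sigma_mm = cond.resolved_psf_fwhm_mm * _FWHM_TO_SIGMA
    vox = v.voxels.astype(np.float64)
    if sigma_mm > 0:
        vox = gaussian_filter(
            vox, sigma=[0.0, sigma_mm / v.spacing[1], sigma_mm / v.spacing[2]],
            mode="nearest",
        )
    for ax in range(3):
        vox = _area_average_axis(vox, ax, float(v.spacing[ax]), float(dsp[ax]))

    rng = np.random.default_rng(seed)
    if cond.noise_sd_hu > 0:
        vox = vox + rng.normal(0.0, cond.noise_sd_hu, vox.shape)

    # output voxel centers: cell edges stay anchored at the input field edge
    left = v.index_to_world([0, 0, 0]) - v.orientation @ (v.spacing / 2.0)
    origin = left + v.orientation @ (dsp / 2.0)
    return Volume(
        voxels=vox.astype(np.float32),
        spacing=dsp,
        origin=origin,
        orientation=v.orientation,
    )


# --------------------------------------------------------------------------- #
# misalignment
# --------------------------------------------------------------------------- #
def random_rigid_transform(
    seed: int,
    max_translation_mm: float = 1.5,
    max_rotation_deg: float = 2.0,
    center=(0.0, 0.0, 0.0),
) -> RigidTransform:
    """A small random rigid transform for misalignment experiments."""
    rng = np.random.default_rng(seed)
    trans = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    angles = rng.uniform(-max_rotation_deg, max_rotation_deg, 3)
    return RigidTransform.from_euler_deg(angles, trans, center)


def misalign(
    v: Volume,
    t: RigidTransform | None = None,
    seed: int | None = None,
    fill_hu: float = 0.0,
) -> Volume:
    """Resample ``v`` under a small rigid transform, simulating an inter-scan shift.

    Pass an explicit transform, or a seed to draw a random small one. The
    fill value defaults to the phantom background (0 HU gelatin) so the shift
    does not introduce artificial air rims.
    """
    if t is None:
        if seed is None:
            raise ValueError("provide a transform or a seed")
        center = v.index_to_world((np.array(v.shape) - 1) / 2.0)
        t = random_rigid_transform(seed, center=center)
    return apply_transform(v, t, target=v, fill_hu=fill_hu)
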