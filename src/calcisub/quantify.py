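"""Lumen diameter by profile-curve half-width, Agatston scoring, and reformats.

The diameter measurement mirrors the profile-curve workflow of clinical CT
workstations: CT values are sampled along a straight line through the lumen
center, and the lumen diameter is the full width at half maximum of the
supra-baseline peak, with the baseline fixed at 0 HU. Measurements are
repeated on six consecutive axial slices and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import measure

from .volume import Volume

__all__ = [
    "ProfileCurve",
    "DiameterMeasurement",
    "AgatstonLesion",
    "AgatstonResult",
    "Centerline",
    "CprResult",
    "GeometryError",
    "profile_curve",
    "fwhm_diameter",
    "measure_lumen",
    "agatston_score",
    "mip_projection",
    "curved_planar_reformat",
]


class GeometryError(ValueError):
    """Raised when a requested sample location falls outside the volume."""


# --------------------------------------------------------------------------- #
# profile curves and FWHM
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class ProfileCurve:
    """HU sampled at uniform steps along a directed line; positions start at 0 mm."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if len(pos) < 2 or len(pos) != len(val):
            raise ValueError("profile needs >= 2 matched samples")
        steps = np.diff(pos)
        if pos[0] != 0 or np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("positions must start at 0 and increase uniformly")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    @property
    def step_mm(self) -> float:
        return float(self.positions[1] - self.positions[0])


def profile_curve(
    v: Volume, a: np.ndarray, b: np.ndarray, step_mm: float | None = None
) -> ProfileCurve:
    """Sample HU by trilinear interpolation along the segment from ``a`` to ``b``.

    Default step: a quarter of the smallest in-plane spacing. Both endpoints
    must lie inside the volume.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    length = float(np.linalg.norm(b - a))
    if length < 1e-12:
        raise ValueError("profile endpoints must differ")
    if step_mm is None:
        step_mm = float(min(v.spacing[1], v.spacing[2])) / 4.0
    n = int(np.floor(length / step_mm)) + 1
    pos = np.arange(n) * step_mm
    pts = a + (pos / length)[:, None] * (b - a)
    idx = v.world_to_index(pts)
    upper = np.array(v.shape) - 1
    if np.any(idx < -1e-6) or np.any(idx > upper + 1e-6):
        raise GeometryError("profile endpoints must lie inside the volume")
    vals = map_coordinates(
        v.voxels.astype(np.float64), idx.T, order=1, mode="nearest"
    )
    return ProfileCurve(pos, vals)


def _runs(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label contiguous True runs 1..n (0 elsewhere)."""
    starts = np.diff(np.concatenate([[0], mask.astype(int)])) == 1
    labels = np.cumsum(starts) * mask
    return labels, int(labels.max())


def fwhm_diameter(
    p: ProfileCurve, baseline_hu: float = 0.0, min_peak_hu: float = 0.0
) -> float | None:
    """Full width at half maximum of the supra-baseline peak, in mm.

    The half level sits midway between ``baseline_hu`` and the peak of the
    supra-baseline region containing the global maximum; the two crossings
    bracketing the peak are located by linear interpolation between samples.
    Returns ``None`` when no sample exceeds the baseline ("no lumen") —
    distinguishable from a zero width. ``min_peak_hu`` additionally requires
    the peak to rise that far above baseline before a lumen is accepted
    (e.g. 150 HU rejects soft-plaque or noise bumps when reading contrast
    defects). When several disjoint supra-baseline regions exist, the one
    holding the global peak is measured and a warning is issued.
    """
    vals = p.values
    above = vals > baseline_hu
    if not above.any():
        return None
    if vals.max() < baseline_hu + min_peak_hu:
        return None
    peak_i = int(np.argmax(vals))
    half = baseline_hu + (vals[peak_i] - baseline_hu) / 2.0
    # warn when a *competing* supra-baseline region reaches the half level —
    # noise blips just above baseline are not worth reporting
    labels, n_regions = _runs(above)
    if n_regions > 1:
        peak_lab = labels[peak_i]
        for lab in range(1, n_regions + 1):
            if lab != peak_lab and vals[labels == lab].max() >= half:
                warnings.warn(
                    "multiple disjoint supra-baseline regions reach the half "
                    "level; measuring the one containing the global peak",
                    stacklevel=2,
                )
                break

    def _cross(i_from: int, direction: int) -> float:
        i = i_from
        while 0 <= i + direction < len(vals) and vals[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(vals):
            return float(p.positions[i])  # peak truncated at profile end
        # linear interpolation between samples i (>= half) and j (< half)
        t = (vals[i] - half) / (vals[i] - vals[j])
        return float(p.positions[i] + t * (p.positions[j] - p.positions[i]))

    left = _cross(peak_i, -1)
    right = _cross(peak_i, +1)
    return abs(right - left)


# --------------------------------------------------------------------------- #
# six-slice lumen measurement
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class DiameterMeasurement:
    """Per-slice FWHM diameters and their mean/sd over the measured slices."""

    per_slice_mm: np.ndarray  # NaN where no lumen was found
    mean_mm: float
    sd_mm: float
    n_slices: int
    n_missing: int
    baseline_hu: float

    @property
    def complete(self) -> bool:
        return self.n_missing == 0


def measure_lumen(
    v: Volume,
    center: np.ndarray,
    direction: np.ndarray,
    half_length_mm: float = 3.0,
    n_slices: int = 6,
    baseline_hu: float = 0.0,
    min_peak_hu: float = 0.0,
    step_mm: float | None = None,
) -> DiameterMeasurement:
    """Six-slice mean FWHM lumen diameter.

    For ``n_slices`` consecutive axial slices centered on ``center``, an
    in-plane profile of half-length ``half_length_mm`` is drawn through the
    lumen center along ``direction`` (a world-space vector, projected into
    the slice plane) and its FWHM above ``baseline_hu`` measured. Slices
    with no supra-baseline signal are recorded as missing (NaN) and excluded
    from the mean.
    """
    center = np.asarray(center, dtype=float)
    direction = np.asarray(direction, dtype=float)
    slice_dir = v.orientation[:, 0]
    direction = direction - (direction @ slice_dir) * slice_dir
    nrm = np.linalg.norm(direction)
    if nrm < 1e-12:
        raise ValueError("direction must have an in-plane component")
    direction = direction / nrm

    k_center = v.world_to_index(center)[0]
    k0 = int(np.round(k_center - (n_slices - 1) / 2.0))
    k0 = max(0, min(k0, v.shape[0] - n_slices))
    diams = np.full(n_slices, np.nan)
    for j in range(n_slices):
        k = k0 + j
        offset = (k - k_center) * v.spacing[0]
        c = center + offset * slice_dir
        prof = profile_curve(
            v, c - half_length_mm * direction, c + half_length_mm * direction, step_mm
        )
        w = fwhm_diameter(prof, baseline_hu, min_peak_hu)
        if w is not None:
            diams[j] = w
    ok = np.isfinite(diams)
    if not ok.any():
        mean = sd = float("nan")
    else:
        mean = float(np.mean(diams[ok]))
        sd = float(np.std(diams[ok], ddof=1)) if ok.sum() > 1 else 0.0
    return DiameterMeasurement(
        per_slice_mm=diams,
        mean_mm=mean,
        sd_mm=sd,
        n_slices=n_slices,
        n_missing=int(n_slices - ok.sum()),
        baseline_hu=baseline_hu,
    )


# --------------------------------------------------------------------------- #
# Agatston calcium score
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class AgatstonLesion:
    slice_index: int
    area_mm2: float
    peak_hu: float
    weight: int
    score: float


@dataclass(frozen=True)
class AgatstonResult:
    lesions: tuple[AgatstonLesion, ...]
    total: float


def _agatston_weight(peak_hu: float) -> int:
    if peak_hu >= 400:
        return 4
    if peak_hu >= 300:
        return 3
    if peak_hu >= 200:
        return 2
    return 1


def agatston_score(
    v: Volume,
    threshold_hu: float = 130.0,
    min_area_mm2: float = 1.0,
    reference_thickness_mm: float = 3.0,
) -> AgatstonResult:
    """Agatston calcium score: per-slice lesions of >= 130 HU, area x HU-band weight.

    Lesions are 8-connected in-plane components of voxels at or above
    ``threshold_hu`` with area >= ``min_area_mm2``; the weight is 1/2/3/4 for
    a peak HU in [130,200)/[200,300)/[300,400)/>=400. The score is defined on
    3 mm slices, so each slice's contribution is scaled by
    ``slice_thickness / reference_thickness_mm`` to stay comparable across
    slice thicknesses (a volume-score-style normalization).
    """
    pixel_area = float(v.spacing[1] * v.spacing[2])
    thickness_factor = float(v.spacing[0]) / reference_thickness_mm
    lesions: list[AgatstonLesion] = []
    for k in range(v.shape[0]):
        sl = v.voxels[k]
        binary = sl >= threshold_hu
        if not binary.any():
            continue
        labels = measure.label(binary, connectivity=2)
        for lab in range(1, labels.max() + 1):
            sel = labels == lab
            area = float(sel.sum()) * pixel_area
            if area < min_area_mm2:
                continue
            peak = float(sl[sel].max())
            w = _agatston_weight(peak)
            lesions.append(
                AgatstonLesion(
                    slice_index=k,
                    area_mm2=area,
                    peak_hu=peak,
                    weight=w,
                    score=area * w * thickness_factor,
                )
            )
    return AgatstonResult(tuple(lesions), float(sum(l.score for l in lesions)))


# --------------------------------------------------------------------------- #
# reformats
# --------------------------------------------------------------------------- #
def mip_projection(v: Volume, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection along a grid axis (per-ray maximum HU)."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    return v.voxels.max(axis=axis)


@dataclass(frozen=True)
class Centerline:
    """Ordered world points (mm) with arc-length parameterization."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(pts) < 2:
            raise ValueError("centerline needs >= 2 points")
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-12):
            raise ValueError("consecutive centerline points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def resample(self, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Uniform arc-length samples: (positions s, points)."""
        arcs = self.arc_lengths
        s = np.arange(0.0, arcs[-1] + 1e-9, step_mm)
        pts = np.stack([np.interp(s, arcs, self.points[:, k]) for k in range(3)], axis=-1)
        return s, pts


@dataclass(frozen=True)
class CprResult:
    """Curved planar reformation output.

    ``longitudinal``: (n_stations, n_lateral) image through the centerline;
    ``cross_sections``: (n_stations, n_u, n_w) planes orthogonal to the
    local tangent; ``stations_mm``: arc-length positions; ``frames``:
    (n_stations, 3, 3) rows (tangent, u, w) of the rotation-minimizing frame.
    ``truncated`` flags stations that left the volume.
    """

    longitudinal: np.ndarray
    cross_sections: np.ndarray
    stations_mm: np.ndarray
    frames: np.ndarray
    lateral_mm: np.ndarray
    truncated: bool


def _rotation_minimizing_frames(pts: np.ndarray) -> np.ndarray:
    """Double-reflection rotation-minimizing frames along a polyline."""
    n = len(pts)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    frames = np.empty((n, 3, 3))
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t0 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ t0) * t0
    u /= np.linalg.norm(u)
    frames[0] = [t0, u, np.cross(t0, u)]
    for i in range(n - 1):
        t_i, u_i = frames[i][0], frames[i][1]
        v1 = pts[i + 1] - pts[i]
        c1 = v1 @ v1
        if c1 < 1e-18:
            frames[i + 1] = frames[i]
            continue
        uL = u_i - (2.0 / c1) * (v1 @ u_i) * v1
        tL = t_i - (2.0 / c1) * (v1 @ t_i) * v1
        v2 = tangents[i + 1] - tL
        c2 = v2 @ v2
        u_next = uL if c2 < 1e-18 else uL - (2.0 / c2) * (v2 @ uL) * v2
        t_next = tangents[i + 1]
        u_next = u_next - (u_next @ t_next) * t_next
        u_next /= np.linalg.norm(u_next)
        frames[i + 1] = [t_next, u_next, np.cross(t_next, u_next)]
    return frames


def curved_planar_reformat(
    v: Volume,
    c: Centerline,
    plane_half_width_mm: float = 5.0,
    step_mm: float = 0.25,
    fill_hu: float = -1024.0,
) -> CprResult:
    """Straighten a vessel along its centerline.

    At each arc-length step the plane orthogonal to the local tangent is
    sampled on a rotation-minimizing frame; the longitudinal image stacks
    each cross-section's central row. Stations outside the volume are filled
    with ``fill_hu`` and flagged via ``truncated``.
    """
    s, pts = c.resample(step_mm)
    frames = _rotation_minimizing_frames(pts)
    lateral = np.arange(-plane_half_width_mm, plane_half_width_mm + 1e-9, step_mm)
    n_st, n_lat = len(s), len(lateral)

    # sample points: p + a*u + b*w for all (station, a, b)
    u = frames[:, 1, :]
    w = frames[:, 2, :]
    sample = (
        pts[:, None, None, :]
        + lateral[None, :, None, None] * u[:, None, None, :]
        + lateral[None, None, :, None] * w[:, None, None, :]
    )  # (n_st, n_lat, n_lat, 3)
    idx = v.world_to_index(sample.reshape(-1, 3))
    upper = np.array(v.shape) - 1
    inside = np.all((idx >= -1e-6) & (idx <= upper + 1e-6), axis=1)
    vals = np.full(len(idx), float(fill_hu))
    if inside.any():
        vals[inside] = map_coordinates(
            v.voxels.astype(np.float64), idx[inside].T, order=1, mode="nearest"
        )
    truncated = not bool(inside.all())
    if truncated:
        warnings.warn("centerline plane samples leave the volume; output truncated",
                      stacklevel=2)
    cross = vals.reshape(n_st, n_lat, n_lat)
    mid = n_lat // 2
    return CprResult(
        longitudinal=cross[:, :, mid].copy(),
        cross_sections=cross,
        stations_mm=s,
        frames=frames,
        lateral_mm=lateral,
        truncated=truncated,
    )
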