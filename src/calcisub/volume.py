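"""Volume data model: a 3-D grid of CT attenuation values with physical geometry.

Conventions used throughout the package, asserted at construction time:

* voxel array axis order is ``(slice, row, column)``;
* the world frame is LPS (left, posterior, superior), in millimetres;
* indices are 0-based; voxel ``(0, 0, 0)`` sits at ``origin``;
* ``orientation`` is a 3x3 direction-cosine matrix whose *columns* are the
  world-space unit directions of the slice, row and column axes, so that

  ``world = origin + orientation @ (spacing * index)``.

Voxel values are Hounsfield units (water = 0, air = -1024).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = ["Volume", "AIR_HU", "resample_to_grid"]

AIR_HU = -1024.0
"""Fill value for out-of-field voxels: the CT attenuation of air."""


@dataclass(frozen=True)
class Volume:
    """A 3-D scalar CT volume in HU with physical spacing, origin and orientation.

    Parameters
    ----------
    voxels
        3-D float array indexed ``(slice, row, column)``.
    spacing
        Per-axis voxel size in mm, same axis order as ``voxels``.
    origin
        World (LPS, mm) position of voxel ``(0, 0, 0)``.
    orientation
        3x3 direction-cosine matrix; column ``k`` is the world direction of
        grid axis ``k``. Must be orthonormal with determinant +1.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    orientation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"voxels must be a 3-D grid, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel values must be finite")
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(spacing <= 0):
            raise ValueError(f"spacing must be positive, got {spacing}")
        origin = (
            np.zeros(3) if self.origin is None
            else np.asarray(self.origin, dtype=float).reshape(3)
        )
        orient = (
            np.eye(3) if self.orientation is None
            else np.asarray(self.orientation, dtype=float).reshape(3, 3)
        )
        if not np.allclose(orient.T @ orient, np.eye(3), atol=1e-6):
            raise ValueError("orientation must be orthonormal")
        if np.linalg.det(orient) < 0:
            raise ValueError("orientation must be proper (determinant +1)")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "orientation", orient)

    # ------------------------------------------------------------------ #
    # geometry
    # ------------------------------------------------------------------ #
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) grid indices to world mm (LPS).

        ``index`` may be a single triple or an ``(N, 3)`` array.
        """
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx * self.spacing) @ self.orientation.T

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Map world mm points to continuous grid indices (inverse of above)."""
        pts = np.asarray(world, dtype=float)
        return ((pts - self.origin) @ self.orientation) / self.spacing

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        """True when both volumes share shape, spacing, origin and orientation."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.orientation, other.orientation, atol=atol)
        )

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """New volume with the same geometry and different voxel data."""
        return replace(self, voxels=voxels)

    # ------------------------------------------------------------------ #
    # SimpleITK bridge
    # ------------------------------------------------------------------ #
    def to_sitk(self) -> sitk.Image:
        """Convert to a SimpleITK image.

        SimpleITK indexes (x, y, z) = (column, row, slice), so axis metadata
        is reversed relative to this package's (slice, row, column) order.
        """
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels, dtype=np.float64))
        img.SetSpacing(tuple(self.spacing[::-1]))
        img.SetOrigin(tuple(self.origin))
        # sitk direction columns are the x, y, z axis directions
        img.SetDirection(tuple(self.orientation[:, ::-1].ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
        return cls(
            voxels=sitk.GetArrayFromImage(img).astype(np.float32),
            spacing=np.asarray(img.GetSpacing())[::-1],
            origin=np.asarray(img.GetOrigin()),
            orientation=direction[:, ::-1],
        )


def resample_to_grid(
    v: Volume,
    target: Volume,
    interpolation: str = "linear",
    fill_hu: float = AIR_HU,
) -> Volume:
    """Resample ``v`` onto the grid of ``target``, interpolating in world space.

    Out-of-field voxels take ``fill_hu`` (default -1024 HU, air).
    ``interpolation`` is ``"linear"`` or ``"nearest"``.
    """
    if np.any(np.asarray(target.spacing) <= 0):
        raise ValueError("degenerate target spacing")
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}
    if interpolation not in interp:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    out = sitk.Resample(
        v.to_sitk(),
        target.to_sitk(),
        sitk.Transform(),
        interp[interpolation],
        float(fill_hu),
    )
    res = Volume.from_sitk(out)
    return replace(target, voxels=res.voxels)
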