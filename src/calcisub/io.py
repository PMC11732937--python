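"""Readers and writers for the medical-image formats the pipeline touches.

NIfTI-1 (``.nii`` / ``.nii.gz``) is the native interchange format; DICOM
series directories are read-only inputs. All volumes come back HU-calibrated
(DICOM rescale slope/intercept applied) with slices sorted along the grid's
slice axis. Masks are stored as NIfTI with 0/1 integer voxels.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk

from .volume import Volume

__all__ = ["read_volume", "write_volume", "FormatError"]


class FormatError(ValueError):
    """Raised when an input file violates the expectations of its format."""


def _canonicalize(v: Volume) -> Volume:
    # Enforce the proper-rotation invariant by flipping the slice axis when a
    # file's geometry maps to a left-handed (slice, row, column) frame.
    if np.linalg.det(v.orientation) > 0:
        return v
    n = v.shape[0]
    orientation = v.orientation.copy()
    origin = v.index_to_world([n - 1, 0, 0])
    orientation[:, 0] *= -1
    return Volume(
        voxels=np.ascontiguousarray(v.voxels[::-1]),
        spacing=v.spacing,
        origin=origin,
        orientation=orientation,
    )


def _read_nifti(path: Path) -> Volume:
    img = sitk.ReadImage(os.fspath(path), sitk.sitkFloat64)
    return _canonicalize(Volume.from_sitk(img))


def _read_dicom_series(path: Path) -> Volume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(os.fspath(f))
        except Exception:  # non-DICOM clutter in the directory
            continue
        if hasattr(ds, "PixelData"):
            datasets.append((f, ds))
    if not datasets:
        raise FormatError(f"no DICOM image files found under {path}")

    ref = datasets[0][1]
    iop = np.asarray(ref.ImageOrientationPatient, dtype=float)
    d_col, d_row = iop[:3], iop[3:]
    d_slice = np.cross(d_row, d_col)  # right-handed in (slice, row, col) order
    in_plane = np.asarray(ref.PixelSpacing, dtype=float)  # (row, col) mm

    slices = []
    for f, ds in datasets:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, float), iop, atol=1e-4):
            raise FormatError(f"slice {f.name} has a different orientation")
        if not np.allclose(np.asarray(ds.PixelSpacing, float), in_plane, rtol=1e-4):
            raise FormatError(f"slice {f.name} has a different in-plane spacing")
        ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float32) * slope + intercept
        slices.append((float(ipp @ d_slice), ipp, hu, f))
    slices.sort(key=lambda s: s[0])

    positions = np.array([s[0] for s in slices])
    if len(slices) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0):
            dup = slices[int(np.argmin(steps)) + 1][3]
            raise FormatError(f"duplicate slice position at {dup.name}")
        if np.any(np.abs(steps - steps.mean()) > 0.01 * steps.mean()):
            bad = slices[int(np.argmax(np.abs(steps - steps.mean()))) + 1][3]
            raise FormatError(
                f"inconsistent slice spacing beyond 1% tolerance at {bad.name}"
            )
        slice_spacing = float(steps.mean())
    else:
        slice_spacing = float(getattr(ref, "SliceThickness", 1.0))

    voxels = np.stack([s[2] for s in slices])
    return Volume(
        voxels=voxels,
        spacing=np.array([slice_spacing, in_plane[0], in_plane[1]]),
        origin=slices[0][1],
        orientation=np.column_stack([d_slice, d_row, d_col]),
    )


def read_volume(path: str | os.PathLike, format: str | None = None) -> Volume:
    """Read a volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"`` or ``"dicom_series"``; when omitted it is
    inferred (directories are DICOM series, files are NIfTI). DICOM stored
    values are converted to HU via rescale slope/intercept, and slices are
    sorted by their position along the stack normal.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        try:
            return _read_nifti(p)
        except RuntimeError as exc:
            raise IOError(f"cannot read NIfTI volume {p}: {exc}") from exc
    if format == "dicom_series":
        return _read_dicom_series(p)
    raise ValueError(f"unknown format {format!r}")


def write_volume(v: Volume, path: str | os.PathLike, format: str = "nifti") -> None:
    """Write ``v`` as NIfTI; geometry (spacing, origin, orientation) is preserved."""
    if format != "nifti":
        raise ValueError(f"unsupported output format {format!r}")
    p = Path(path)
    if p.parent and not p.parent.exists():
        raise IOError(f"destination directory does not exist: {p.parent}")
    try:
        sitk.WriteImage(v.to_sitk(), os.fspath(p))
    except RuntimeError as exc:
        raise IOError(f"cannot write volume to {p}: {exc}") from exc
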