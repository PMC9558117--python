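"""NIfTI (and optionally DICOM) readers/writers for :class:`VolumeGrid`.

NIfTI stores arrays in ``(x, y, z)`` index order; internally we keep
``(z, y, x)``, so volumes are transposed on the way in and out.  Round trips
are bit-exact: the on-disk dtype is the in-memory dtype and no intensity
rescaling is applied.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import MaskVolume, VolumeGrid

__all__ = ["read_volume", "write_volume", "read_mask", "write_json", "read_json"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


class FormatError(ValueError):
    """Raised for unreadable or inconsistent image inputs."""


def write_volume(volume: VolumeGrid, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1, preserving geometry and dtype."""
    path = Path(path)
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data).transpose(2, 1, 0), volume.affine)
    img.header.set_data_dtype(data.dtype)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise FormatError(f"failed to write volume to {path}: {exc}") from exc


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a NIfTI file or a DICOM series directory into a volume.

    DICOM support requires the optional ``pydicom`` dependency; slices are
    sorted by position along the slice normal and must share orientation and
    spacing.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    name = path.name.lower()
    if not name.endswith(_NIFTI_SUFFIXES):
        raise FormatError(f"unsupported image format: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"failed to read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3D volume in {path}, got shape {data.shape}")
    return VolumeGrid(np.ascontiguousarray(data.transpose(2, 1, 0)), np.asarray(img.affine))


def read_mask(path: str | os.PathLike) -> MaskVolume:
    vol = read_volume(path)
    return MaskVolume(vol.data != 0, vol.affine)


def _read_dicom_series(directory: Path) -> VolumeGrid:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "reading DICOM series requires the optional 'pydicom' dependency "
            "(pip install prostseg[dicom])"
        ) from exc

    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM slices in {directory}")

    orientations = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 5)) for s in slices}
    if len(orientations) != 1:
        raise FormatError(f"mixed slice orientations in series {directory}")
    orient = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = orient[:3], orient[3:]
    normal = np.cross(row_dir, col_dir)

    slices.sort(key=lambda s: float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)))
    positions = np.array([np.dot(np.asarray(s.ImagePositionPatient, float), normal) for s in slices])
    if len(positions) > 1:
        steps = np.diff(positions)
        if steps.min() <= 0 or not np.allclose(steps, steps[0], atol=1e-3):
            raise FormatError(f"inconsistent slice spacing in series {directory}")
        slice_step = float(steps[0])
    else:
        slice_step = float(getattr(slices[0], "SliceThickness", 1.0))

    py, px = (float(v) for v in slices[0].PixelSpacing)
    data = np.stack([s.pixel_array for s in slices], axis=0)  # (z, y, x)

    aff = np.eye(4)
    aff[:3, 0] = row_dir * px
    aff[:3, 1] = col_dir * py
    aff[:3, 2] = normal * slice_step
    aff[:3, 3] = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    return VolumeGrid(data, aff)


def write_json(obj, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)
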