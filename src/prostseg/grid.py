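"""Volume containers with geometry metadata.

Arrays are axial stacks indexed ``(z, y, x)`` — slice, row, column — with
slice 0 the most cranial slice, +y posterior, and +x toward the patient's
left.  The affine follows the NIfTI convention: it maps homogeneous voxel
coordinates ordered ``(x, y, z)`` (column, row, slice) to world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "MaskVolume", "affine_from_spacing"]


def affine_from_spacing(
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Axis-aligned affine from ``(z, y, x)`` spacing and world ``(x, y, z)`` origin."""
    sz, sy, sx = spacing
    aff = np.eye(4)
    aff[0, 0] = sx
    aff[1, 1] = sy
    aff[2, 2] = sz
    aff[:3, 3] = origin
    return aff


@dataclass
class VolumeGrid:
    """A 3D scalar image plus its grid-to-world transform.

    Parameters
    ----------
    data:
        Voxel array indexed ``(z, y, x)``.
    affine:
        4x4 matrix mapping voxel indices ordered ``(x, y, z)`` to world mm.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing in mm, ordered ``(z, y, x)``."""
        lens = np.linalg.norm(self.affine[:3, :3], axis=0)  # per (x, y, z) axis
        return (float(lens[2]), float(lens[1]), float(lens[0]))

    @property
    def origin(self) -> tuple[float, float, float]:
        """World coordinates of voxel (0, 0, 0), ordered ``(x, y, z)``."""
        return tuple(float(v) for v in self.affine[:3, 3])  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_from_index(self, zyx: np.ndarray) -> np.ndarray:
        """Map ``(n, 3)`` voxel indices ordered (z, y, x) to world mm points."""
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        xyz = zyx[:, ::-1]
        return xyz @ self.affine[:3, :3].T + self.affine[:3, 3]

    def index_from_world(self, pts: np.ndarray) -> np.ndarray:
        """Map ``(n, 3)`` world mm points to fractional (z, y, x) indices."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        xyz = pts @ inv[:3, :3].T + inv[:3, 3]
        return xyz[:, ::-1]

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """New volume on this grid with different voxel values."""
        return VolumeGrid(np.asarray(data), self.affine.copy())


class MaskVolume(VolumeGrid):
    """Binary label volume sharing a :class:`VolumeGrid` geometry."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask data must be binary")
            self.data = self.data.astype(bool)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def with_data(self, data: np.ndarray) -> "MaskVolume":
        return MaskVolume(np.asarray(data), self.affine.copy())
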