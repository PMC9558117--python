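"""Connected-component extraction for binary lesion masks."""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage

__all__ = ["Component", "extract_components"]


@dataclass(frozen=True)
class Component:
    """One connected component of a binary 3D mask.

    Voxel indices are ``(z, y, x)`` rows; spacing is ``(z, y, x)`` mm.
    """

    indices: np.ndarray  # (n, 3) int
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    label: int = 0

    @property
    def voxel_count(self) -> int:
        return int(self.indices.shape[0])

    @property
    def volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return self.voxel_count * sz * sy * sx

    @property
    def bbox(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        """Inclusive ``((zmin, zmax), (ymin, ymax), (xmin, xmax))``."""
        lo = self.indices.min(axis=0)
        hi = self.indices.max(axis=0)
        return tuple((int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]

    @cached_property
    def slice_areas(self) -> dict[int, int]:
        """Voxel count per axial slice index (only nonzero slices)."""
        zs, counts = np.unique(self.indices[:, 0], return_counts=True)
        return {int(z): int(c) for z, c in zip(zs, counts)}

    def mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[tuple(self.indices.T)] = True
        return out


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"unsupported 3D connectivity: {connectivity}")


def extract_components(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    connectivity: int = 26,
    min_volume_mm3: float = 0.0,
) -> list[Component]:
    """Split a binary mask into connected components above a volume cutoff.

    Components are 26-connected by default and returned in label order;
    those strictly below ``min_volume_mm3`` are discarded.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3D mask")
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    out: list[Component] = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        comp = Component(indices=idx, shape=mask.shape, spacing=tuple(spacing), label=lab)
        if comp.volume_mm3 >= min_volume_mm3:
            out.append(comp)
    return out
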