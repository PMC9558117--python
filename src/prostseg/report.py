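"""Sextant partitioning, lesion measurements, and the structured report.

Conventions: slice index 0 is the most cranial slice, so the first third of
the gland's occupied craniocaudal span is the base, the last third the apex;
+x is the patient's left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .components import Component
from .evaluate import MatchRuleConfig, lesion_sextant_labels
from .grid import MaskVolume, VolumeGrid
from . import io as psio

__all__ = [
    "SEXTANT_LABELS",
    "SextantMap",
    "LesionReport",
    "StructuredReport",
    "partition_sextants",
    "diameters_3d",
    "select_key_image",
    "build_report",
    "save_key_image_png",
]

SEXTANT_LABELS = (
    "right-base", "left-base",
    "right-mid", "left-mid",
    "right-apex", "left-apex",
)


@dataclass
class SextantMap:
    """Six disjoint masks partitioning the gland, keyed by sextant label."""

    masks: dict[str, MaskVolume]

    def __post_init__(self) -> None:
        if set(self.masks) != set(SEXTANT_LABELS):
            raise ValueError(f"expected labels {SEXTANT_LABELS}, got {sorted(self.masks)}")

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data for k, v in self.masks.items()}

    @property
    def voxel_counts(self) -> dict[str, int]:
        return {k: v.voxel_count for k, v in self.masks.items()}

    def union(self) -> np.ndarray:
        out = np.zeros(next(iter(self.masks.values())).shape, dtype=bool)
        for m in self.masks.values():
            out |= m.data
        return out


def partition_sextants(gland: MaskVolume) -> SextantMap:
    """Split the gland into left/right x base/mid/apex sextants.

    Left/right by the sagittal plane through the gland centroid; base/mid/apex
    by dividing the occupied craniocaudal span into three equal-thickness
    slice bands (base = most cranial third).
    """
    data = gland.data
    if not data.any():
        raise ValueError("gland mask is empty")
    zs = np.unique(np.nonzero(data)[0])
    z_lo, z_hi = int(zs.min()), int(zs.max())
    n_slices = z_hi - z_lo + 1
    if n_slices < 3:
        raise ValueError(f"gland spans only {n_slices} slices; need >= 3 to form bands")

    # equal-thickness bands over the occupied span (remainders go caudally)
    b1 = z_lo + int(round(n_slices / 3.0))
    b2 = z_lo + int(round(2.0 * n_slices / 3.0))
    b1 = min(max(b1, z_lo + 1), z_hi - 1)
    b2 = min(max(b2, b1 + 1), z_hi)

    cx = np.nonzero(data)[2].mean()
    zz, _, xx = np.indices(data.shape, sparse=True)
    right = xx < cx  # +x is patient left
    bands = {
        "base": zz < b1,
        "mid": (zz >= b1) & (zz < b2),
        "apex": zz >= b2,
    }
    masks = {}
    for band_name, band in bands.items():
        for side_name, side in (("right", right), ("left", ~right)):
            masks[f"{side_name}-{band_name}"] = gland.with_data(data & band & side)
    smap = SextantMap(masks)
    if (smap.union() != data).any():  # pragma: no cover - partition contract
        raise AssertionError("sextants do not partition the gland")
    return smap


def diameters_3d(mask, spacing: tuple[float, float, float] | None = None) -> dict[str, float]:
    """Axis-aligned extents of a mask's bounding box in mm.

    Returns left-right (``lr``), anterior-posterior (``ap``), craniocaudal
    (``cc``) extents — each ``(index span + 1) * spacing`` — plus the
    greatest of the three.
    """
    if isinstance(mask, MaskVolume):
        spacing = mask.spacing
        data = mask.data
    else:
        if spacing is None:
            raise ValueError("spacing required for plain arrays")
        data = np.asarray(mask).astype(bool)
    if not data.any():
        raise ValueError("cannot measure an empty mask")
    sz, sy, sx = spacing
    idx = np.argwhere(data)
    span = idx.max(axis=0) - idx.min(axis=0)  # (z, y, x)
    cc = (int(span[0]) + 1) * sz
    ap = (int(span[1]) + 1) * sy
    lr = (int(span[2]) + 1) * sx
    return {"lr": lr, "ap": ap, "cc": cc, "greatest": max(lr, ap, cc)}


def select_key_image(adc: VolumeGrid, lesion_mask: np.ndarray) -> tuple[int, np.ndarray]:
    """Pick the axial slice with maximal lesion area; ties go cranially.

    Returns the slice index and an RGB raster of the ADC slice with the
    lesion boundary drawn in red.
    """
    lesion = np.asarray(lesion_mask).astype(bool)
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    areas = lesion.reshape(lesion.shape[0], -1).sum(axis=1)
    z = int(np.argmax(areas))  # argmax returns the first (most cranial) max

    sl = adc.data[z].astype(float)
    lo, hi = float(sl.min()), float(sl.max())
    gray = np.zeros_like(sl) if hi == lo else (sl - lo) / (hi - lo)
    rgb = np.stack([gray, gray, gray], axis=-1)
    boundary = lesion[z] & ~ndimage.binary_erosion(lesion[z])
    rgb[boundary] = (1.0, 0.0, 0.0)
    return z, (rgb * 255).astype(np.uint8)


def save_key_image_png(raster: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(raster).save(str(path))


@dataclass
class LesionReport:
    index: int
    diameters_mm: dict[str, float]
    volume_mm3: float
    sextants: list[str]
    key_slice: int

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "diameters_mm": self.diameters_mm,
            "volume_mm3": self.volume_mm3,
            "sextants": self.sextants,
            "key_slice": self.key_slice,
        }


@dataclass
class StructuredReport:
    patient_id: str
    status: str  # "csPCa" | "non-csPCa"
    gland_diameters_mm: dict[str, float]
    lesions: list[LesionReport] = field(default_factory=list)
    sector_map: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("csPCa", "non-csPCa"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "non-csPCa" and self.lesions:
            raise ValueError("non-csPCa report cannot carry lesions")
        if self.status == "csPCa" and any(not l.sextants for l in self.lesions):
            raise ValueError("every reported lesion needs at least one sextant label")
        if set(self.sector_map) != set(SEXTANT_LABELS):
            raise ValueError("sector map must carry all six sextant labels")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "status": self.status,
            "gland_diameters_mm": self.gland_diameters_mm,
            "lesions": [l.to_dict() for l in self.lesions],
            "sector_map": self.sector_map,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructuredReport":
        return cls(
            patient_id=d["patient_id"],
            status=d["status"],
            gland_diameters_mm=dict(d["gland_diameters_mm"]),
            lesions=[LesionReport(**l) for l in d["lesions"]],
            sector_map=dict(d["sector_map"]),
        )

    def save(self, path: str | Path) -> None:
        psio.write_json(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "StructuredReport":
        return cls.from_dict(psio.read_json(path))


def build_report(
    patient_id: str,
    detections: list[Component],
    gland: MaskVolume,
    adc: VolumeGrid,
    sextant_map: SextantMap | None = None,
    match_cfg: MatchRuleConfig = MatchRuleConfig(),
) -> StructuredReport:
    """Assemble the structured report for one patient's cascade output.

    Sextant assignment reuses the evaluation module's 50% containment rule so
    the report can never disagree with the sextant-level metrics.
    """
    if sextant_map is None:
        sextant_map = partition_sextants(gland)
    arrays = sextant_map.arrays()
    gland_diam = diameters_3d(gland)

    lesions: list[LesionReport] = []
    positive: set[str] = set()
    for i, comp in enumerate(detections):
        labels = sorted(lesion_sextant_labels(comp, arrays, match_cfg))
        if not labels:  # fall back to the sextant holding most of the lesion
            mask = comp.mask()
            overlaps = {k: int((mask & a).sum()) for k, a in arrays.items()}
            labels = [max(overlaps, key=overlaps.get)]
        positive |= set(labels)
        mask = comp.mask()
        z, _ = select_key_image(adc, mask)
        lesions.append(
            LesionReport(
                index=i,
                diameters_mm=diameters_3d(mask, spacing=comp.spacing),
                volume_mm3=comp.volume_mm3,
                sextants=labels,
                key_slice=z,
            )
        )

    return StructuredReport(
        patient_id=patient_id,
        status="csPCa" if lesions else "non-csPCa",
        gland_diameters_mm=gland_diam,
        lesions=lesions,
        sector_map={k: k in positive for k in SEXTANT_LABELS},
    )
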