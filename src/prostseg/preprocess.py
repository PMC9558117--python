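"""Preprocessing chain: rigid header-based resampling, K-means prostate
localization on high-b DWI, 128x128 cropping, [0, 1] normalization, and
train-time augmentation.

Images are interpolated with third-order B-splines; binary masks are
Gaussian-smoothed, linearly resampled, and re-thresholded at 0.5 so they
stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .grid import MaskVolume, VolumeGrid

__all__ = [
    "RegistrationSpec",
    "LocalizerConfig",
    "AugmentConfig",
    "BoundingBox",
    "CropPlacement",
    "LocalizationError",
    "resample_to_grid",
    "localize_prostate",
    "crop_patch",
    "uncrop",
    "normalize_patch",
    "augment",
]


class LocalizationError(RuntimeError):
    """Raised when the coarse prostate localizer cannot find a candidate."""


@dataclass(frozen=True)
class RegistrationSpec:
    """Resampling onto a target grid using header transforms only."""

    target_affine: np.ndarray
    target_shape: tuple[int, int, int]
    image_order: int = 3
    label_sigma: float = 0.5  # voxels, Gaussian label interpolation
    label_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.image_order < 0:
            raise ValueError("interpolation order must be >= 0")
        a = np.asarray(self.target_affine, dtype=float)
        if a.shape != (4, 4) or abs(np.linalg.det(a[:3, :3])) < 1e-12:
            raise ValueError("target affine must be an invertible 4x4 matrix")


@dataclass(frozen=True)
class LocalizerConfig:
    k: int = 2
    max_iter: int = 100
    tol: float = 1e-4
    opening_radius: int = 1
    patch_size: int = 128
    margin_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 clusters")
        if self.patch_size <= 0:
            raise ValueError("patch size must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    mirror_prob: float = 0.5
    rotation_deg: float = 10.0
    noise_amplitude: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_deg < 0 or self.noise_amplitude < 0:
            raise ValueError("rotation and noise bounds must be >= 0")


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive voxel bounds ``(z, y, x)``."""

    zmin: int
    zmax: int
    ymin: int
    ymax: int
    xmin: int
    xmax: int

    @property
    def center_yx(self) -> tuple[float, float]:
        return ((self.ymin + self.ymax) / 2.0, (self.xmin + self.xmax) / 2.0)

    def contains_mask(self, mask: np.ndarray) -> bool:
        idx = np.argwhere(np.asarray(mask).astype(bool))
        if idx.size == 0:
            return True
        lo = idx.min(axis=0)
        hi = idx.max(axis=0)
        return bool(
            self.zmin <= lo[0] and hi[0] <= self.zmax
            and self.ymin <= lo[1] and hi[1] <= self.ymax
            and self.xmin <= lo[2] and hi[2] <= self.xmax
        )


def _index_transform(source: VolumeGrid, spec: RegistrationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/offset mapping target (z, y, x) indices to source indices."""
    m = np.linalg.inv(source.affine) @ np.asarray(spec.target_affine, dtype=float)
    perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    return perm @ m[:3, :3] @ perm, perm @ m[:3, 3]


def resample_to_grid(source: VolumeGrid, spec: RegistrationSpec, is_label: bool = False):
    """Resample a volume onto the target grid via the header transforms.

    Images use B-spline interpolation of ``spec.image_order``; labels are
    smoothed with a Gaussian of ``spec.label_sigma`` voxels, resampled
    linearly, and thresholded, so the output stays binary.
    """
    matrix, offset = _index_transform(source, spec)
    if is_label:
        soft = np.asarray(source.data).astype(np.float32)
        if spec.label_sigma > 0:
            soft = ndimage.gaussian_filter(soft, spec.label_sigma)
        res = ndimage.affine_transform(
            soft, matrix, offset=offset, output_shape=spec.target_shape, order=1, mode="constant"
        )
        out = res >= spec.label_threshold
        cls = MaskVolume
    else:
        out = ndimage.affine_transform(
            np.asarray(source.data, dtype=float), matrix, offset=offset,
            output_shape=spec.target_shape, order=spec.image_order, mode="constant",
        )
        cls = VolumeGrid
    return cls(out, np.asarray(spec.target_affine, dtype=float))


def localize_prostate(
    high_b: VolumeGrid, cfg: LocalizerConfig = LocalizerConfig()
) -> tuple[BoundingBox, MaskVolume]:
    """Coarse prostate localization by intensity K-means on high-b DWI.

    Voxel intensities within the central half of the in-plane field of view
    are clustered; the brightest cluster is cleaned by morphological opening
    and its largest 26-connected component kept.  Returns that component's
    bounding box dilated by the configured margin, plus the coarse mask.
    """
    data = np.asarray(high_b.data, dtype=float)
    if np.ptp(data) == 0:
        raise LocalizationError("cannot localize on a constant volume")

    nz, ny, nx = data.shape
    central = np.zeros_like(data, dtype=bool)
    central[:, ny // 4: ny - ny // 4, nx // 4: nx - nx // 4] = True
    values = data[central].reshape(-1, 1)
    if np.ptp(values) == 0:
        raise LocalizationError("central field of view is constant")

    km = KMeans(n_clusters=cfg.k, n_init=4, max_iter=cfg.max_iter, tol=cfg.tol,
                random_state=cfg.seed)
    labels = km.fit_predict(values)
    bright = int(np.argmax(km.cluster_centers_.ravel()))

    mask = np.zeros_like(data, dtype=bool)
    mask[central] = labels == bright
    if cfg.opening_radius > 0:
        ball = _ball(cfg.opening_radius)
        mask = ndimage.binary_opening(mask, structure=ball)
    if not mask.any():
        raise LocalizationError("no bright cluster survived morphological cleanup")

    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    comp = lab == (int(np.argmax(sizes)) + 1)

    idx = np.argwhere(comp)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    sz, sy, sx = high_b.spacing
    mz, my, mx = (int(np.ceil(cfg.margin_mm / s)) for s in (sz, sy, sx))
    box = BoundingBox(
        zmin=max(int(lo[0]) - mz, 0), zmax=min(int(hi[0]) + mz, nz - 1),
        ymin=max(int(lo[1]) - my, 0), ymax=min(int(hi[1]) + my, ny - 1),
        xmin=max(int(lo[2]) - mx, 0), xmax=min(int(hi[2]) + mx, nx - 1),
    )
    return box, MaskVolume(comp, high_b.affine.copy())


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.indices((2 * r + 1,) * 3) - r
    return zz**2 + yy**2 + xx**2 <= r**2


@dataclass(frozen=True)
class CropPlacement:
    """Where a patch sits in its original volume (for lossless un-cropping)."""

    original_shape: tuple[int, int, int]
    y0: int  # patch row 0 maps to original row y0 (may be negative)
    x0: int
    size: int


def crop_patch(volume: VolumeGrid, box: BoundingBox, size: int = 128):
    """Extract a per-slice ``size x size`` patch centred on the box centroid.

    Out-of-bounds regions are zero-padded; the returned placement allows
    mapping patch-space predictions back to original voxel indices.
    """
    data = np.asarray(volume.data)
    nz, ny, nx = data.shape
    cy, cx = box.center_yx
    y0 = int(round(cy)) - size // 2
    x0 = int(round(cx)) - size // 2

    patch = np.zeros((nz, size, size), dtype=data.dtype)
    ys = slice(max(y0, 0), min(y0 + size, ny))
    xs = slice(max(x0, 0), min(x0 + size, nx))
    pys = slice(ys.start - y0, ys.stop - y0)
    pxs = slice(xs.start - x0, xs.stop - x0)
    if ys.start < ys.stop and xs.start < xs.stop:
        patch[:, pys, pxs] = data[:, ys, xs]

    placement = CropPlacement(original_shape=(nz, ny, nx), y0=y0, x0=x0, size=size)
    return volume.with_data(patch), placement


def uncrop(patch_data: np.ndarray, placement: CropPlacement) -> np.ndarray:
    """Re-insert a patch-space array at its original voxel indices."""
    patch_data = np.asarray(patch_data)
    nz, ny, nx = placement.original_shape
    out = np.zeros((nz, ny, nx), dtype=patch_data.dtype)
    y0, x0, size = placement.y0, placement.x0, placement.size
    ys = slice(max(y0, 0), min(y0 + size, ny))
    xs = slice(max(x0, 0), min(x0 + size, nx))
    if ys.start < ys.stop and xs.start < xs.stop:
        out[:, ys, xs] = patch_data[:, ys.start - y0: ys.stop - y0, xs.start - x0: xs.stop - x0]
    return out


def normalize_patch(patch):
    """Min-max scale voxel values into [0, 1]; constant inputs map to zeros."""
    if isinstance(patch, VolumeGrid):
        return patch.with_data(normalize_patch(patch.data))
    arr = np.asarray(patch, dtype=np.float32)
    lo = float(arr.min())
    hi = float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def augment(
    images: np.ndarray,
    masks: np.ndarray,
    cfg: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | None = None,
    mirror: bool | None = None,
    angle_deg: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one joint geometric augmentation to image and mask stacks.

    ``images`` and ``masks`` are ``(c, h, w)`` stacks sharing geometry.  The
    same mirror and in-plane rotation are applied to both; uniform additive
    noise bounded by ``cfg.noise_amplitude`` goes to the images only, and
    masks stay binary (nearest-neighbour resampling).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks).astype(bool)

    if mirror is None:
        mirror = bool(rng.random() < cfg.mirror_prob)
    if angle_deg is None:
        angle_deg = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)) \
            if cfg.rotation_deg > 0 else 0.0
    if abs(angle_deg) > cfg.rotation_deg:
        raise ValueError("rotation angle exceeds the configured bound")

    if mirror:
        images = images[..., ::-1]
        masks = masks[..., ::-1]
    if angle_deg != 0.0:
        images = ndimage.rotate(images, angle_deg, axes=(-2, -1), reshape=False,
                                order=1, mode="constant")
        masks = ndimage.rotate(masks.astype(np.uint8), angle_deg, axes=(-2, -1),
                               reshape=False, order=0, mode="constant").astype(bool)
    if cfg.noise_amplitude > 0:
        images = images + rng.uniform(-cfg.noise_amplitude, cfg.noise_amplitude,
                                      size=images.shape).astype(np.float32)
    return np.ascontiguousarray(images), np.ascontiguousarray(masks)
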