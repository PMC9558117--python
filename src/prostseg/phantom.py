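"""Synthetic biparametric prostate MRI phantoms with ground-truth masks.

Each case carries T2WI, ADC, and high-b DWI volumes on a shared axial grid,
a superellipsoid gland split into a posterior peripheral-zone shell and a
central gland, and 0-4 hypointense-on-ADC lesions whose multiplicity, zone,
and greatest-dimension distributions are configurable.  A fixed seed makes
the whole cohort reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .grid import MaskVolume, VolumeGrid, affine_from_spacing
from . import io as psio

__all__ = [
    "PhantomConfig",
    "Lesion",
    "PatientCase",
    "generate_patient",
    "sample_cohort",
    "write_cohort",
    "read_cohort",
    "sample_lesion_diameters",
    "render_lesion_mask",
]

#: lesion multiplicity among lesion-bearing patients, (173, 49, 10, 3)/235
_DEFAULT_COUNT_PROBS = (0.0, 173 / 235, 49 / 235, 10 / 235, 3 / 235)


@dataclass(frozen=True)
class PhantomConfig:
    """Generator calibration; defaults mirror the target cohort statistics."""

    shape: tuple[int, int, int] = (16, 128, 128)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (4.0, 0.75, 0.75)  # mm
    gland_semiaxes_mean: tuple[float, float, float] = (16.0, 18.0, 22.0)  # (z, y, x) mm
    gland_semiaxes_sd: tuple[float, float, float] = (1.5, 2.0, 2.0)
    superellipse_power: float = 2.5
    pz_thickness_frac: float = 0.35
    lesion_count_probs: tuple[float, ...] = _DEFAULT_COUNT_PROBS
    lesion_pz_prob: float = 212 / 313
    lesion_dim_mean_cm: float = 1.6
    lesion_dim_sd_cm: float = 0.7
    lesion_dim_min_cm: float = 0.4
    #: fraction of the greatest dimension used for the minor in-plane / z axes
    lesion_axis_fracs: tuple[float, float] = (0.75, 0.6)
    #: tissue intensity means per sequence: background, CG, PZ, lesion
    t2_means: tuple[float, float, float, float] = (90.0, 190.0, 290.0, 120.0)
    adc_means: tuple[float, float, float, float] = (700.0, 1150.0, 1500.0, 550.0)
    highb_means: tuple[float, float, float, float] = (40.0, 150.0, 180.0, 330.0)
    noise_sd: float = 15.0
    lesion_max_retries: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.lesion_count_probs, dtype=float)
        if probs.size != 5 or probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("lesion count probabilities must be 5 non-negative values summing to 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be strictly positive")
        if any(a <= 0 for a in self.gland_semiaxes_mean):
            raise ValueError("gland semi-axes must be strictly positive")
        if not 0.0 < self.pz_thickness_frac < 1.0:
            raise ValueError("pz_thickness_frac must be in (0, 1)")
        if not 0.0 <= self.lesion_pz_prob <= 1.0:
            raise ValueError("lesion_pz_prob must be a probability")
        if self.lesion_dim_min_cm <= 0 or self.lesion_dim_sd_cm <= 0:
            raise ValueError("lesion size parameters must be positive")


@dataclass
class Lesion:
    mask: MaskVolume
    zone: str  # "PZ" | "TZ"
    sampled_diameter_cm: float
    #: greatest in-plane extent and greatest 3D extent of the rendered mask, mm
    inplane_diameter_mm: float
    greatest_diameter_mm: float


@dataclass
class PatientCase:
    """One synthetic patient: registered sequences plus ground-truth masks."""

    patient_id: str
    t2w: VolumeGrid
    adc: VolumeGrid
    highb: VolumeGrid
    gland: MaskVolume
    pz: MaskVolume
    cg: MaskVolume
    lesions: list[Lesion] = field(default_factory=list)

    @property
    def is_positive(self) -> bool:
        return len(self.lesions) > 0

    def lesion_union(self) -> MaskVolume:
        out = np.zeros(self.gland.shape, dtype=bool)
        for l in self.lesions:
            out |= l.mask.data
        return self.gland.with_data(out)

    def validate(self) -> None:
        """Check the zone-partition and containment invariants."""
        if (self.pz.data & self.cg.data).any():
            raise AssertionError("PZ and CG overlap")
        if ((self.pz.data | self.cg.data) != self.gland.data).any():
            raise AssertionError("PZ ∪ CG != gland")
        for l in self.lesions:
            if (l.mask.data & ~self.gland.data).any():
                raise AssertionError("lesion extends outside the gland")


_TRUNCNORM_CACHE: dict[tuple[float, float, float], tuple[float, float]] = {}


def _matched_truncnorm_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Parent (mu, sigma) such that the lower-truncated normal has the
    requested mean and sd (moment matching, so the sampler reproduces the
    configured statistics rather than the parent's)."""
    key = (mean, sd, lower)
    if key not in _TRUNCNORM_CACHE:
        from scipy.optimize import fsolve

        def moments(params):
            mu, log_sigma = params
            sigma = np.exp(log_sigma)
            d = stats.truncnorm((lower - mu) / sigma, np.inf, loc=mu, scale=sigma)
            return [d.mean() - mean, d.std() - sd]

        sol, _info, ier, _msg = fsolve(moments, [mean, np.log(sd)], full_output=True)
        if ier == 1:
            _TRUNCNORM_CACHE[key] = (float(sol[0]), float(np.exp(sol[1])))
        else:
            # infeasible target moments (e.g. sd too large for the truncation
            # point); fall back to the naive parent parameters
            _TRUNCNORM_CACHE[key] = (mean, sd)
    return _TRUNCNORM_CACHE[key]


def _truncnorm(cfg: PhantomConfig) -> stats.rv_continuous:
    mu, sigma = _matched_truncnorm_params(
        cfg.lesion_dim_mean_cm, cfg.lesion_dim_sd_cm, cfg.lesion_dim_min_cm)
    a = (cfg.lesion_dim_min_cm - mu) / sigma
    return stats.truncnorm(a, np.inf, loc=mu, scale=sigma)


def sample_lesion_diameters(cfg: PhantomConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Greatest lesion dimensions in cm from the truncated-normal sampler."""
    return _truncnorm(cfg).rvs(size=n, random_state=rng)


def render_lesion_mask(
    diameter_cm: float,
    spacing: tuple[float, float, float],
    axis_fracs: tuple[float, float] = (0.75, 0.6),
) -> MaskVolume:
    """Render a free-standing lesion ellipsoid on its own minimal grid.

    The greatest axis (length ``diameter_cm``) lies in-plane along x; the
    minor in-plane and craniocaudal axes are the configured fractions of it.
    """
    d_mm = diameter_cm * 10.0
    sz, sy, sx = spacing
    ax = d_mm / 2.0
    ay = axis_fracs[0] * ax
    az = max(axis_fracs[1] * ax, sz / 2.0)
    # odd dimensions put a voxel center exactly at the ellipsoid center
    nz = 2 * int(np.ceil(az / sz)) + 3
    ny = 2 * int(np.ceil(ay / sy)) + 3
    nx = 2 * int(np.ceil(ax / sx)) + 3
    zc, yc, xc = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    zz, yy, xx = np.indices((nz, ny, nx))
    r = (((zz - zc) * sz / az) ** 2 + ((yy - yc) * sy / ay) ** 2 + ((xx - xc) * sx / ax) ** 2)
    return MaskVolume(r <= 1.0, affine_from_spacing(spacing))


def _superellipsoid(shape, spacing, center_mm, semiaxes, power) -> np.ndarray:
    zz, yy, xx = np.indices(shape, sparse=True)
    sz, sy, sx = spacing
    cz, cy, cx = center_mm
    az, ay, ax = semiaxes
    r = (
        np.abs((zz * sz - cz) / az) ** power
        + np.abs((yy * sy - cy) / ay) ** power
        + np.abs((xx * sx - cx) / ax) ** power
    )
    return r <= 1.0


def _normalized_radius(shape, spacing, center_mm, semiaxes, power) -> np.ndarray:
    zz, yy, xx = np.indices(shape, sparse=True)
    sz, sy, sx = spacing
    cz, cy, cx = center_mm
    az, ay, ax = semiaxes
    r = (
        np.abs((zz * sz - cz) / az) ** power
        + np.abs((yy * sy - cy) / ay) ** power
        + np.abs((xx * sx - cx) / ax) ** power
    )
    return r ** (1.0 / power)


def _sample_lesion_count(cfg: PhantomConfig, rng: np.random.Generator, with_lesions: bool) -> int:
    probs = np.asarray(cfg.lesion_count_probs, dtype=float)
    if not with_lesions:
        return 0
    cond = probs[1:].copy()
    if cond.sum() <= 0:
        raise ValueError("cannot draw a lesion-bearing case: P(count >= 1) = 0")
    cond /= cond.sum()
    return int(rng.choice(np.arange(1, 5), p=cond))


def _place_lesion(
    cfg: PhantomConfig,
    rng: np.random.Generator,
    gland: np.ndarray,
    zone_mask: np.ndarray,
    zone: str,
) -> Lesion | None:
    d_cm = float(sample_lesion_diameters(cfg, 1, rng)[0])
    d_mm = d_cm * 10.0
    sz, sy, sx = cfg.spacing
    ax = d_mm / 2.0
    ay = cfg.lesion_axis_fracs[0] * ax
    az = max(cfg.lesion_axis_fracs[1] * ax, sz / 2.0)

    # candidate centers: zone voxels away from the gland edge
    interior = ndimage.binary_erosion(gland, iterations=2) & zone_mask
    candidates = np.argwhere(interior if interior.any() else zone_mask)
    if candidates.size == 0:
        return None
    czyx = candidates[rng.integers(len(candidates))]
    center_mm = (czyx[0] * sz, czyx[1] * sy, czyx[2] * sx)
    ell = _superellipsoid(gland.shape, cfg.spacing, center_mm, (az, ay, ax), 2.0)
    if not ell.any():
        return None
    inside = ell & gland
    if inside.sum() < 0.6 * ell.sum():
        return None  # would be clipped too heavily; treat as a failed placement
    idx = np.argwhere(inside)
    span = idx.max(axis=0) - idx.min(axis=0) + 1
    inplane = float(max(span[1] * sy, span[2] * sx))
    greatest = float(max(span[0] * sz, inplane))
    return Lesion(
        mask=MaskVolume(inside, affine_from_spacing(cfg.spacing)),
        zone=zone,
        sampled_diameter_cm=d_cm,
        inplane_diameter_mm=inplane,
        greatest_diameter_mm=greatest,
    )


def generate_patient(
    config: PhantomConfig,
    with_lesions: bool = True,
    deranged_geometry: bool = False,
    rng: np.random.Generator | None = None,
    patient_id: str = "case_0000",
) -> PatientCase:
    """Generate one synthetic patient satisfying all mask invariants.

    With ``deranged_geometry`` the T2WI is produced on a shifted and slightly
    rotated grid relative to the ADC/DWI frame, to exercise registration.
    Lesion placements that would fall outside the gland are resampled up to
    ``config.lesion_max_retries`` times before erroring.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = config.shape
    sz, sy, sx = config.spacing
    fov_mm = (shape[0] * sz, shape[1] * sy, shape[2] * sx)

    semi = np.abs(rng.normal(config.gland_semiaxes_mean, config.gland_semiaxes_sd))
    semi = np.maximum(semi, (2 * sz, 4 * sy, 4 * sx))
    center = np.array(fov_mm) / 2.0 + rng.normal(0.0, (sz, 2 * sy, 2 * sx))

    radius = _normalized_radius(shape, config.spacing, center, semi, config.superellipse_power)
    gland = radius <= 1.0
    if not gland.any():
        raise RuntimeError("degenerate configuration: empty gland")

    yy = np.indices(shape)[1] * sy
    posterior = yy >= center[1]
    pz = gland & (radius >= 1.0 - config.pz_thickness_frac) & posterior
    cg = gland & ~pz
    if not pz.any() or not cg.any():
        raise RuntimeError("degenerate configuration: empty PZ or CG")

    n_lesions = _sample_lesion_count(config, rng, with_lesions)
    lesions: list[Lesion] = []
    for _ in range(n_lesions):
        zone = "PZ" if rng.random() < config.lesion_pz_prob else "TZ"
        zone_mask = pz if zone == "PZ" else cg
        placed = None
        for _attempt in range(config.lesion_max_retries):
            placed = _place_lesion(config, rng, gland, zone_mask, zone)
            if placed is not None:
                break
        if placed is None:
            raise RuntimeError(
                f"failed to place a {zone} lesion within "
                f"{config.lesion_max_retries} retries (gland too small for sampled size)"
            )
        lesions.append(placed)

    lesion_union = np.zeros(shape, dtype=bool)
    for l in lesions:
        lesion_union |= l.mask.data

    def _scene(means: tuple[float, float, float, float]) -> np.ndarray:
        bg, cg_mu, pz_mu, les_mu = means
        img = np.full(shape, bg, dtype=np.float32)
        img[cg] = cg_mu
        img[pz] = pz_mu
        img[lesion_union] = les_mu
        img += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
        return img

    affine = affine_from_spacing(config.spacing)
    t2_scene = _scene(config.t2_means)
    adc_vol = VolumeGrid(_scene(config.adc_means), affine)
    highb_vol = VolumeGrid(_scene(config.highb_means), affine)

    if deranged_geometry:
        t2w = _derange(t2_scene, affine, rng)
    else:
        t2w = VolumeGrid(t2_scene, affine)

    case = PatientCase(
        patient_id=patient_id,
        t2w=t2w,
        adc=adc_vol,
        highb=highb_vol,
        gland=MaskVolume(gland, affine),
        pz=MaskVolume(pz, affine),
        cg=MaskVolume(cg, affine),
        lesions=lesions,
    )
    case.validate()
    return case


def _derange(scene: np.ndarray, affine: np.ndarray, rng: np.random.Generator) -> VolumeGrid:
    """Resample the T2 scene onto a shifted, slightly rotated grid."""
    theta = np.deg2rad(rng.uniform(1.0, 4.0)) * rng.choice((-1.0, 1.0))
    rot = np.eye(4)
    rot[0, 0] = rot[1, 1] = np.cos(theta)
    rot[0, 1] = -np.sin(theta)
    rot[1, 0] = np.sin(theta)
    shift = np.eye(4)
    shift[:3, 3] = rng.uniform(-4.0, 4.0, size=3) * (1.0, 1.0, 0.25)
    target_affine = shift @ affine @ rot

    # map target voxel -> source voxel: inv(A_src) @ A_tgt, in (x, y, z) order
    m = np.linalg.inv(affine) @ target_affine
    perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)  # zyx <-> xyz
    matrix = perm @ m[:3, :3] @ perm
    offset = perm @ m[:3, 3]
    data = ndimage.affine_transform(
        scene, matrix, offset=offset, output_shape=scene.shape, order=1, mode="nearest"
    ).astype(np.float32)
    return VolumeGrid(data, target_affine)


def sample_cohort(
    config: PhantomConfig,
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator | None = None,
    deranged_geometry: bool = False,
    id_prefix: str = "case",
) -> list[PatientCase]:
    """Exactly ``n_pos`` lesion-bearing and ``n_neg`` lesion-free cases."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("cohort sizes must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cases = []
    for i in range(n_pos + n_neg):
        cases.append(
            generate_patient(
                config,
                with_lesions=i < n_pos,
                deranged_geometry=deranged_geometry,
                rng=rng,
                patient_id=f"{id_prefix}_{i:04d}",
            )
        )
    return cases


def write_cohort(cases: list[PatientCase], directory: str | Path) -> dict:
    """Write one NIfTI per sequence/mask per patient plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for case in cases:
        pdir = directory / case.patient_id
        pdir.mkdir(exist_ok=True)
        paths = {}
        for name, vol in (
            ("t2w", case.t2w), ("adc", case.adc), ("highb", case.highb),
            ("gland", case.gland), ("pz", case.pz), ("cg", case.cg),
        ):
            p = pdir / f"{name}.nii.gz"
            psio.write_volume(vol, p)
            paths[name] = str(p.relative_to(directory))
        lesion_entries = []
        for j, lesion in enumerate(case.lesions):
            p = pdir / f"lesion_{j}.nii.gz"
            psio.write_volume(lesion.mask, p)
            lesion_entries.append({
                "path": str(p.relative_to(directory)),
                "zone": lesion.zone,
                "sampled_diameter_cm": lesion.sampled_diameter_cm,
                "inplane_diameter_mm": lesion.inplane_diameter_mm,
                "greatest_diameter_mm": lesion.greatest_diameter_mm,
            })
        entries.append({
            "patient_id": case.patient_id,
            "is_positive": case.is_positive,
            "paths": paths,
            "lesions": lesion_entries,
        })
    manifest = {"n_cases": len(cases), "cases": entries}
    psio.write_json(manifest, directory / "manifest.json")
    return manifest


def read_cohort(manifest_path: str | Path) -> list[PatientCase]:
    """Rebuild a cohort from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = psio.read_json(manifest_path)
    cases = []
    for entry in manifest["cases"]:
        paths = entry["paths"]
        lesions = [
            Lesion(
                mask=psio.read_mask(root / l["path"]),
                zone=l["zone"],
                sampled_diameter_cm=l["sampled_diameter_cm"],
                inplane_diameter_mm=l["inplane_diameter_mm"],
                greatest_diameter_mm=l["greatest_diameter_mm"],
            )
            for l in entry["lesions"]
        ]
        case = PatientCase(
            patient_id=entry["patient_id"],
            t2w=psio.read_volume(root / paths["t2w"]),
            adc=psio.read_volume(root / paths["adc"]),
            highb=psio.read_volume(root / paths["highb"]),
            gland=psio.read_mask(root / paths["gland"]),
            pz=psio.read_mask(root / paths["pz"]),
            cg=psio.read_mask(root / paths["cg"]),
            lesions=lesions,
        )
        cases.append(case)
    return cases


def config_to_dict(cfg: PhantomConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    for key in ("shape", "spacing", "gland_semiaxes_mean", "gland_semiaxes_sd",
                "lesion_count_probs", "lesion_axis_fracs",
                "t2_means", "adc_means", "highb_means"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomConfig(**d)
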