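"""Three-stage cascade: gland -> peripheral zone -> lesion segmentation.

Stage 1 segments the whole gland from the image stack (T2WI+ADC or ADC
alone), stage 2 adds the gland mask as a conditioning channel and segments
the peripheral zone (clipped to the gland), the central gland is the gland
minus the PZ, and stage 3 takes images plus both zone masks and segments
lesions.  During training the conditioning masks come from ground truth;
at inference from the previous stages' predictions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .components import Component, extract_components
from .evaluate import dsc
from .grid import MaskVolume
from .phantom import PatientCase
from .preprocess import (AugmentConfig, CropPlacement, LocalizerConfig, augment,
                         crop_patch, localize_prostate, normalize_patch, uncrop)
from .resunet import Adam, NetworkSpec, ResUNet, build_network, get_loss

__all__ = [
    "CascadeSpec",
    "TrainConfig",
    "PreparedCase",
    "CascadeResult",
    "prepare_case",
    "build_stage_inputs",
    "train_stage",
    "infer_case",
    "extract_components",
    "Component",
]

STAGES = (1, 2, 3)
_STAGE_TARGETS = {1: "gland", 2: "pz", 3: "lesion"}


@dataclass(frozen=True)
class CascadeSpec:
    variant: str = "bp"  # "bp" (T2WI+ADC) | "adc"
    depth: int = 4
    base_width: int = 32
    patch_size: int = 128
    threshold: float = 0.5
    constrain_to_gland: bool = True
    min_lesion_volume_mm3: float = 25.0
    connectivity: int = 26
    gland_largest_component: bool = True
    localizer: LocalizerConfig = field(default_factory=LocalizerConfig)

    def __post_init__(self) -> None:
        if self.variant not in ("bp", "adc"):
            raise ValueError("variant must be 'bp' or 'adc'")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    @property
    def n_images(self) -> int:
        return 2 if self.variant == "bp" else 1

    def stage_in_channels(self, stage: int) -> int:
        if stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        return self.n_images + {1: 0, 2: 1, 3: 2}[stage]

    def network_spec(self, stage: int) -> NetworkSpec:
        return NetworkSpec(
            in_channels=self.stage_in_channels(stage),
            depth=self.depth,
            base_width=self.base_width,
            input_size=self.patch_size,
        )


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 20
    learning_rate: float = 1e-4
    epochs: int = 120
    optimizer: str = "adam"
    loss: str = "dice"
    seed: int = 0
    val_every: int = 1
    augment: bool = False
    augment_cfg: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adaptive-moment optimizer is supported")


@dataclass
class PreparedCase:
    """A patient after localization, cropping, and normalization."""

    patient_id: str
    images: np.ndarray  # (n_images, z, s, s) in [0, 1]
    gland: np.ndarray  # (z, s, s) bool, patch space
    pz: np.ndarray
    cg: np.ndarray
    lesion: np.ndarray
    placement: CropPlacement
    case: PatientCase

    @property
    def n_slices(self) -> int:
        return self.images.shape[1]


def prepare_case(case: PatientCase, spec: CascadeSpec) -> PreparedCase:
    """Localize on high-b DWI, crop all sequences/masks, and normalize."""
    box, _ = localize_prostate(case.highb, dataclasses.replace(
        spec.localizer, patch_size=spec.patch_size))
    size = spec.patch_size

    def crop_image(vol):
        patch, placement = crop_patch(vol, box, size)
        return normalize_patch(patch.data).astype(np.float32), placement

    adc_patch, placement = crop_image(case.adc)
    channels = [adc_patch]
    if spec.variant == "bp":
        t2 = case.t2w
        if not t2.same_geometry(case.adc):
            from .preprocess import RegistrationSpec, resample_to_grid
            t2 = resample_to_grid(t2, RegistrationSpec(case.adc.affine, case.adc.shape))
        channels.insert(0, crop_image(t2)[0])

    def crop_mask(mask: MaskVolume) -> np.ndarray:
        patch, _ = crop_patch(mask.with_data(mask.data.astype(np.uint8)), box, size)
        return patch.data.astype(bool)

    return PreparedCase(
        patient_id=case.patient_id,
        images=np.stack(channels, axis=0),
        gland=crop_mask(case.gland),
        pz=crop_mask(case.pz),
        cg=crop_mask(case.cg),
        lesion=crop_mask(case.lesion_union()),
        placement=placement,
        case=case,
    )


def build_stage_inputs(prep: PreparedCase, stage: int, spec: CascadeSpec,
                       gland: np.ndarray | None = None,
                       pz: np.ndarray | None = None,
                       cg: np.ndarray | None = None) -> np.ndarray:
    """Channel stack ``(z, c, s, s)`` for one case at one cascade stage.

    Conditioning masks default to ground truth (training-time teacher
    forcing); pass predicted masks at inference.
    """
    chans = [prep.images[i] for i in range(prep.images.shape[0])]
    if stage >= 2:
        chans.append((prep.gland if gland is None else gland).astype(np.float32))
    if stage == 3:
        chans.append((prep.pz if pz is None else pz).astype(np.float32))
        chans.append((prep.cg if cg is None else cg).astype(np.float32))
        chans.pop(-3)  # stage 3 conditions on PZ + CG, not the gland
    return np.stack(chans, axis=1)


def _stage_targets(prep: PreparedCase, stage: int) -> np.ndarray:
    return getattr(prep, _STAGE_TARGETS[stage])


def _stage_slices(prep: PreparedCase, stage: int) -> np.ndarray:
    """Slice indices used for training a stage.

    Stage 1 uses every slice (it must learn to emit background); stages 2-3
    train on gland-bearing slices only, mirroring the conditioning masks.
    """
    if stage == 1:
        return np.arange(prep.n_slices)
    return np.unique(np.nonzero(prep.gland)[0])


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = float("nan")


def train_stage(
    stage: int,
    cohort: list[PatientCase | PreparedCase],
    spec: CascadeSpec,
    cfg: TrainConfig,
    val_cohort: list[PatientCase | PreparedCase] | None = None,
) -> tuple[ResUNet, TrainHistory]:
    """Train one cascade stage; returns the best-validation-DSC network.

    Fully seeded: weight init, batch shuffling, and augmentation draw from
    ``cfg.seed``.  Without a validation cohort the final weights are kept.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    if not cohort:
        raise ValueError("empty training cohort")

    preps = [c if isinstance(c, PreparedCase) else prepare_case(c, spec) for c in cohort]
    val_preps = [c if isinstance(c, PreparedCase) else prepare_case(c, spec)
                 for c in (val_cohort or [])]

    xs, ys = [], []
    for prep in preps:
        sl = _stage_slices(prep, stage)
        if sl.size == 0:
            continue
        xs.append(build_stage_inputs(prep, stage, spec)[sl])
        ys.append(_stage_targets(prep, stage)[sl][:, None].astype(np.float32))
    if not xs:
        raise ValueError("no usable training slices in cohort")
    x_all = np.concatenate(xs, axis=0)
    y_all = np.concatenate(ys, axis=0)

    rng = np.random.default_rng(cfg.seed)
    net = build_network(spec.network_spec(stage), seed=cfg.seed)
    opt = Adam(net.params(), lr=cfg.learning_rate)
    loss_fn = get_loss(cfg.loss)

    history = TrainHistory()
    best_state = None
    n = x_all.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_all[idx]
            yb = y_all[idx]
            if cfg.augment:
                xb = xb.copy()
                yb = yb.copy()
                for i in range(xb.shape[0]):
                    xb[i], m = augment(xb[i], yb[i] > 0.5, cfg.augment_cfg, rng=rng)
                    yb[i] = m.astype(np.float32)
            prob = net.forward(xb, train=True)
            loss, dprob = loss_fn(prob, yb)
            net.zero_grad()
            net.backward(dprob)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.loss.append(epoch_loss / max(n_batches, 1))

        if val_preps and (epoch + 1) % cfg.val_every == 0:
            val = _validation_dsc(net, val_preps, stage, spec)
            history.val_dsc.append(val)
            if history.best_epoch < 0 or val > history.best_val_dsc:
                history.best_epoch = epoch
                history.best_val_dsc = val
                best_state = net.state_dict()

    if best_state is not None:
        net.load_state_dict(best_state)
    else:
        history.best_epoch = cfg.epochs - 1
    return net, history


def _validation_dsc(net: ResUNet, preps: list[PreparedCase], stage: int,
                    spec: CascadeSpec, batch: int = 32) -> float:
    scores = []
    for prep in preps:
        sl = _stage_slices(prep, stage)
        if sl.size == 0:
            continue
        x = build_stage_inputs(prep, stage, spec)[sl]
        prob = _predict(net, x, batch)
        pred = prob[:, 0] >= spec.threshold
        scores.append(dsc(pred, _stage_targets(prep, stage)[sl]))
    return float(np.mean(scores)) if scores else float("nan")


def _predict(net: ResUNet, x: np.ndarray, batch: int = 32) -> np.ndarray:
    outs = [net.forward(x[i:i + batch], train=False) for i in range(0, x.shape[0], batch)]
    return np.concatenate(outs, axis=0)


@dataclass
class CascadeResult:
    """Inference output mapped back to the original ADC grid."""

    patient_id: str
    gland: MaskVolume
    pz: MaskVolume
    cg: MaskVolume
    lesion_prob: np.ndarray  # (z, y, x) on the ADC grid
    lesion_mask: MaskVolume
    components: list[Component]

    @property
    def is_positive(self) -> bool:
        return len(self.components) > 0


def infer_case(
    case: PatientCase | PreparedCase,
    networks: dict[int, ResUNet],
    spec: CascadeSpec,
) -> CascadeResult:
    """Run the full cascade on one case.

    Enforces the mask hierarchy (PZ within the gland, CG = gland minus PZ),
    thresholds the lesion probability map at ``spec.threshold``, optionally
    intersects lesions with the gland, and drops components below the
    minimum volume.  All outputs live on the original ADC grid.
    """
    for stage in STAGES:
        if stage not in networks:
            raise ValueError(f"missing checkpoint for cascade stage {stage}")
        want = spec.stage_in_channels(stage)
        got = networks[stage].spec.in_channels
        if want != got:
            raise ValueError(
                f"stage {stage} network expects {got} channels, variant needs {want}")

    prep = case if isinstance(case, PreparedCase) else prepare_case(case, spec)
    adc = prep.case.adc

    x1 = build_stage_inputs(prep, 1, spec)
    gland_patch = _predict(networks[1], x1)[:, 0] >= spec.threshold
    if spec.gland_largest_component and gland_patch.any():
        lab, nlab = ndimage.label(gland_patch, structure=np.ones((3, 3, 3), bool))
        if nlab > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, nlab + 1))
            gland_patch = lab == (int(np.argmax(sizes)) + 1)

    x2 = build_stage_inputs(prep, 2, spec, gland=gland_patch)
    pz_patch = (_predict(networks[2], x2)[:, 0] >= spec.threshold) & gland_patch
    cg_patch = gland_patch & ~pz_patch

    x3 = build_stage_inputs(prep, 3, spec, gland=gland_patch, pz=pz_patch, cg=cg_patch)
    prob_patch = _predict(networks[3], x3)[:, 0]
    lesion_patch = prob_patch >= spec.threshold
    if spec.constrain_to_gland:
        lesion_patch &= gland_patch

    gland_full = uncrop(gland_patch, prep.placement)
    pz_full = uncrop(pz_patch, prep.placement)
    cg_full = gland_full & ~pz_full
    prob_full = uncrop(prob_patch.astype(np.float32), prep.placement)
    lesion_full = uncrop(lesion_patch, prep.placement)

    comps = extract_components(lesion_full, adc.spacing,
                               connectivity=spec.connectivity,
                               min_volume_mm3=spec.min_lesion_volume_mm3)
    kept = np.zeros_like(lesion_full)
    for c in comps:
        kept[tuple(c.indices.T)] = True

    aff = adc.affine
    return CascadeResult(
        patient_id=prep.patient_id,
        gland=MaskVolume(gland_full, aff.copy()),
        pz=MaskVolume(pz_full, aff.copy()),
        cg=MaskVolume(cg_full, aff.copy()),
        lesion_prob=prob_full,
        lesion_mask=MaskVolume(kept, aff.copy()),
        components=comps,
    )
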