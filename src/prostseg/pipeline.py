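"""End-to-end orchestration: simulate, train, infer, evaluate, report.

Everything is driven by a JSON run configuration whose sections map onto the
module configs; all stochastic components draw from one global seed.  Paper
defaults (batch 20, learning rate 1e-4, 120 epochs, threshold 0.5, 128
patch, 10 degree rotations, 0.001 noise, 50% matching rules) live in the
respective config dataclasses and are never hard-coded here.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np

from . import io as psio
from .cascade import (CascadeSpec, TrainConfig, extract_components, infer_case,
                      train_stage)
from .evaluate import (MatchRuleConfig, classify_patient, match_lesions,
                       match_sextants, mcnemar, patient_level, rates_with_ci)
from .grid import VolumeGrid
from .phantom import (PhantomConfig, config_from_dict, read_cohort, sample_cohort,
                      write_cohort)
from .report import build_report, partition_sextants, save_key_image_png, select_key_image
from .resunet import load_checkpoint, save_checkpoint

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("prostseg")

COMMANDS = ("simulate", "train", "infer", "evaluate", "report", "all")


@dataclasses.dataclass
class RunConfig:
    """Top-level run configuration (see ``RunConfig.from_json``)."""

    out_dir: Path
    cohort_manifest: Path | None = None
    ckpt_dir: Path | None = None
    pred_dir: Path | None = None
    seed: int = 0
    n_pos: int = 10
    n_neg: int = 10
    n_val_pos: int = 2
    n_val_neg: int = 2
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    cascade: CascadeSpec = dataclasses.field(default_factory=CascadeSpec)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    match: MatchRuleConfig = dataclasses.field(default_factory=MatchRuleConfig)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = psio.read_json(path)
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: dict, **overrides) -> "RunConfig":
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        kwargs: dict = {}
        for key in ("out_dir", "cohort_manifest", "ckpt_dir", "pred_dir"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for key in ("seed", "n_pos", "n_neg", "n_val_pos", "n_val_neg"):
            if key in raw:
                kwargs[key] = int(raw[key])
        if "phantom" in raw:
            kwargs["phantom"] = config_from_dict(raw["phantom"])
        if "cascade" in raw:
            c = dict(raw["cascade"])
            from .preprocess import LocalizerConfig
            if "localizer" in c:
                c["localizer"] = LocalizerConfig(**c["localizer"])
            kwargs["cascade"] = CascadeSpec(**c)
        if "train" in raw:
            t = dict(raw["train"])
            from .preprocess import AugmentConfig
            if "augment_cfg" in t:
                t["augment_cfg"] = AugmentConfig(**t["augment_cfg"])
            kwargs["train"] = TrainConfig(**t)
        if "match" in raw:
            kwargs["match"] = MatchRuleConfig(**raw["match"])
        if "out_dir" not in kwargs:
            raise ValueError("run config needs an out_dir")
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig, command: str) -> dict:
    """Dispatch one pipeline command; returns a summary of artifacts."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    log.info("command=%s seed=%d config=%s python=%s numpy=%s",
             command, config.seed, config.config_hash(),
             sys.version.split()[0], np.__version__)
    return _DISPATCH[command](config)


# ---------------------------------------------------------------------------

def cmd_simulate(config: RunConfig) -> dict:
    cohort_dir = config.out_dir / "cohort"
    rng = np.random.default_rng(config.seed)
    cases = sample_cohort(config.phantom, config.n_pos, config.n_neg, rng=rng)
    manifest = write_cohort(cases, cohort_dir)
    return {"manifest": str(cohort_dir / "manifest.json"), "n_cases": manifest["n_cases"]}


def cmd_train(config: RunConfig, stages=(1, 2, 3)) -> dict:
    if config.cohort_manifest is None:
        raise ValueError("training requires a cohort manifest")
    cases = read_cohort(config.cohort_manifest)
    n_val = config.n_val_pos + config.n_val_neg
    train_cases = cases[:-n_val] if n_val and len(cases) > n_val else cases
    val_cases = cases[-n_val:] if n_val and len(cases) > n_val else None

    ckpt_dir = config.ckpt_dir or (config.out_dir / "ckpt")
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for stage in stages:
        net, history = train_stage(stage, train_cases, config.cascade, config.train,
                                   val_cohort=val_cases)
        path = ckpt_dir / f"stage{stage}_{config.cascade.variant}.npz"
        save_checkpoint(net, path)
        psio.write_json(
            {"loss": history.loss, "val_dsc": history.val_dsc,
             "best_epoch": history.best_epoch},
            ckpt_dir / f"stage{stage}_{config.cascade.variant}_history.json")
        out[f"stage{stage}"] = str(path)
        log.info("trained stage %d: best_val_dsc=%.3f", stage, history.best_val_dsc)
    return out


def _load_networks(config: RunConfig) -> dict:
    ckpt_dir = config.ckpt_dir or (config.out_dir / "ckpt")
    nets = {}
    for stage in (1, 2, 3):
        path = ckpt_dir / f"stage{stage}_{config.cascade.variant}.npz"
        if not path.exists():
            raise FileNotFoundError(
                f"missing checkpoint for cascade stage {stage}: {path}")
        nets[stage] = load_checkpoint(path)
    return nets


def cmd_infer(config: RunConfig) -> dict:
    if config.cohort_manifest is None:
        raise ValueError("inference requires a cohort manifest")
    nets = _load_networks(config)
    cases = read_cohort(config.cohort_manifest)
    pred_dir = config.pred_dir or (config.out_dir / "pred")
    pred_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for case in cases:
        result = infer_case(case, nets, config.cascade)
        pdir = pred_dir / case.patient_id
        pdir.mkdir(exist_ok=True)
        psio.write_volume(result.gland, pdir / "gland.nii.gz")
        psio.write_volume(result.pz, pdir / "pz.nii.gz")
        psio.write_volume(result.cg, pdir / "cg.nii.gz")
        psio.write_volume(result.lesion_mask, pdir / "lesion_mask.nii.gz")
        psio.write_volume(VolumeGrid(result.lesion_prob, result.gland.affine),
                          pdir / "lesion_prob.nii.gz")
        index.append({
            "patient_id": case.patient_id,
            "is_positive_pred": result.is_positive,
            "n_components": len(result.components),
        })
    psio.write_json({"cases": index}, pred_dir / "predictions.json")
    return {"pred_dir": str(pred_dir), "n_cases": len(index)}


def cmd_evaluate(config: RunConfig) -> dict:
    if config.cohort_manifest is None:
        raise ValueError("evaluation requires a cohort manifest")
    pred_dir = config.pred_dir or (config.out_dir / "pred")
    cases = read_cohort(config.cohort_manifest)

    lesion_counts = None
    sextant_counts = None
    outcomes = []
    lesion_dscs: list[float] = []
    for case in cases:
        lesion_mask = psio.read_mask(pred_dir / case.patient_id / "lesion_mask.nii.gz")
        spacing = case.adc.spacing
        pred_comps = extract_components(lesion_mask.data, spacing,
                                        config.cascade.connectivity,
                                        config.cascade.min_lesion_volume_mm3)
        gt_comps = []
        for lesion in case.lesions:
            gt_comps.extend(extract_components(lesion.mask.data, spacing))

        res = match_lesions(pred_comps, gt_comps, config.match)
        lesion_counts = res.counts if lesion_counts is None else lesion_counts + res.counts
        lesion_dscs.extend(res.lesion_dsc.values())

        smap = partition_sextants(case.gland)
        sc = match_sextants(pred_comps, gt_comps, smap.arrays(), config.match)
        sextant_counts = sc if sextant_counts is None else sextant_counts + sc
        outcomes.append(classify_patient(pred_comps, gt_comps, config.match))

    patient_counts = patient_level(outcomes)
    tables = {
        "lesion": rates_with_ci(lesion_counts),
        "sextant": rates_with_ci(sextant_counts),
        "patient": rates_with_ci(patient_counts),
    }
    if lesion_dscs:
        tables["lesion"].mean_lesion_dsc = float(np.mean(lesion_dscs))
        tables["lesion"].sd_lesion_dsc = (
            float(np.std(lesion_dscs, ddof=1)) if len(lesion_dscs) > 1 else 0.0)

    metrics = {level: t.to_dict() for level, t in tables.items()}
    psio.write_json(metrics, config.out_dir / "metrics.json")
    _write_metrics_csv(tables, config.out_dir / "metrics.csv")
    return {"metrics": str(config.out_dir / "metrics.json")}


def _write_metrics_csv(tables: dict, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "rate", "percent", "numerator", "denominator",
                         "ci_low", "ci_high"])
        for level, table in tables.items():
            for name, row in table.rows.items():
                writer.writerow([level, name, f"{row.percent:.1f}", row.numerator,
                                 row.denominator, f"{row.ci_low:.1f}", f"{row.ci_high:.1f}"])


def compare_detectors(outcomes_a: list[str], outcomes_b: list[str]) -> dict:
    """McNemar comparison of two detectors' per-unit outcomes."""
    correct = {"TP": True, "TN": True, "FP": False, "FN": False}
    a = np.array([correct[o] for o in outcomes_a])
    b = np.array([correct[o] for o in outcomes_b])
    p, nb, nc, method = mcnemar(a, b)
    return {"p": p, "b": nb, "c": nc, "method": method}


def cmd_report(config: RunConfig) -> dict:
    if config.cohort_manifest is None:
        raise ValueError("reporting requires a cohort manifest")
    pred_dir = config.pred_dir or (config.out_dir / "pred")
    report_dir = config.out_dir / "reports"
    report_dir.mkdir(parents=True, exist_ok=True)
    cases = read_cohort(config.cohort_manifest)
    written = []
    for case in cases:
        pdir = pred_dir / case.patient_id
        gland = psio.read_mask(pdir / "gland.nii.gz")
        lesion_mask = psio.read_mask(pdir / "lesion_mask.nii.gz")
        comps = extract_components(lesion_mask.data, case.adc.spacing,
                                   config.cascade.connectivity,
                                   config.cascade.min_lesion_volume_mm3)
        if not gland.data.any():  # cascade found no gland; report negative
            continue
        report = build_report(case.patient_id, comps, gland, case.adc,
                              match_cfg=config.match)
        report.save(report_dir / f"{case.patient_id}.json")
        for lesion in report.lesions:
            _, raster = select_key_image(case.adc,
                                         comps[lesion.index].mask())
            save_key_image_png(
                raster, report_dir / f"{case.patient_id}_lesion{lesion.index}.png")
        written.append(case.patient_id)
    return {"report_dir": str(report_dir), "n_reports": len(written)}


def cmd_all(config: RunConfig) -> dict:
    out = {}
    out["simulate"] = cmd_simulate(config)
    config.cohort_manifest = Path(out["simulate"]["manifest"])
    out["train"] = cmd_train(config)
    out["infer"] = cmd_infer(config)
    out["evaluate"] = cmd_evaluate(config)
    out["report"] = cmd_report(config)
    return out


_DISPATCH = {
    "simulate": cmd_simulate,
    "train": cmd_train,
    "infer": cmd_infer,
    "evaluate": cmd_evaluate,
    "report": cmd_report,
    "all": cmd_all,
}
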