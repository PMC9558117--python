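# prostseg

Fully automated detection and localization of clinically significant
prostate-cancer lesions on biparametric prostate MRI (ADC + T2WI), built as a
cascade of three residual U-Nets, together with the full preprocessing chain,
lesion/sextant/patient-level evaluation statistics, a machine-readable
structured report, and a synthetic phantom generator that makes every stage
trainable and testable without patient data.

## What's inside

| Module | Purpose |
| --- | --- |
| `prostseg.phantom` | Synthetic biparametric phantoms: superellipsoid gland with a posterior peripheral-zone shell and central gland, 0–4 hypointense-on-ADC lesions with calibrated multiplicity / zone / size distributions, NIfTI cohort writer |
| `prostseg.preprocess` | Header-based rigid resampling (3rd-order B-spline for images, Gaussian label interpolation for masks), K-means prostate localization on high-b DWI, 128×128 cropping with lossless un-crop, [0, 1] normalization, mirror/rotate/noise augmentation |
| `prostseg.resunet` | A pure-NumPy 2D residual U-Net (residual blocks with 1×1-conv shortcuts, batch norm, max-pool encoder, nearest-neighbour-upsample decoder with long skips, logistic head) with hand-written backprop, soft-Dice/BCE losses, and Adam |
| `prostseg.cascade` | The three-stage hierarchy (gland → PZ → lesion; CG = gland − PZ) in biparametric and ADC-only variants, training with teacher forcing and seeded reproducibility, inference with gland constraint and minimum-volume filtering, 26-connected component extraction |
| `prostseg.evaluate` | Dice, the ≥50 %-of-truth-on-one-slice lesion matching rule, the 50 % sextant containment rules, patient-level rules, exact Clopper–Pearson confidence intervals, and the McNemar paired test (exact below 25 discordant pairs) |
| `prostseg.report` | Sextant partitioning of the gland (left/right × base/mid/apex), axis-aligned 3D diameters, key-image selection with lesion-contour overlay, structured JSON report with a sector map |
| `prostseg.pipeline` / `prostseg.cli` | JSON-configured end-to-end orchestration and the `prostseg` command-line interface |

The network is implemented in NumPy (with analytic gradients verified against
finite differences) so the whole pipeline runs on a plain CPU with no deep
learning framework.

## CLI

```bash
# synthetic cohort with ground-truth masks
prostseg simulate --out runs/demo --n-pos 10 --n-neg 10 --seed 1

# train the three cascade stages (paper defaults: batch 20, lr 1e-4, 120 epochs)
prostseg train --config cfg.json --cohort runs/demo/cohort/manifest.json --out runs/demo

# inference, metrics, and structured reports
prostseg infer    --config cfg.json --cohort ... --ckpt-dir runs/demo/ckpt --out runs/demo
prostseg evaluate --config cfg.json --cohort ... --pred runs/demo/pred --out runs/demo
prostseg report   --config cfg.json --cohort ... --pred runs/demo/pred --out runs/demo

# everything end to end on a synthetic cohort
prostseg all --config cfg.json
```

The JSON run config mirrors the dataclass sections (`phantom`, `cascade`,
`train`, `match`); every stated default (probability threshold 0.5, 128×128
patch, rotation ≤ 10°, additive noise ≤ 0.001, 50 % matching rules) lives in
the dataclasses and can be overridden there.

## Conventions

Arrays are axial stacks indexed `(z, y, x)` with slice 0 the most cranial
slice, +y posterior, and +x toward the patient's left; affines follow the
NIfTI voxel-to-world convention. Masks are strictly binary everywhere; the
zones always satisfy PZ ∪ CG = gland with PZ ∩ CG = ∅.
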