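"""Detection metrics: Dice, lesion/sextant/patient matching, exact CIs, McNemar.

Matching rules
--------------
* Lesion level: a predicted component is a true positive if, on at least one
  axial slice, it covers >= half of a ground-truth lesion's area on that
  slice.  Unmatched predictions are false positives; undetected truth lesions
  are false negatives.  True negatives are undefined at this level.
* Sextant level: a sextant contains a lesion if it holds >= half of the
  lesion's volume, or the lesion occupies >= half of the sextant.  The rule
  is applied identically to predicted and ground-truth lesions.
* Patient level: any true-positive lesion match makes a positive patient a
  true positive; any predicted component makes a negative patient a false
  positive.

Rates carry exact two-sided Clopper-Pearson 95% confidence intervals, and
paired detectors are compared with the McNemar test (exact binomial below 25
discordant pairs, continuity-corrected chi-square otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .components import Component
from .grid import MaskVolume

__all__ = [
    "MatchRuleConfig",
    "ConfusionCounts",
    "RateRow",
    "MetricsTable",
    "LesionMatchResult",
    "dsc",
    "match_lesions",
    "lesion_sextant_labels",
    "match_sextants",
    "classify_patient",
    "patient_level",
    "clopper_pearson",
    "rates_with_ci",
    "mcnemar",
]


@dataclass(frozen=True)
class MatchRuleConfig:
    """Overlap fractions used by the matching rules (all in ``(0, 1]``)."""

    lesion_slice_overlap: float = 0.5
    sextant_lesion_coverage: float = 0.5
    sextant_occupancy: float = 0.5

    def __post_init__(self) -> None:
        for name in ("lesion_slice_overlap", "sextant_lesion_coverage", "sextant_occupancy"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN tallies at one evaluation level (TN undefined for lesions)."""

    level: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int | None:
        return None if self.tn is None else self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.level != other.level:
            raise ValueError("cannot add counts from different levels")
        tn = None
        if self.tn is not None and other.tn is not None:
            tn = self.tn + other.tn
        return ConfusionCounts(self.level, self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, tn)


def dsc(x, y) -> float:
    """Dice similarity coefficient ``2|X∩Y| / (|X| + |Y|)``.

    Accepts boolean arrays or :class:`MaskVolume` on the same grid.  Two empty
    masks yield 1.0 by convention; one empty mask yields 0.0.
    """
    if isinstance(x, MaskVolume) and isinstance(y, MaskVolume):
        if not x.same_geometry(y):
            raise ValueError("masks are on different grids")
        x, y = x.data, y.data
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx = int(x.sum())
    ny = int(y.sum())
    if nx + ny == 0:
        return 1.0
    inter = int(np.logical_and(x, y).sum())
    return 2.0 * inter / (nx + ny)


# ---------------------------------------------------------------------------
# lesion level
# ---------------------------------------------------------------------------

@dataclass
class LesionMatchResult:
    counts: ConfusionCounts
    #: pairs (pred index, gt index) that satisfy the slice-overlap rule
    matches: list[tuple[int, int]] = field(default_factory=list)
    #: per detected ground-truth lesion: DSC against the union of its matches
    lesion_dsc: dict[int, float] = field(default_factory=dict)

    @property
    def detected_gt(self) -> set[int]:
        return {g for _, g in self.matches}


def _slice_overlap_match(pred: Component, gt: Component, frac: float) -> bool:
    """True if pred covers >= frac of gt's area on at least one axial slice."""
    pred_slices = pred.slice_areas
    common = set(pred_slices) & set(gt.slice_areas)
    if not common:
        return False
    pset = {tuple(r) for r in pred.indices}
    for z in common:
        gt_rows = gt.indices[gt.indices[:, 0] == z]
        inter = sum(1 for r in gt_rows if tuple(r) in pset)
        if inter / len(gt_rows) >= frac:
            return True
    return False


def match_lesions(
    pred_components: list[Component],
    gt_components: list[Component],
    cfg: MatchRuleConfig = MatchRuleConfig(),
) -> LesionMatchResult:
    """Apply the per-lesion >=50%-of-truth-on-one-slice rule.

    A truth lesion counts as detected at most once regardless of how many
    predictions match it; each unmatched prediction is a separate false
    positive.
    """
    shapes = {c.shape for c in pred_components} | {c.shape for c in gt_components}
    if len(shapes) > 1:
        raise ValueError("components are on different grids")

    matches: list[tuple[int, int]] = []
    for pi, pred in enumerate(pred_components):
        for gi, gt in enumerate(gt_components):
            if _slice_overlap_match(pred, gt, cfg.lesion_slice_overlap):
                matches.append((pi, gi))

    matched_preds = {p for p, _ in matches}
    detected = {g for _, g in matches}
    tp = len(detected)
    fp = len(pred_components) - len(matched_preds)
    fn = len(gt_components) - len(detected)
    counts = ConfusionCounts("lesion", tp=tp, fp=fp, fn=fn, tn=None)

    lesion_dsc: dict[int, float] = {}
    for gi in sorted(detected):
        union = np.zeros(gt_components[gi].shape, dtype=bool)
        for pi, g in matches:
            if g == gi:
                union[tuple(pred_components[pi].indices.T)] = True
        lesion_dsc[gi] = dsc(union, gt_components[gi].mask())
    return LesionMatchResult(counts=counts, matches=matches, lesion_dsc=lesion_dsc)


# ---------------------------------------------------------------------------
# sextant level
# ---------------------------------------------------------------------------

def lesion_sextant_labels(
    component: Component,
    sextants: dict[str, np.ndarray],
    cfg: MatchRuleConfig = MatchRuleConfig(),
) -> set[str]:
    """Sextants considered to contain the lesion under the 50% rules.

    A sextant qualifies if it holds >= ``sextant_lesion_coverage`` of the
    lesion's voxels, or the lesion fills >= ``sextant_occupancy`` of the
    sextant.
    """
    lesion = component.mask()
    n_lesion = component.voxel_count
    out: set[str] = set()
    for name, sextant in sextants.items():
        inter = int(np.logical_and(lesion, sextant).sum())
        if inter == 0:
            continue
        n_sext = int(np.asarray(sextant).sum())
        if inter / n_lesion >= cfg.sextant_lesion_coverage:
            out.add(name)
        elif n_sext > 0 and inter / n_sext >= cfg.sextant_occupancy:
            out.add(name)
    return out


def match_sextants(
    pred_components: list[Component],
    gt_components: list[Component],
    sextants: dict[str, np.ndarray],
    cfg: MatchRuleConfig = MatchRuleConfig(),
) -> ConfusionCounts:
    """Tally sextant-level confusion counts for one patient (six units)."""
    if len(sextants) != 6:
        raise ValueError(f"expected 6 sextants, got {len(sextants)}")
    union = np.zeros_like(next(iter(sextants.values())), dtype=int)
    for m in sextants.values():
        union = union + np.asarray(m).astype(int)
    if union.max() > 1:
        raise ValueError("sextant masks overlap")

    pred_pos: set[str] = set()
    for c in pred_components:
        pred_pos |= lesion_sextant_labels(c, sextants, cfg)
    gt_pos: set[str] = set()
    for c in gt_components:
        gt_pos |= lesion_sextant_labels(c, sextants, cfg)

    tp = len(pred_pos & gt_pos)
    fp = len(pred_pos - gt_pos)
    fn = len(gt_pos - pred_pos)
    tn = 6 - tp - fp - fn
    return ConfusionCounts("sextant", tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# patient level
# ---------------------------------------------------------------------------

def classify_patient(
    pred_components: list[Component],
    gt_components: list[Component],
    cfg: MatchRuleConfig = MatchRuleConfig(),
) -> str:
    """One of ``TP``/``FP``/``FN``/``TN`` for a single patient.

    A positive patient (>=1 truth lesion) is TP as soon as one lesion is
    detected under the slice-overlap rule; a negative patient is FP as soon
    as one component is predicted.
    """
    if gt_components:
        result = match_lesions(pred_components, gt_components, cfg)
        return "TP" if result.counts.tp >= 1 else "FN"
    return "FP" if pred_components else "TN"


def patient_level(outcomes: list[str]) -> ConfusionCounts:
    """Aggregate per-patient outcomes into patient-level confusion counts."""
    valid = {"TP", "FP", "FN", "TN"}
    bad = set(outcomes) - valid
    if bad:
        raise ValueError(f"unknown patient outcomes: {sorted(bad)}")
    return ConfusionCounts(
        "patient",
        tp=outcomes.count("TP"),
        fp=outcomes.count("FP"),
        fn=outcomes.count("FN"),
        tn=outcomes.count("TN"),
    )


# ---------------------------------------------------------------------------
# rates, confidence intervals, paired comparison
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval, beta-quantile form."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


@dataclass
class RateRow:
    """One diagnostic rate as a percentage with its exact 95% CI."""

    name: str
    numerator: int
    denominator: int
    percent: float
    ci_low: float
    ci_high: float

    def formatted(self) -> str:
        return (f"{self.percent:.1f} ({self.numerator}/{self.denominator}) "
                f"[{self.ci_low:.1f}, {self.ci_high:.1f}]")


@dataclass
class MetricsTable:
    level: str
    rows: dict[str, RateRow]
    mean_lesion_dsc: float | None = None
    sd_lesion_dsc: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "level": self.level,
            "rates": {
                k: {
                    "percent": r.percent,
                    "numerator": r.numerator,
                    "denominator": r.denominator,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                }
                for k, r in self.rows.items()
            },
        }
        if self.mean_lesion_dsc is not None:
            out["mean_lesion_dsc"] = self.mean_lesion_dsc
            out["sd_lesion_dsc"] = self.sd_lesion_dsc
        if self.p_values:
            out["p_values"] = self.p_values
        return out


def _rate_row(name: str, k: int, n: int, alpha: float) -> RateRow:
    lo, hi = clopper_pearson(k, n, alpha)
    return RateRow(name, k, n, 100.0 * k / n, 100.0 * lo, 100.0 * hi)


def rates_with_ci(counts: ConfusionCounts, alpha: float = 0.05) -> MetricsTable:
    """Sensitivity/specificity/accuracy (percent) with exact CIs.

    Rates whose denominator is zero are omitted rather than fabricated;
    specificity and accuracy require defined true negatives.
    """
    rows: dict[str, RateRow] = {}
    if counts.n_positive > 0:
        rows["sensitivity"] = _rate_row("sensitivity", counts.tp, counts.n_positive, alpha)
    if counts.tn is not None:
        n_neg = counts.tn + counts.fp
        if n_neg > 0:
            rows["specificity"] = _rate_row("specificity", counts.tn, n_neg, alpha)
        total = counts.tp + counts.fp + counts.fn + counts.tn
        if total > 0:
            rows["accuracy"] = _rate_row("accuracy", counts.tp + counts.tn, total, alpha)
    return MetricsTable(level=counts.level, rows=rows)


def mcnemar(
    a_correct: np.ndarray,
    b_correct: np.ndarray,
    exact_threshold: int = 25,
) -> tuple[float, int, int, str]:
    """McNemar paired test on two detectors' per-unit correctness vectors.

    Returns ``(p, b, c, method)`` where ``b`` counts units A got right and B
    wrong, ``c`` the reverse.  Uses the exact two-sided binomial test when
    ``b + c < exact_threshold``, otherwise the continuity-corrected
    chi-square; ``b + c == 0`` yields p = 1.0.
    """
    a = np.asarray(a_correct).astype(bool)
    b_vec = np.asarray(b_correct).astype(bool)
    if a.shape != b_vec.shape:
        raise ValueError("outcome vectors must be paired (same length)")
    b = int(np.sum(a & ~b_vec))
    c = int(np.sum(~a & b_vec))
    n = b + c
    if n == 0:
        return 1.0, b, c, "degenerate"
    if n < exact_threshold:
        p = 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5))
        # the two tails overlap at the midpoint for even splits
        p = min(1.0, p)
        return p, b, c, "exact"
    x2 = (abs(b - c) - 1.0) ** 2 / n
    return float(stats.chi2.sf(x2, df=1)), b, c, "chi2"


def mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return math.nan, math.nan
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0
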