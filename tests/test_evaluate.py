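"""Metric tests, including brute-force voxel-counting oracles for every
matching rule (independent of the package's vectorized implementations)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from prostseg.components import Component, extract_components
from prostseg.evaluate import (ConfusionCounts, MatchRuleConfig, classify_patient,
                               clopper_pearson, dsc, lesion_sextant_labels,
                               match_lesions, match_sextants, mcnemar,
                               patient_level, rates_with_ci)

SPACING = (1.0, 1.0, 1.0)


def comp_from_mask(mask):
    idx = np.argwhere(np.asarray(mask).astype(bool))
    return Component(indices=idx, shape=mask.shape, spacing=SPACING)


# ---------------------------------------------------------------------------
# brute-force oracles (plain python loops, no shared code with the package)
# ---------------------------------------------------------------------------

def brute_components(mask, conn26=True):
    """Flood fill over an explicit adjacency; returns list of voxel sets."""
    mask = np.asarray(mask).astype(bool)
    voxels = {tuple(v) for v in np.argwhere(mask)}
    if conn26:
        offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    comps = []
    while voxels:
        seed = voxels.pop()
        queue = [seed]
        comp = {seed}
        while queue:
            z, y, x = queue.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in voxels:
                    voxels.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def brute_lesion_match(pred_sets, gt_sets, frac=0.5):
    """Slice-by-slice rule applied with explicit loops."""
    matches = set()
    for pi, pred in enumerate(pred_sets):
        for gi, gt in enumerate(gt_sets):
            slices = {v[0] for v in gt}
            for z in slices:
                gt_slice = {v for v in gt if v[0] == z}
                inter = len(gt_slice & pred)
                if inter / len(gt_slice) >= frac:
                    matches.add((pi, gi))
                    break
    tp = len({g for _, g in matches})
    fp = len(pred_sets) - len({p for p, _ in matches})
    fn = len(gt_sets) - tp
    return tp, fp, fn, matches


def brute_sextant_labels(lesion_set, sextant_sets, cov=0.5, occ=0.5):
    labels = set()
    for name, sx in sextant_sets.items():
        inter = len(lesion_set & sx)
        if inter == 0:
            continue
        if inter / len(lesion_set) >= cov or (len(sx) > 0 and inter / len(sx) >= occ):
            labels.add(name)
    return labels


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------

class TestDsc:
    def test_identity(self, rng):
        m = rng.random((4, 5, 5)) > 0.5
        m[0, 0, 0] = True
        assert dsc(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((2, 4, 4), bool)
        b = np.zeros((2, 4, 4), bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert dsc(a, b) == 0.0

    def test_closed_form(self):
        # |X| = 4, |Y| = 6, |X ∩ Y| = 3 -> 2*3/(4+6) = 0.6
        a = np.zeros((1, 4, 4), bool)
        b = np.zeros((1, 4, 4), bool)
        a[0, 0, :4] = True
        b[0, 0, 1:4] = True
        b[0, 1, :3] = True
        assert int(a.sum()) == 4 and int(b.sum()) == 6
        assert int((a & b).sum()) == 3
        assert dsc(a, b) == pytest.approx(0.6)

    def test_both_empty(self):
        z = np.zeros((2, 2, 2), bool)
        assert dsc(z, z) == 1.0

    def test_one_empty(self):
        a = np.zeros((2, 2, 2), bool)
        b = a.copy()
        b[0, 0, 0] = True
        assert dsc(a, b) == 0.0

    def test_symmetry_property(self, rng):
        for _ in range(20):
            a = rng.random((3, 6, 6)) > 0.6
            b = rng.random((3, 6, 6)) > 0.6
            assert dsc(a, b) == dsc(b, a)
            assert 0.0 <= dsc(a, b) <= 1.0

    def test_monotone_in_intersection(self):
        # fixed |X| = |Y| = 8; growing overlap strictly raises DSC
        vals = []
        for k in range(0, 9):
            a = np.zeros((1, 4, 8), bool)
            b = np.zeros((1, 4, 8), bool)
            a[0, 0, :8] = True
            b[0, 0, :k] = True
            b[0, 1, : 8 - k] = True
            vals.append(dsc(a, b))
        assert vals == sorted(vals)
        assert vals[0] == 0.0 and vals[-1] == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))

    @given(st.integers(0, 2**27 - 1), st.integers(0, 2**27 - 1))
    @settings(max_examples=100, deadline=None)
    def test_hypothesis_range_and_symmetry(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(27)], bool).reshape(3, 3, 3)
        b = np.array([(bits_b >> i) & 1 for i in range(27)], bool).reshape(3, 3, 3)
        v = dsc(a, b)
        assert 0.0 <= v <= 1.0
        assert v == dsc(b, a)
        # closed form against integer voxel counts
        na, nb, ni = int(a.sum()), int(b.sum()), int((a & b).sum())
        expected = 1.0 if na + nb == 0 else 2.0 * ni / (na + nb)
        assert v == pytest.approx(expected)


# ---------------------------------------------------------------------------
# lesion matching
# ---------------------------------------------------------------------------

class TestMatchLesions:
    def test_identical_prediction(self, rng):
        mask = np.zeros((4, 8, 8), bool)
        mask[1:3, 2:5, 2:5] = True
        mask[0, 6:8, 6:8] = True
        comps = extract_components(mask, SPACING)
        res = match_lesions(comps, comps)
        assert res.counts.tp == len(comps)
        assert res.counts.fp == 0
        assert res.counts.fn == 0
        assert all(v == 1.0 for v in res.lesion_dsc.values())

    def test_half_coverage_on_one_slice_is_tp(self):
        gt = np.zeros((3, 4, 4), bool)
        gt[0, 0, :4] = True   # slice 0: area 4
        gt[1, 0, :4] = True   # slice 1: area 4
        pred = np.zeros((3, 4, 4), bool)
        pred[0, 0, :2] = True  # covers exactly 50% of slice-0 area
        res = match_lesions([comp_from_mask(pred)], [comp_from_mask(gt)])
        assert res.counts.tp == 1 and res.counts.fp == 0 and res.counts.fn == 0

    def test_forty_percent_everywhere_is_fp_and_fn(self):
        gt = np.zeros((2, 5, 5), bool)
        gt[:, 0, :5] = True   # area 5 per slice
        pred = np.zeros((2, 5, 5), bool)
        pred[:, 0, :2] = True  # 2/5 = 40% per slice
        res = match_lesions([comp_from_mask(pred)], [comp_from_mask(gt)])
        assert res.counts.tp == 0 and res.counts.fp == 1 and res.counts.fn == 1

    def test_gt_detected_at_most_once(self):
        gt = np.zeros((1, 6, 6), bool)
        gt[0, 2, 1:5] = True
        p1 = np.zeros_like(gt)
        p1[0, 2, 1:3] = True
        p2 = np.zeros_like(gt)
        p2[0, 2, 3:5] = True
        res = match_lesions([comp_from_mask(p1), comp_from_mask(p2)],
                            [comp_from_mask(gt)])
        assert res.counts.tp == 1  # one truth lesion, counted once
        assert res.counts.fp == 0
        # per-lesion DSC uses the union of both matching predictions
        assert res.lesion_dsc[0] == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        a = comp_from_mask(np.ones((1, 2, 2), bool))
        b = comp_from_mask(np.ones((1, 3, 3), bool))
        with pytest.raises(ValueError, match="grids"):
            match_lesions([a], [b])

    def test_brute_force_equivalence_200_trials(self):
        rng = np.random.default_rng(123)
        for trial in range(200):
            shape = tuple(rng.integers(4, 17, size=3))
            pred = ndi_smooth_random(rng, shape, 0.12)
            gt = ndi_smooth_random(rng, shape, 0.12)
            pred_comps = extract_components(pred, SPACING)
            gt_comps = extract_components(gt, SPACING)
            res = match_lesions(pred_comps, gt_comps)
            pred_sets = [{tuple(v) for v in c.indices} for c in pred_comps]
            gt_sets = [{tuple(v) for v in c.indices} for c in gt_comps]
            tp, fp, fn, _ = brute_lesion_match(pred_sets, gt_sets)
            assert (res.counts.tp, res.counts.fp, res.counts.fn) == (tp, fp, fn), trial
            # bookkeeping identity: TP + FN = number of truth lesions
            assert res.counts.tp + res.counts.fn == len(gt_comps)


def ndi_smooth_random(rng, shape, p):
    """Sparse random blobs: random voxels dilated once."""
    from scipy import ndimage
    seeds = rng.random(shape) < p
    return ndimage.binary_dilation(seeds, iterations=1)


# ---------------------------------------------------------------------------
# component extraction vs oracle
# ---------------------------------------------------------------------------

class TestComponents:
    def test_empty_mask(self):
        assert extract_components(np.zeros((3, 3, 3), bool), SPACING) == []

    def test_corner_touching_voxels(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True  # touch only at a corner
        assert len(extract_components(mask, SPACING, connectivity=26)) == 1
        assert len(extract_components(mask, SPACING, connectivity=6)) == 2

    def test_min_volume_arithmetic(self):
        # 3x3x1 blob at 0.75 x 0.75 x 4 mm: 9 * 2.25 = 20.25 mm^3 < 25 -> dropped
        mask = np.zeros((3, 5, 5), bool)
        mask[1, 1:4, 1:4] = True
        spacing = (4.0, 0.75, 0.75)
        comps = extract_components(mask, spacing)
        assert comps[0].volume_mm3 == pytest.approx(20.25)
        assert extract_components(mask, spacing, min_volume_mm3=25.0) == []

    def test_slice_areas_and_bbox(self):
        mask = np.zeros((4, 6, 6), bool)
        mask[1, 1:4, 2:5] = True
        mask[2, 2:3, 2:4] = True
        c = extract_components(mask, SPACING)[0]
        assert c.slice_areas == {1: 9, 2: 2}
        assert c.bbox == ((1, 2), (1, 3), (2, 4))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            shape = tuple(rng.integers(3, 13, size=3))
            mask = rng.random(shape) < 0.25
            for conn26 in (True, False):
                got = extract_components(mask, SPACING, connectivity=26 if conn26 else 6)
                want = brute_components(mask, conn26=conn26)
                got_sets = sorted([frozenset(map(tuple, c.indices)) for c in got],
                                  key=sorted)
                want_sets = sorted([frozenset(c) for c in want], key=sorted)
                assert got_sets == want_sets


# ---------------------------------------------------------------------------
# sextant matching
# ---------------------------------------------------------------------------

def block_sextants(shape=(6, 6, 6)):
    """Simple synthetic 6-way partition of the full grid: 3 z-bands x 2 halves."""
    nz, ny, nx = shape
    zz, _, xx = np.indices(shape)
    bands = [zz < nz // 3, (zz >= nz // 3) & (zz < 2 * nz // 3), zz >= 2 * nz // 3]
    out = {}
    for bi, band in enumerate(bands):
        out[f"right-{bi}"] = band & (xx < nx // 2)
        out[f"left-{bi}"] = band & (xx >= nx // 2)
    return out


class TestMatchSextants:
    def test_lesion_inside_one_sextant(self):
        sextants = block_sextants()
        lesion = np.zeros((6, 6, 6), bool)
        lesion[0, 1, 0:2] = True  # fully in right band 0
        labels = lesion_sextant_labels(comp_from_mask(lesion), sextants)
        assert labels == {"right-0"}

    def test_fifty_fifty_split_marks_both(self):
        sextants = block_sextants()
        lesion = np.zeros((6, 6, 6), bool)
        lesion[0, 1, 2:4] = True  # two voxels: one in each half
        labels = lesion_sextant_labels(comp_from_mask(lesion), sextants)
        assert labels == {"right-0", "left-0"}

    def test_small_lesion_fails_both_clauses(self):
        # lesion holds 30% of its own volume in the sextant, fills 10% of it
        sextants = {"a": np.zeros((1, 10, 10), bool), "b": np.zeros((1, 10, 10), bool)}
        sextants["a"][0, :, :2] = True   # 20 voxels
        sextants["b"][0, :, 2:] = True   # 80 voxels
        lesion = np.zeros((1, 10, 10), bool)
        lesion[0, 0, 0:2] = True   # 2 voxels in a  (2/20 = 10% occupancy)
        lesion[0, 1:5, 2] = True   # 4 voxels in b
        # coverage in a: 2/6 = 33% < 50%; occupancy 10% < 50% -> not labeled
        labels = lesion_sextant_labels(comp_from_mask(lesion), sextants)
        assert "a" not in labels

    def test_counts_sum_to_six(self, rng):
        sextants = block_sextants()
        for _ in range(20):
            pred = rng.random((6, 6, 6)) < 0.1
            gt = rng.random((6, 6, 6)) < 0.1
            pc = extract_components(pred, SPACING)
            gc = extract_components(gt, SPACING)
            counts = match_sextants(pc, gc, sextants)
            assert counts.tp + counts.fp + counts.fn + counts.tn == 6

    def test_overlapping_sextants_rejected(self):
        sextants = {f"s{i}": np.ones((2, 2, 2), bool) for i in range(6)}
        with pytest.raises(ValueError, match="overlap"):
            match_sextants([], [], sextants)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(77)
        sextants = block_sextants()
        sx_sets = {k: {tuple(v) for v in np.argwhere(m)} for k, m in sextants.items()}
        for _ in range(50):
            lesion = ndi_smooth_random(rng, (6, 6, 6), 0.05)
            if not lesion.any():
                continue
            for comp in extract_components(lesion, SPACING):
                got = lesion_sextant_labels(comp, sextants)
                want = brute_sextant_labels({tuple(v) for v in comp.indices}, sx_sets)
                assert got == want


# ---------------------------------------------------------------------------
# patient level
# ---------------------------------------------------------------------------

class TestPatientLevel:
    def _lesion(self, z, y, x, shape=(4, 8, 8)):
        m = np.zeros(shape, bool)
        m[z, y: y + 2, x: x + 2] = True
        return m

    def test_one_of_three_detected_is_tp(self):
        gts = [comp_from_mask(self._lesion(0, 0, 0)),
               comp_from_mask(self._lesion(1, 4, 4)),
               comp_from_mask(self._lesion(3, 0, 4))]
        pred = [comp_from_mask(self._lesion(0, 0, 0))]  # detects only lesion 1
        assert classify_patient(pred, gts) == "TP"

    def test_negative_patient_with_prediction_is_fp(self):
        assert classify_patient([comp_from_mask(self._lesion(0, 0, 0))], []) == "FP"

    def test_negative_patient_no_prediction_is_tn(self):
        assert classify_patient([], []) == "TN"

    def test_positive_patient_nothing_detected_is_fn(self):
        gts = [comp_from_mask(self._lesion(0, 0, 0))]
        pred = [comp_from_mask(self._lesion(3, 4, 4))]  # elsewhere
        assert classify_patient(pred, gts) == "FN"

    def test_aggregation(self):
        counts = patient_level(["TP", "TP", "FN", "FP", "TN", "TN"])
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 1, 1, 2)

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            patient_level(["TP", "??"])


# ---------------------------------------------------------------------------
# rates, Clopper-Pearson, McNemar
# ---------------------------------------------------------------------------

class TestRatesWithCi:
    def test_sensitivity_84_of_88(self):
        counts = ConfusionCounts("lesion", tp=84, fp=0, fn=4)
        table = rates_with_ci(counts)
        row = table.rows["sensitivity"]
        assert row.percent == pytest.approx(95.45, abs=0.01)
        assert round(row.percent, 1) == 95.5

    def test_perfect_sensitivity_ci_hits_100(self):
        counts = ConfusionCounts("lesion", tp=41, fp=0, fn=0)
        row = rates_with_ci(counts).rows["sensitivity"]
        assert row.percent == 100.0
        assert row.ci_high == 100.0

    def test_ci_bounds_order(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson(k, n)
            assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_zero_denominator_omitted(self):
        counts = ConfusionCounts("patient", tp=0, fp=2, fn=0, tn=5)
        table = rates_with_ci(counts)
        assert "sensitivity" not in table.rows
        assert "specificity" in table.rows

    def test_lesion_level_has_no_specificity(self):
        counts = ConfusionCounts("lesion", tp=5, fp=1, fn=1, tn=None)
        table = rates_with_ci(counts)
        assert set(table.rows) == {"sensitivity"}

    @given(st.integers(1, 500).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n))))
    @settings(max_examples=100, deadline=None)
    def test_hypothesis_cp_interval_contains_point(self, nk):
        n, k = nk
        lo, hi = clopper_pearson(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0
        # nesting: a wider alpha gives a narrower interval
        lo90, hi90 = clopper_pearson(k, n, alpha=0.10)
        assert lo90 >= lo and hi90 <= hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 4)

    def test_coverage_simulation(self):
        # 10,000 replicates at p = 0.9, n = 88: true p inside CI >= ~95%
        rng = np.random.default_rng(2024)
        ks = rng.binomial(88, 0.9, size=10000)
        uniq, counts = np.unique(ks, return_counts=True)
        covered = 0
        for k, c in zip(uniq, counts):
            lo, hi = clopper_pearson(int(k), 88)
            if lo <= 0.9 <= hi:
                covered += c
        assert covered / 10000 >= 0.95 - 0.01  # Monte-Carlo slack


class TestMcnemar:
    def test_symmetric_discordance(self):
        a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)
        b = ~a
        p, bb, cc, method = mcnemar(a, b)
        assert (bb, cc) == (5, 5)
        assert p == 1.0
        assert method == "exact"

    def test_exact_tail_enumeration(self):
        # b = 10, c = 2: p = 2 * P(X <= 2 | n=12, 1/2) = 158/4096
        a = np.concatenate([np.ones(12, bool), np.zeros(2, bool), np.ones(4, bool)])
        b = np.concatenate([np.zeros(10, bool), np.ones(2, bool), np.ones(2, bool),
                            np.zeros(0, bool), np.ones(4, bool)])
        p, bb, cc, method = mcnemar(a, b)
        assert (bb, cc) == (10, 2)
        assert method == "exact"
        assert p == pytest.approx(158 / 4096)

    def test_chi_square_closed_form(self):
        # b = 60, c = 20: X2 = (40-1)^2/80 = 19.0125
        a = np.concatenate([np.ones(60, bool), np.zeros(20, bool), np.ones(20, bool)])
        b = np.concatenate([np.zeros(60, bool), np.ones(20, bool), np.ones(20, bool)])
        p, bb, cc, method = mcnemar(a, b)
        assert (bb, cc) == (60, 20)
        assert method == "chi2"
        assert p == pytest.approx(float(stats.chi2.sf(19.0125, 1)))
        assert p < 0.001

    def test_no_discordance(self):
        a = np.ones(10, bool)
        p, bb, cc, method = mcnemar(a, a)
        assert p == 1.0 and method == "degenerate"

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            mcnemar(np.ones(3, bool), np.ones(4, bool))
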