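"""Tests of RP segmentation, morphology and the five-metric suite."""

from datetime import date, timedelta

import numpy as np
import pytest

from t2rp.segmentation import (
    cohort_summary,
    dice,
    evaluate_patient,
    filter_segmentation_cohort,
    hd95,
    seg_auc,
    sensitivity_precision,
    smooth_mask,
    threshold_rp_mask,
    SegmentationReport,
)
from t2rp.types import DoseGrid, PatientCase, QuantitativeMap, StructureSet

SPACING = (1.0, 1.0, 1.0)


def _case(gap_days, grade=1, pid="p01"):
    masks = {"lung": np.ones((4, 4, 2), dtype=bool)}
    structs = StructureSet(masks=masks, spacing_mm=SPACING)
    dose = DoseGrid(np.zeros((4, 4, 2)), "physical", 3, 13.5, SPACING)
    d0 = date(2024, 6, 1)
    return PatientCase(
        id=pid, series=None, structures=structs, dose=dose, rp_grade=grade,
        fupct_date=d0, fupmri_date=d0 + timedelta(days=gap_days),
    )


class TestEligibility:
    def test_strictly_more_than_four_weeks_excluded(self):
        cases = [_case(10, pid="a"), _case(30, pid="b"), _case(28, pid="c")]
        kept = filter_segmentation_cohort(cases)
        assert [c.id for c in kept] == ["a", "c"]

    def test_infinite_gap_keeps_all_rp(self):
        cases = [_case(100, pid="a"), _case(500, pid="b"), _case(3, grade=0, pid="c")]
        kept = filter_segmentation_cohort(cases, max_gap_days=np.inf)
        assert [c.id for c in kept] == ["a", "b"]  # non-RP never eligible

    def test_missing_dates_reported_with_ids(self):
        broken = _case(5, pid="px")
        broken.fupmri_date = None
        with pytest.raises(ValueError, match="px"):
            filter_segmentation_cohort([broken])


class TestThreshold:
    def test_cutoff_selects_upper_values(self):
        values = np.zeros((2, 2, 1))
        values[0, 0, 0], values[0, 1, 0] = 5.0, 10.0
        qmap = QuantitativeMap(values, SPACING)
        roi = np.zeros((2, 2, 1), dtype=bool)
        roi[0, :, 0] = True
        out = threshold_rp_mask(qmap, 7.0, roi)
        assert out[0, 1, 0] and not out[0, 0, 0]

    def test_cutoff_below_minimum_returns_roi(self, rng):
        values = rng.uniform(5, 10, (4, 4, 2))
        qmap = QuantitativeMap(values, SPACING)
        roi = rng.random((4, 4, 2)) > 0.4
        assert np.array_equal(threshold_rp_mask(qmap, 0.0, roi), roi)

    def test_count_matches_bruteforce_and_monotone_in_cutoff(self, rng):
        values = rng.normal(size=(6, 6, 3))
        valid = rng.random((6, 6, 3)) > 0.2
        qmap = QuantitativeMap(values, SPACING, valid_mask=valid)
        roi = rng.random((6, 6, 3)) > 0.4
        prev = None
        for cut in (-1.0, 0.0, 1.0):
            out = threshold_rp_mask(qmap, cut, roi)
            brute = int((roi & valid & (values >= cut)).sum())
            assert out.sum() == brute
            if prev is not None:
                assert out.sum() <= prev  # raising the cut-off shrinks the mask
            prev = out.sum()


class TestSmoothing:
    def test_empty_mask_unchanged(self):
        empty = np.zeros((8, 8, 2), dtype=bool)
        assert not smooth_mask(empty, coronal_axis=2).any()

    def test_single_voxel_dilation_erosion_oracle(self):
        """6x6 dilation of a point is a 6x6 square; 3x3 erosion leaves 4x4."""
        mask = np.zeros((16, 16, 1), dtype=bool)
        mask[8, 8, 0] = True
        dilated_only = smooth_mask(mask, coronal_axis=2, dilation_px=6, erosion_px=1)
        assert dilated_only.sum() == 36
        out = smooth_mask(mask, coronal_axis=2)
        idx = np.argwhere(out[:, :, 0])
        assert idx.shape[0] == 16  # 4x4 square
        spans = idx.max(axis=0) - idx.min(axis=0)
        assert np.all(spans == 3)

    def test_closes_small_gaps(self):
        mask = np.zeros((20, 20, 1), dtype=bool)
        mask[5:15, 5:9, 0] = True
        mask[5:15, 11:15, 0] = True  # 2-px gap between the halves
        out = smooth_mask(mask, coronal_axis=2)
        assert np.all(out[6:13, 9:11, 0])  # gap filled

    def test_slicewise_never_crosses_slices(self):
        mask = np.zeros((12, 12, 3), dtype=bool)
        mask[6, 6, 1] = True
        out = smooth_mask(mask, coronal_axis=2)
        assert not out[:, :, 0].any() and not out[:, :, 2].any()


class TestOverlapMetrics:
    def test_dice_examples(self):
        a = np.zeros((10, 10, 1), dtype=bool)
        b = np.zeros_like(a)
        a[:5], b[:5] = True, True
        assert dice(a, b) == 1.0
        b[:] = False
        b[5:] = True
        assert dice(a, b) == 0.0
        assert dice(np.zeros_like(a), np.zeros_like(a)) == 1.0

    def test_dice_half_overlap(self):
        # |A| = |B| = 100 voxels, overlap 50 -> DSC 0.5
        a = np.zeros((20, 10, 1), dtype=bool)
        b = np.zeros_like(a)
        a[0:10], b[5:15] = True, True
        assert a.sum() == b.sum() == 100 and (a & b).sum() == 50
        assert dice(a, b) == pytest.approx(0.5)

    def test_dice_symmetry(self, rng):
        for _ in range(10):
            a = rng.random((6, 6, 3)) > 0.5
            b = rng.random((6, 6, 3)) > 0.5
            assert dice(a, b) == dice(b, a)

    def test_sensitivity_precision_examples(self):
        truth = np.zeros((10, 10, 1), dtype=bool)
        truth[2:6, 2:6, 0] = True
        assert sensitivity_precision(truth, truth) == (1.0, 1.0)
        pred = np.zeros_like(truth)
        pred[2:6, 2:10, 0] = True  # superset, double volume
        sens, prec = sensitivity_precision(pred, truth)
        assert sens == 1.0 and prec == pytest.approx(0.5)
        empty = np.zeros_like(truth)
        sens, prec = sensitivity_precision(empty, truth)
        assert sens == 0.0 and np.isnan(prec)  # empty prediction: undefined precision

    def test_confusion_matrix_oracle(self, rng):
        for _ in range(10):
            pred = rng.random((5, 5, 4)) > 0.5
            truth = rng.random((5, 5, 4)) > 0.5
            roi = rng.random((5, 5, 4)) > 0.3
            tp = (pred & truth & roi).sum()
            fn = (~pred & truth & roi).sum()
            fp = (pred & ~truth & roi).sum()
            sens, prec = sensitivity_precision(pred, truth, roi)
            if tp + fn:
                assert sens == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert prec == pytest.approx(tp / (tp + fp))


class TestSegAuc:
    def test_indicator_score_is_perfect(self):
        truth = np.zeros((6, 6, 2), dtype=bool)
        truth[1:3, 1:3, 0] = True
        score = QuantitativeMap(truth.astype(float), SPACING)
        roi = np.ones_like(truth)
        assert seg_auc(score, truth, roi) == 1.0

    def test_constant_score_is_chance(self):
        truth = np.zeros((6, 6, 2), dtype=bool)
        truth[1:3, 1:3, 0] = True
        score = QuantitativeMap(np.full(truth.shape, 3.3), SPACING)
        assert seg_auc(score, truth, np.ones_like(truth)) == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self, rng):
        values = rng.normal(size=(10, 10, 2))
        truth = rng.random((10, 10, 2)) > 0.7
        roi = np.ones_like(truth)
        score = QuantitativeMap(values, SPACING)
        got = seg_auc(score, truth, roi)
        pos = values[truth]
        neg = values[~truth]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert got == pytest.approx(wins / (pos.size * neg.size))

    def test_one_class_roi_rejected(self):
        truth = np.ones((3, 3, 1), dtype=bool)
        score = QuantitativeMap(np.zeros((3, 3, 1)), SPACING)
        with pytest.raises(ValueError):
            seg_auc(score, truth, np.ones_like(truth))


class TestHd95:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8, 4), dtype=bool)
        m[2:6, 2:6, 1:3] = True
        assert hd95(m, m, SPACING) == 0.0

    def test_two_points_on_axis(self):
        a = np.zeros((20, 4, 4), dtype=bool)
        b = np.zeros_like(a)
        a[2, 1, 1] = True
        b[12, 1, 1] = True
        assert hd95(a, b, SPACING) == pytest.approx(10.0)

    def test_symmetry_and_empty_flagged(self, rng):
        a = rng.random((7, 7, 4)) > 0.6
        b = rng.random((7, 7, 4)) > 0.6
        a[3, 3, 1] = b[2, 2, 2] = True
        assert hd95(a, b, SPACING) == hd95(b, a, SPACING)
        assert np.isnan(hd95(a, np.zeros_like(a), SPACING))

    def test_matches_bruteforce_percentile(self, rng):
        spacing = (1.6, 1.6, 8.8)
        for _ in range(5):
            a = np.zeros((12, 12, 5), dtype=bool)
            b = np.zeros_like(a)
            ca, cb = rng.integers(3, 9, 2), rng.integers(3, 9, 2)
            a[ca[0] - 2 : ca[0] + 2, ca[1] - 2 : ca[1] + 2, 1:3] = True
            b[cb[0] - 3 : cb[0] + 1, cb[1] - 1 : cb[1] + 3, 2:4] = True
            got = hd95(a, b, spacing)

            def boundary(m):
                pts = []
                for p in np.argwhere(m):
                    for ax in range(3):
                        for step in (-1, 1):
                            q = p.copy()
                            q[ax] += step
                            if (q < 0).any() or (q >= np.array(m.shape)).any() or not m[tuple(q)]:
                                pts.append(p)
                                break
                        else:
                            continue
                        break
                return np.array(pts) * spacing

            pa, pb = boundary(a), boundary(b)
            d_ab = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
            d_ba = [min(np.linalg.norm(p - q) for q in pa) for p in pb]
            assert got == pytest.approx(np.percentile(d_ab + d_ba, 95), abs=1e-9)


class TestEvaluate:
    def _rp_case(self):
        shape = (20, 20, 4)
        lung = np.ones(shape, dtype=bool)
        truth = np.zeros(shape, dtype=bool)
        truth[4:14, 4:14, 1:3] = True
        v20 = np.ones(shape, dtype=bool)
        values = np.where(truth, 20.0, -5.0)
        structs = StructureSet(
            masks={"lung": lung, "rp_truth": truth, "v20": v20}, spacing_mm=SPACING
        )
        case = PatientCase(
            id="rp1", series=None, structures=structs,
            dose=DoseGrid(np.zeros(shape), "physical", 3, 13.5, SPACING),
            rp_grade=2, fupct_date=date(2024, 1, 1), fupmri_date=date(2024, 1, 10),
        )
        case.t2_corr = QuantitativeMap(values, SPACING)
        return case

    def test_selfconsistent_phantom_scores_high(self):
        report = evaluate_patient(self._rp_case(), cutoff_ms=7.0)
        # smoothing grows the thresholded mask by a ~1.5 px rim, so the DSC
        # against an exactly matching truth is high but below 1
        assert report.dsc > 0.7
        assert report.sensitivity == 1.0
        assert report.hd95_mm <= 5.0
        assert report.seg_auc == 1.0

    def test_infinite_cutoff_empty_prediction(self):
        report = evaluate_patient(self._rp_case(), cutoff_ms=np.inf)
        assert report.n_voxels_pred == 0
        assert report.dsc == 0.0
        assert report.sensitivity == 0.0
        assert np.isnan(report.precision)
        assert np.isnan(report.hd95_mm)

    def test_single_report_summary_is_itself(self):
        r = SegmentationReport("p", 0.4, 0.5, 0.6, 0.7, 12.0, 10, 20)
        s = cohort_summary([r])
        assert s == {
            "dsc": 0.4, "sensitivity": 0.5, "precision": 0.6,
            "seg_auc": 0.7, "hd95_mm": 12.0,
        }
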