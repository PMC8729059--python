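"""Confusion-matrix metrics, cutoff recall, and detection mAP."""

import numpy as np
import pytest

from cytoscreen import (
    Bethesda,
    BinaryCounts,
    BoundingBox,
    ConfusionMatrix,
    DataError,
    cutoff_recall,
    detection_map,
    metrics,
    one_vs_rest,
    report,
)
from cytoscreen.evaluation import round_half_up_percent


def brute_force_counts(counts, k):
    """Cell-by-cell one-vs-rest tally."""
    tp = fp = fn = tn = 0
    c = counts.shape[0]
    for i in range(c):
        for j in range(c):
            v = int(counts[i, j])
            if i == k and j == k:
                tp += v
            elif i == k:
                fn += v
            elif j == k:
                fp += v
            else:
                tn += v
    return tp, fp, fn, tn


class TestOneVsRest:
    def test_reference_stage2_nilm_counts(self, stage2_cm):
        c = one_vs_rest(stage2_cm, "NILM")
        assert (c.tp, c.fp, c.fn, c.tn) == (24, 2, 2, 177)

    def test_identity_matrix_has_no_confusions(self):
        cm = ConfusionMatrix(np.eye(6, dtype=int) * 5)
        for name in cm.class_order:
            c = one_vs_rest(cm, name)
            assert c.fp == c.fn == 0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.integers(0, 30, size=(3, 3))
            cm = ConfusionMatrix(m, class_order=("a", "b", "c"))
            for k in range(3):
                c = one_vs_rest(cm, k)
                assert (c.tp, c.fp, c.fn, c.tn) == brute_force_counts(m, k)

    def test_conservation(self, stage1_cm, stage2_cm):
        for cm in (stage1_cm, stage2_cm):
            for name in cm.class_order:
                assert one_vs_rest(cm, name).total == cm.total

    def test_unknown_class_rejected(self, stage1_cm):
        with pytest.raises(IndexError):
            one_vs_rest(stage1_cm, "AGC")


class TestMetrics:
    def test_reference_stage2_nilm_values(self, stage2_cm):
        m = metrics(one_vs_rest(stage2_cm, "NILM"))
        assert round_half_up_percent(m.precision) == 92.3
        assert round_half_up_percent(m.recall) == 92.3
        assert round_half_up_percent(m.f_measure) == 92.3
        assert round_half_up_percent(m.accuracy) == 98.0

    def test_perfect_counts(self):
        m = metrics(BinaryCounts(tp=10, fp=0, fn=0, tn=0))
        assert (m.accuracy, m.precision, m.recall, m.f_measure) == (1, 1, 1, 1)

    def test_zero_denominator_convention(self):
        m = metrics(BinaryCounts(tp=0, fp=0, fn=5, tn=5))
        assert m.precision == 0.0 and "precision" in m.undefined
        assert m.recall == 0.0 and "recall" not in m.undefined
        assert m.f_measure == 0.0 and "f_measure" in m.undefined
        all_zero = metrics(BinaryCounts(0, 0, 0, 0))
        assert all_zero.accuracy == 0.0 and "accuracy" in all_zero.undefined


class TestReport:
    def test_macro_values_for_reference_matrices(self, stage1_cm, stage2_cm):
        r1, r2 = report(stage1_cm), report(stage2_cm)
        assert round_half_up_percent(r1.macro_f_measure) == 54.9
        assert round_half_up_percent(r2.macro_f_measure) == 70.5
        assert round_half_up_percent(r2.macro_precision) == 71.8
        assert round_half_up_percent(r2.macro_recall) == 70.8

    def test_macro_invariant_under_class_permutation(self, stage2_cm):
        perm = [3, 0, 5, 1, 4, 2]
        cm_p = ConfusionMatrix(
            stage2_cm.counts[np.ix_(perm, perm)],
            class_order=tuple(stage2_cm.class_order[i] for i in perm),
        )
        rp, r = report(cm_p), report(stage2_cm)
        assert rp.macro_f_measure == pytest.approx(r.macro_f_measure, abs=1e-12)
        assert rp.per_class["SCC"].recall == pytest.approx(
            r.per_class["SCC"].recall, abs=1e-12
        )

    def test_empty_matrix_rejected(self):
        with pytest.raises(DataError):
            ConfusionMatrix(np.zeros((0, 0), dtype=int), class_order=())


class TestCutoffRecall:
    def test_stage1_ascus_cutoff_is_perfect(self, stage1_cm):
        assert cutoff_recall(stage1_cm, "ASC-US") == 1.0

    def test_identity_matrix_any_cutoff(self):
        cm = ConfusionMatrix(np.eye(6, dtype=int) * 3)
        for name in cm.class_order:
            assert cutoff_recall(cm, name) == 1.0

    def test_matches_quadrant_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            m = rng.integers(0, 20, size=(6, 6))
            cm = ConfusionMatrix(m)
            for cut in range(1, 6):
                tp = m[cut:, cut:].sum()
                fn = m[cut:, :cut].sum()
                expected = tp / (tp + fn) if tp + fn else 0.0
                assert cutoff_recall(cm, cut) == pytest.approx(expected, abs=1e-12)


class TestCsvRoundTrip:
    def test_round_trip(self, stage1_cm, tmp_path):
        path = tmp_path / "cm.csv"
        stage1_cm.to_csv(path)
        back = ConfusionMatrix.from_csv(path)
        assert np.array_equal(back.counts, stage1_cm.counts)
        assert back.class_order == stage1_cm.class_order

    def test_reference_totals(self, stage1_cm, stage2_cm):
        assert stage1_cm.total == 222
        assert stage2_cm.total == 205


def gt_box(cx, cy, label=Bethesda.HSIL):
    return BoundingBox(cx=cx, cy=cy, w=0.2, h=0.2, class_label=label)


def pred_box(cx, cy, conf, label=Bethesda.HSIL):
    return BoundingBox(cx=cx, cy=cy, w=0.2, h=0.2, class_label=label, confidence=conf)


class TestDetectionMap:
    def test_perfect_predictions(self):
        gt = {"a": [gt_box(0.3, 0.3), gt_box(0.7, 0.7, Bethesda.SCC)]}
        preds = {
            "a": [pred_box(0.3, 0.3, 1.0), pred_box(0.7, 0.7, 1.0, Bethesda.SCC)]
        }
        res = detection_map(preds, gt)
        assert res.map == pytest.approx(1.0)
        assert set(res.per_class_ap) == {"HSIL", "SCC"}

    def test_no_predictions(self):
        gt = {"a": [gt_box(0.3, 0.3)]}
        assert detection_map({"a": []}, gt).map == 0.0

    def test_duplicate_detection_ap_hand_computed(self):
        """TP, duplicate-FP, TP ranking gives all-points AP = 5/6."""
        gt = {"a": [gt_box(0.3, 0.3), gt_box(0.7, 0.7)]}
        preds = {
            "a": [
                pred_box(0.3, 0.3, 0.9),
                pred_box(0.31, 0.3, 0.8),  # duplicate of first ground truth
                pred_box(0.7, 0.7, 0.7),
            ]
        }
        res = detection_map(preds, gt)
        assert res.per_class_ap["HSIL"] == pytest.approx(5 / 6, abs=1e-9)

    def test_invariant_to_confidence_rescaling(self):
        gt = {"a": [gt_box(0.3, 0.3), gt_box(0.7, 0.7)]}
        preds = {
            "a": [pred_box(0.3, 0.3, 0.9), pred_box(0.5, 0.5, 0.6),
                  pred_box(0.7, 0.7, 0.3)]
        }
        res1 = detection_map(preds, gt)
        scaled = {
            "a": [
                BoundingBox(
                    cx=p.cx, cy=p.cy, w=p.w, h=p.h,
                    class_label=p.class_label, confidence=p.confidence / 2,
                )
                for p in preds["a"]
            ]
        }
        res2 = detection_map(scaled, gt)
        assert res1.map == pytest.approx(res2.map, abs=1e-12)

    def test_no_ground_truth_rejected(self):
        with pytest.raises(DataError):
            detection_map({"a": [pred_box(0.5, 0.5, 0.9)]}, {"a": []})

    def test_invalid_iou_threshold(self):
        gt = {"a": [gt_box(0.3, 0.3)]}
        with pytest.raises(ValueError):
            detection_map({"a": []}, gt, iou_threshold=1.5)
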