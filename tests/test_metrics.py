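"""Detection metrics: matching, average precision against a brute-force
oracle, mAP aggregation and the fold summary statistics."""

import statistics

import numpy as np
import pytest

from lemonsurf.arch import Detection
from lemonsurf.metrics import (GroundTruthBox, average_precision, evaluate,
                               fold_aggregate, map_range, match_detections,
                               precision_recall, render_tp_fp_fn,
                               FN_COLOR, FP_COLOR, TP_COLOR)


def det(conf, box, cid=0):
    return Detection(cid, conf, box)


def gt(box, cid=0):
    return GroundTruthBox(cid, box)


UNIT = (0.0, 0.0, 10.0, 10.0)


class TestMatching:
    def test_perfect_single_match(self):
        m = match_detections([det(0.9, UNIT)], [gt(UNIT)], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        assert m.matched_iou[0] == pytest.approx(1.0)

    def test_low_iou_is_fp_plus_fn(self):
        m = match_detections([det(0.9, (0, 0, 10, 3))], [gt(UNIT)], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_second_detection_on_same_gt_is_fp(self):
        d1 = det(0.9, (0, 0, 10, 6))       # IoU 0.6
        d2 = det(0.8, (0, 0, 10, 5.5))     # IoU 0.55
        m = match_detections([d1, d2], [gt(UNIT)], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.det_status == [True, False]

    def test_class_mismatch_never_matches(self):
        m = match_detections([det(0.9, UNIT, cid=1)], [gt(UNIT, cid=0)], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_one_to_one_tp_bounded(self, rng):
        for _ in range(20):
            dets = [det(float(c), _rand_box(rng)) for c in rng.random(5)]
            gts = [gt(_rand_box(rng)) for _ in range(3)]
            m = match_detections(dets, gts, 0.3)
            assert m.tp <= min(len(dets), len(gts))
            assert sum(m.gt_matched) == m.tp


def _rand_box(rng, span=20.0):
    x0, y0 = rng.random(2) * span
    w, h = rng.random(2) * span / 2 + 1
    return (float(x0), float(y0), float(x0 + w), float(y0 + h))


def brute_force_ap(confs, flags, n_gt):
    """Independent AP oracle: enumerate every confidence cutoff, compute
    (P, R) pointwise, and integrate sum_k (R_k - R_{k-1}) * max_{R>=R_k} P."""
    pairs = sorted(zip(confs, flags), key=lambda t: -t[0])
    pr = []
    tp = fp = 0
    for c, f in pairs:
        tp += bool(f)
        fp += not f
        pr.append((tp / (tp + fp), tp / n_gt))
    ap, prev_r = 0.0, 0.0
    seen_r = sorted({r for _, r in pr})
    for r in seen_r:
        p_at = max((p for p, rr in pr if rr >= r), default=0.0)
        ap += (r - prev_r) * p_at
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_single_tp_on_single_gt(self):
        assert average_precision([0.9], [True], 1) == 1.0

    def test_tp_then_fp_with_two_gts_is_half(self):
        assert average_precision([0.9, 0.8], [True, False], 2) == pytest.approx(0.5)

    def test_no_detections_zero(self):
        assert average_precision([], [], 3) == 0.0

    def test_undefined_without_ground_truth(self):
        with pytest.raises(ValueError):
            average_precision([0.9], [True], 0)

    def test_matches_brute_force_oracle_on_500_random_instances(self, rng):
        for _ in range(500):
            n_gt = int(rng.integers(1, 5))
            n_det = int(rng.integers(0, 7))
            confs = np.round(rng.random(n_det), 3).tolist()
            # flags consistent with one-to-one matching: at most n_gt TPs
            flags = (rng.random(n_det) < 0.5)
            while flags.sum() > n_gt:
                flags[np.flatnonzero(flags)[-1]] = False
            ours = average_precision(confs, flags.tolist(), n_gt)
            ref = brute_force_ap(confs, flags.tolist(), n_gt)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_geometric_instances_match_oracle(self, rng):
        """End-to-end: random boxes through greedy matching, then AP both ways."""
        for _ in range(100):
            gts = [gt(_rand_box(rng)) for _ in range(int(rng.integers(1, 5)))]
            dets = [det(float(np.round(c, 3)), _rand_box(rng))
                    for c in rng.random(int(rng.integers(0, 7)))]
            m = match_detections(dets, gts, 0.5)
            confs = [d.confidence for d in dets]
            ours = average_precision(confs, m.det_status, len(gts))
            assert ours == pytest.approx(
                brute_force_ap(confs, m.det_status, len(gts)), abs=1e-12)

    def test_101point_close_to_all_points_on_dense_curve(self, rng):
        confs = rng.random(200).tolist()
        flags = (rng.random(200) < 0.6).tolist()
        a = average_precision(confs, flags, 150, method="all_points")
        b = average_precision(confs, flags, 150, method="101point")
        assert abs(a - b) < 0.02


class TestAggregation:
    def test_map_range_examples(self):
        assert map_range([1.0] * 10) == 1.0
        assert map_range([0.0] * 10) == 0.0
        assert map_range(np.arange(1.0, 0.05, -0.1)) == pytest.approx(0.55)
        with pytest.raises(ValueError):
            map_range([1.0] * 9)

    def test_fold_aggregate_closed_form(self):
        agg = fold_aggregate([1, 2, 3, 4, 5])
        assert agg.mu == 3.0
        assert agg.sigma == pytest.approx(np.sqrt(2.0))

    def test_fold_aggregate_constant_is_zero_sigma(self):
        agg = fold_aggregate([4.2] * 5)
        assert agg.sigma == 0.0

    def test_fold_aggregate_against_independent_implementation(self):
        vals = [87.5, 88.0, 90.0, 86.5, 88.0]
        agg = fold_aggregate(vals)
        assert agg.mu == pytest.approx(statistics.fmean(vals))
        assert agg.sigma == pytest.approx(statistics.pstdev(vals))

    def test_fold_aggregate_requires_five(self):
        with pytest.raises(ValueError):
            fold_aggregate([1, 2, 3])

    def test_precision_recall_formulas(self):
        assert precision_recall(3, 1, 2) == (0.75, 0.6)
        assert precision_recall(0, 0, 0) == (0.0, 0.0)


class TestEvaluate:
    def _toy(self):
        dets = [[det(0.9, UNIT, 0), det(0.8, (20, 20, 30, 30), 1)]]
        gts = [[gt(UNIT, 0), gt((20, 20, 30, 30), 1)]]
        return dets, gts

    def test_perfect_detector_scores_one(self):
        dets, gts = self._toy()
        rep = evaluate(dets, gts, num_classes=2)
        assert rep.map50 == 1.0
        assert rep.map50_95 == 1.0
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_map_invariant_to_class_relabeling(self, rng):
        dets = [[det(float(c), _rand_box(rng), int(k))
                 for c, k in zip(rng.random(6), rng.integers(0, 2, 6))]]
        gts = [[gt(_rand_box(rng), int(k)) for k in [0, 0, 1, 1]]]
        rep = evaluate(dets, gts, num_classes=2)
        swap_d = [[Detection(1 - d.class_id, d.confidence, d.box)
                   for d in dets[0]]]
        swap_g = [[GroundTruthBox(1 - g.class_id, g.box) for g in gts[0]]]
        rep2 = evaluate(swap_d, swap_g, num_classes=2)
        assert rep.map50 == pytest.approx(rep2.map50)
        assert rep.map50_95 == pytest.approx(rep2.map50_95)

    def test_class_without_ground_truth_excluded_from_mean(self):
        dets = [[det(0.9, UNIT, 0)]]
        gts = [[gt(UNIT, 0)]]
        rep = evaluate(dets, gts, num_classes=2)
        assert rep.map50 == 1.0       # class 1 undefined, not counted as 0
        assert (1, 0.5) not in rep.ap


class TestRendering:
    def test_tp_fp_fn_colors(self):
        img = np.zeros((60, 60, 3), np.uint8)
        dets = [det(0.9, (5, 25, 15, 35), 0),       # TP
                det(0.8, (40, 40, 50, 50), 1)]      # FP (no gt there)
        gts = [gt((5, 25, 15, 35), 0), gt((25, 5, 35, 15), 0)]  # second: FN
        m = match_detections(dets, gts, 0.5)
        out = render_tp_fp_fn(img, dets, gts, m)
        assert (out == np.array(TP_COLOR)).all(axis=-1).any()
        assert (out == np.array(FP_COLOR)).all(axis=-1).any()
        assert (out == np.array(FN_COLOR)).all(axis=-1).any()
        assert img.sum() == 0    # input untouched

    def test_perfect_detections_render_only_green(self):
        img = np.zeros((40, 40, 3), np.uint8)
        dets = [det(0.9, (5, 8, 15, 18), 0)]
        gts = [gt((5, 8, 15, 18), 0)]
        m = match_detections(dets, gts, 0.5)
        out = render_tp_fp_fn(img, dets, gts, m)
        assert (out == np.array(TP_COLOR)).all(axis=-1).any()
        assert not (out == np.array(FP_COLOR)).all(axis=-1).any()
        assert not (out == np.array(FN_COLOR)).all(axis=-1).any()

    def test_no_detections_renders_all_gts_blue(self):
        img = np.zeros((40, 40, 3), np.uint8)
        gts = [gt((5, 8, 15, 18), 0), gt((20, 20, 30, 30), 1)]
        m = match_detections([], gts, 0.5)
        out = render_tp_fp_fn(img, [], gts, m)
        assert not (out == np.array(TP_COLOR)).all(axis=-1).any()
        assert (out == np.array(FN_COLOR)).all(axis=-1).any()
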