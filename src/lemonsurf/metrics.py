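"""Detection metrics: greedy IoU matching, precision / recall, average
precision as the area under the precision-recall curve, mAP@50 and
mAP@50-95, and the 5-fold mean / population standard deviation summary.

Precision = TP / (TP + FP); Recall = TP / (TP + FN).  AP integrates the
PR curve (all-point interpolation with the monotone precision envelope;
a 101-point grid is available as the COCO-style alternative).  mAP is the
unweighted mean of per-class APs; classes without ground truth are
excluded.  The fold summary uses the population (divide-by-k) standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arch import Detection, iou_matrix

IOU_RANGE = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class GroundTruthBox:
    class_id: int
    box: tuple  # xyxy pixels


@dataclass
class MatchResult:
    """Outcome of matching one image's detections to its ground truths."""
    det_status: list          # per detection: True = TP, False = FP
    gt_matched: list          # per ground truth: matched?
    matched_iou: dict         # det index -> IoU of its match

    @property
    def tp(self):
        return sum(self.det_status)

    @property
    def fp(self):
        return len(self.det_status) - self.tp

    @property
    def fn(self):
        return len(self.gt_matched) - sum(self.gt_matched)


def match_detections(dets, gts, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching by descending confidence.

    A detection is a true positive iff it shares the class of, and has
    IoU >= threshold with, a not-yet-matched ground truth; among candidates
    the highest-IoU unmatched ground truth wins, ties broken by index.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    det_status = [False] * len(dets)
    gt_matched = [False] * len(gts)
    matched_iou = {}
    if gts:
        gt_boxes = np.asarray([g.box for g in gts], dtype=np.float64)
    for di in order:
        det = dets[di]
        if not gts:
            continue
        ious = iou_matrix(np.asarray([det.box], dtype=np.float64), gt_boxes)[0]
        best_gi, best_iou = -1, -1.0
        for gi, gt in enumerate(gts):
            if gt_matched[gi] or gt.class_id != det.class_id:
                continue
            # strict > keeps the lowest gt index on ties
            if ious[gi] >= iou_threshold and ious[gi] > best_iou:
                best_gi, best_iou = gi, ious[gi]
        if best_gi >= 0:
            det_status[di] = True
            gt_matched[best_gi] = True
            matched_iou[di] = float(best_iou)
    return MatchResult(det_status, gt_matched, matched_iou)


def precision_recall(tp: int, fp: int, fn: int):
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def average_precision(confidences, is_tp, n_gt: int,
                      method: str = "all_points") -> float:
    """Area under the precision-recall curve for one class.

    confidences / is_tp: per-detection score and TP flag over the whole
    evaluation set; n_gt: number of ground truths of the class.
    """
    if n_gt == 0:
        raise ValueError("AP undefined for a class with no ground truth")
    if len(confidences) == 0:
        return 0.0
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.asarray(is_tp, dtype=np.float64)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone precision envelope over the full curve
    r = np.concatenate([[0.0], recall, [1.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    if method == "all_points":
        idx = np.where(r[1:] != r[:-1])[0]
        return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    if method == "101point":
        # step evaluation: precision of the envelope at the first recall >= g
        grid = np.linspace(0, 1, 101)
        idx = np.minimum(np.searchsorted(r, grid, side="left"), p.size - 1)
        return float(np.mean(p[idx]))
    raise ValueError(f"unknown AP method {method!r}")


@dataclass
class EvalReport:
    """Per-class AP at each IoU threshold plus the summary scalars."""
    ap: dict = field(default_factory=dict)       # (class_id, iou) -> AP
    map50: float = 0.0
    map50_95: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    per_class_ap50: dict = field(default_factory=dict)

    def to_dict(self):
        return {"mAP50": self.map50, "mAP50_95": self.map50_95,
                "precision": self.precision, "recall": self.recall,
                "per_class_AP50": dict(self.per_class_ap50)}


def evaluate(detections_per_image, gts_per_image, num_classes: int = 2,
             iou_thresholds=IOU_RANGE, pr_iou: float = 0.5,
             method: str = "all_points") -> EvalReport:
    """Full evaluation over a set of images.

    detections_per_image: list over images of lists of Detection;
    gts_per_image: matching list of lists of GroundTruthBox.
    Precision/recall are reported at IoU = ``pr_iou``.
    """
    report = EvalReport()
    n_gt = {c: sum(sum(1 for g in gts if g.class_id == c)
                   for gts in gts_per_image) for c in range(num_classes)}
    # precision / recall at the reporting threshold, over all classes
    tp_tot = fp_tot = fn_tot = 0
    for dets, gts in zip(detections_per_image, gts_per_image):
        m = match_detections(dets, gts, pr_iou)
        tp_tot += m.tp
        fp_tot += m.fp
        fn_tot += m.fn
    for thr in iou_thresholds:
        per_class = {}
        for c in range(num_classes):
            if n_gt[c] == 0:
                continue    # AP undefined; excluded from the class mean
            confs, flags = [], []
            for dets, gts in zip(detections_per_image, gts_per_image):
                cdets = [d for d in dets if d.class_id == c]
                cgts = [g for g in gts if g.class_id == c]
                m = match_detections(cdets, cgts, thr)
                confs.extend(d.confidence for d in cdets)
                flags.extend(m.det_status)
            per_class[c] = average_precision(confs, flags, n_gt[c], method)
            report.ap[(c, float(thr))] = per_class[c]
        if np.isclose(thr, pr_iou):
            report.per_class_ap50 = dict(per_class)
    ap50 = [report.ap[(c, 0.5)] for c in range(num_classes) if (c, 0.5) in report.ap]
    report.map50 = float(np.mean(ap50)) if ap50 else 0.0
    all_aps = [v for v in report.ap.values()]
    report.map50_95 = float(np.mean([
        np.mean([report.ap[(c, float(t))] for c in range(num_classes)
                 if (c, float(t)) in report.ap])
        for t in iou_thresholds])) if all_aps else 0.0
    report.precision, report.recall = precision_recall(tp_tot, fp_tot, fn_tot)
    return report


def map_range(ap_by_threshold) -> float:
    """Unweighted mean over the 10 IoU thresholds (each already a class mean)."""
    vals = list(ap_by_threshold)
    if len(vals) != len(IOU_RANGE):
        raise ValueError(f"expected {len(IOU_RANGE)} thresholds, got {len(vals)}")
    return float(np.mean(vals))


@dataclass(frozen=True)
class FoldAggregate:
    mu: float
    sigma: float


def fold_aggregate(values) -> FoldAggregate:
    """Mean and population (divide-by-5) standard deviation over 5 folds."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size != 5:
        raise ValueError(f"expected exactly 5 fold values, got {vals.size}")
    mu = float(vals.mean())
    sigma = float(np.sqrt(((vals - mu) ** 2).mean()))
    return FoldAggregate(mu, sigma)


TP_COLOR = (0, 200, 0)      # green
FN_COLOR = (30, 60, 230)    # blue
FP_COLOR = (230, 30, 30)    # red


def render_tp_fp_fn(image: np.ndarray, dets, gts, match: MatchResult,
                    thickness: int = 2) -> np.ndarray:
    """Annotate a copy of `image`: TP green, FP red, missed ground truth blue."""
    out = image.copy()
    for di, det in enumerate(dets):
        color = TP_COLOR if match.det_status[di] else FP_COLOR
        _draw_box(out, det.box, color, thickness)
        _draw_tag(out, det.box, color, f"{det.class_id}:{det.confidence:.2f}")
    for gi, gt in enumerate(gts):
        if not match.gt_matched[gi]:
            _draw_box(out, gt.box, FN_COLOR, thickness)
            _draw_tag(out, gt.box, FN_COLOR, str(gt.class_id))
    return out


def _draw_box(img, box, color, t):
    h, w = img.shape[:2]
    x0, y0, x1, y1 = (int(round(v)) for v in box)
    x0, x1 = np.clip([x0, x1], 0, w - 1)
    y0, y1 = np.clip([y0, y1], 0, h - 1)
    img[y0:y0 + t, x0:x1 + 1] = color
    img[max(y1 - t + 1, 0):y1 + 1, x0:x1 + 1] = color
    img[y0:y1 + 1, x0:x0 + t] = color
    img[y0:y1 + 1, max(x1 - t + 1, 0):x1 + 1] = color


_GLYPHS = {c: i for i, c in enumerate("0123456789:.")}


def _draw_tag(img, box, color, text):
    """Minimal 3x5-dot glyph tag above the box corner (class/conf label)."""
    dots = {
        "0": "111101101101111", "1": "010110010010111", "2": "111001111100111",
        "3": "111001111001111", "4": "101101111001001", "5": "111100111001111",
        "6": "111100111101111", "7": "111001010010010", "8": "111101111101111",
        "9": "111101111001111", ":": "000010000010000", ".": "000000000010000",
    }
    h, w = img.shape[:2]
    x = int(round(box[0]))
    y = int(round(box[1])) - 7
    for ch in text:
        pat = dots.get(ch)
        if pat is None:
            x += 4
            continue
        for r in range(5):
            for c in range(3):
                if pat[r * 3 + c] == "1":
                    yy, xx = y + r, x + c
                    if 0 <= yy < h and 0 <= xx < w:
                        img[yy, xx] = color
        x += 4
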