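"""Training losses for the anchor-free head.

The stack is the standard one for this detector family: a task-aligned
assigner picks, per ground-truth box, the top-k grid cells whose centres
lie inside the box, scored by classification^alpha * IoU^beta; assigned
cells contribute a complete-IoU (CIoU) box loss and a distribution-focal
(DFL) edge loss, and every cell contributes binary cross-entropy against
its (soft) target score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch import iou_matrix
from .heads import (dfl_expectation, distances_to_boxes,
                    flatten_head_outputs, grid_anchors)
from .nn import tensor as T


@dataclass(frozen=True)
class LossWeights:
    box: float = 7.5
    cls: float = 0.5
    dfl: float = 1.5


@dataclass(frozen=True)
class AssignerConfig:
    topk: int = 10
    alpha: float = 0.5
    beta: float = 6.0


def assign_targets(pred_scores, pred_boxes, points, gts_per_image,
                   num_classes, cfg: AssignerConfig = AssignerConfig()):
    """Task-aligned assignment (pure numpy, no gradients).

    pred_scores: [N,A,nc] sigmoid scores; pred_boxes: [N,A,4] xyxy pixels;
    points: [A,2] cell centres; gts_per_image: list of [M,5] (class,xyxy).

    Returns fg_mask [N,A] bool, target_boxes [N,A,4], target_scores
    [N,A,nc] (soft), target_dist_gt [N,A] index of assigned gt.
    """
    n, a, nc = pred_scores.shape
    fg = np.zeros((n, a), dtype=bool)
    tboxes = np.zeros((n, a, 4), dtype=np.float32)
    tscores = np.zeros((n, a, nc), dtype=np.float32)
    tcls = np.zeros((n, a), dtype=np.int64)
    for bi in range(n):
        gts = gts_per_image[bi]
        if gts is None or len(gts) == 0:
            continue
        cls_ids = gts[:, 0].astype(int)
        gt_boxes = gts[:, 1:5].astype(np.float32)
        m = len(gts)
        inside = ((points[None, :, 0] > gt_boxes[:, None, 0])
                  & (points[None, :, 0] < gt_boxes[:, None, 2])
                  & (points[None, :, 1] > gt_boxes[:, None, 1])
                  & (points[None, :, 1] < gt_boxes[:, None, 3]))   # [M,A]
        overlaps = iou_matrix(gt_boxes, pred_boxes[bi])            # [M,A]
        cls_score = pred_scores[bi][:, cls_ids].T                  # [M,A]
        metric = (cls_score ** cfg.alpha) * (overlaps ** cfg.beta)
        metric = np.where(inside, metric, 0.0)
        # top-k candidate cells per gt
        cand = np.zeros_like(inside)
        k = min(cfg.topk, a)
        topk_idx = np.argpartition(-metric, k - 1, axis=1)[:, :k]
        rows = np.repeat(np.arange(m), k)
        sel = topk_idx.ravel()
        keep = metric[rows, sel] > 0
        cand[rows[keep], sel[keep]] = True
        # a cell claimed by several gts goes to the highest-IoU one
        claimed = cand.sum(axis=0)
        if (claimed > 1).any():
            multi = np.where(claimed > 1)[0]
            best = overlaps[:, multi].argmax(axis=0)
            cand[:, multi] = False
            cand[best, multi] = True
        gt_of = cand.argmax(axis=0)        # [A]
        fg_bi = cand.any(axis=0)
        # per-gt normalised target score: metric / max_metric * max_iou
        pos_metric = np.where(cand, metric, 0.0)
        pos_iou = np.where(cand, overlaps, 0.0)
        max_met = pos_metric.max(axis=1, keepdims=True)
        max_iou = pos_iou.max(axis=1, keepdims=True)
        norm = pos_metric * max_iou / np.maximum(max_met, 1e-9)    # [M,A]
        score_of = norm.max(axis=0)
        fg[bi] = fg_bi
        tboxes[bi][fg_bi] = gt_boxes[gt_of[fg_bi]]
        tcls[bi] = np.where(fg_bi, cls_ids[gt_of], 0)
        tscores[bi][fg_bi, cls_ids[gt_of[fg_bi]]] = score_of[fg_bi]
    return fg, tboxes, tscores, tcls


def ciou_terms(pred, target):
    """Complete IoU between matched [F,4] xyxy (pred: Tensor, target: array)."""
    px0, py0 = T.select_col(pred, 0), T.select_col(pred, 1)
    px1, py1 = T.select_col(pred, 2), T.select_col(pred, 3)
    tx0, ty0, tx1, ty1 = (target[:, i] for i in range(4))
    iw = T.clamp_min(T.minimum(px1, tx1) - T.maximum(px0, tx0), 0.0)
    ih = T.clamp_min(T.minimum(py1, ty1) - T.maximum(py0, ty0), 0.0)
    inter = T.mul(iw, ih)
    pw, ph = T.clamp_min(px1 - px0, 1e-6), T.clamp_min(py1 - py0, 1e-6)
    tw, th = np.maximum(tx1 - tx0, 1e-6), np.maximum(ty1 - ty0, 1e-6)
    union = T.add(T.add(T.mul(pw, ph), tw * th), T.mul(inter, -1.0))
    iou = T.div(inter, T.clamp_min(union, 1e-9))
    # enclosing box diagonal and centre distance
    cw = T.maximum(px1, tx1) - T.minimum(px0, tx0)
    ch = T.maximum(py1, ty1) - T.minimum(py0, ty0)
    c2 = T.clamp_min(T.add(T.mul(cw, cw), T.mul(ch, ch)), 1e-9)
    dx = (px0 + px1) * 0.5 - (tx0 + tx1) * 0.5
    dy = (py0 + py1) * 0.5 - (ty0 + ty1) * 0.5
    rho2 = T.add(T.mul(dx, dx), T.mul(dy, dy))
    # aspect-ratio consistency
    v = T.mul(T.power(T.atan(T.Tensor(tw / th)) - T.atan(T.div(pw, ph)), 2.0),
              4.0 / np.pi ** 2)
    alpha = T.div(v.detach(), T.clamp_min(
        T.add(T.Tensor(1.0) - iou.detach(), v.detach()), 1e-9)).detach()
    return iou - T.div(rho2, c2) - T.mul(v, alpha.numpy())


def compute_loss(raw, gts_per_image, strides, num_classes,
                 reg_max=16, weights: LossWeights = LossWeights(),
                 assigner: AssignerConfig = AssignerConfig()):
    """Total training loss for one batch.

    raw: per-level (box_logits, cls_logits) Tensors from the head;
    gts_per_image: list of [M,5] arrays (class, x0, y0, x1, y1) in input
    pixels.  Returns (loss Tensor scalar, components dict of floats).
    """
    shapes = [tuple(b.shape[2:]) for b, _ in raw]
    points, stride = grid_anchors(shapes, strides)
    box_l, cls_l = flatten_head_outputs(raw)          # [N,A,4R], [N,A,nc]
    n, a = cls_l.shape[0], cls_l.shape[1]

    with T.no_grad():
        dist_det = dfl_expectation(box_l.detach(), reg_max).numpy()
    boxes_det = distances_to_boxes(dist_det, points, stride)
    with np.errstate(over="ignore"):    # saturated logits -> exact 0/1
        scores_det = 1.0 / (1.0 + np.exp(-cls_l.numpy()))
    fg, tboxes, tscores, _ = assign_targets(scores_det, boxes_det, points,
                                            gts_per_image, num_classes,
                                            assigner)

    score_sum = max(float(tscores.sum()), 1.0)
    cls_loss = T.mul(T.bce_with_logits(cls_l, tscores), 1.0 / score_sum)

    flat_fg = np.flatnonzero(fg.reshape(-1))
    comps = {}
    if flat_fg.size:
        w_fg = tscores.reshape(n * a, -1).sum(axis=1)[flat_fg]
        w_norm = w_fg / score_sum
        pd = T.gather_rows(box_l.reshape(n * a, 4 * reg_max), flat_fg)
        probs = T.softmax(pd.reshape(flat_fg.size, 4, reg_max), axis=-1)
        proj = np.arange(reg_max, dtype=np.float32).reshape(reg_max, 1)
        dist_fg = T.matmul(probs, proj).reshape(flat_fg.size, 4)
        pts_fg = points[flat_fg % a]
        sx = stride[flat_fg % a].astype(np.float32)
        tb = tboxes.reshape(n * a, 4)[flat_fg]
        # predicted box in pixels (differentiable through dist_fg)
        px0 = T.Tensor(pts_fg[:, 0]) - T.mul(T.select_col(dist_fg, 0), sx)
        py0 = T.Tensor(pts_fg[:, 1]) - T.mul(T.select_col(dist_fg, 1), sx)
        px1 = T.Tensor(pts_fg[:, 0]) + T.mul(T.select_col(dist_fg, 2), sx)
        py1 = T.Tensor(pts_fg[:, 1]) + T.mul(T.select_col(dist_fg, 3), sx)
        pbox = T.stack_cols([px0, py0, px1, py1])
        ciou = ciou_terms(pbox, tb)
        box_loss = T.reduce_sum(T.mul(T.add(T.mul(ciou, -1.0), 1.0), w_norm))
        # DFL: cross-entropy against the two bins bracketing the true distance
        tdist = np.stack([
            (pts_fg[:, 0] - tb[:, 0]) / sx, (pts_fg[:, 1] - tb[:, 1]) / sx,
            (tb[:, 2] - pts_fg[:, 0]) / sx, (tb[:, 3] - pts_fg[:, 1]) / sx,
        ], axis=1)
        tdist = np.clip(tdist, 0, reg_max - 1 - 1e-3)
        tl = np.floor(tdist).astype(np.int64)
        wl = (tl + 1 - tdist).astype(np.float32)
        wr = 1.0 - wl
        logp = T.log_softmax(pd.reshape(flat_fg.size, 4, reg_max), axis=-1)
        f_idx = np.arange(flat_fg.size)[:, None]
        e_idx = np.arange(4)[None, :]
        nll = T.add(T.mul(T.getitem(logp, (f_idx, e_idx, tl)), -wl),
                    T.mul(T.getitem(logp, (f_idx, e_idx, tl + 1)), -wr))
        dfl_loss = T.reduce_sum(T.mul(T.reduce_mean(nll, axis=1),
                                      w_norm))
    else:
        box_loss = T.Tensor(0.0)
        dfl_loss = T.Tensor(0.0)

    total = T.mul(T.add(T.add(T.mul(box_loss, weights.box),
                              T.mul(cls_loss, weights.cls)),
                        T.mul(dfl_loss, weights.dfl)), float(n))
    comps = {"box": float(box_loss.numpy()) * weights.box,
             "cls": float(cls_loss.numpy()) * weights.cls,
             "dfl": float(dfl_loss.numpy()) * weights.dfl,
             "total": float(total.numpy()),
             "num_fg": int(flat_fg.size)}
    for k, v in comps.items():
        if isinstance(v, float) and not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component {k}: {comps}")
    return total, comps
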