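"""Decoupled anchor-free detection head with distribution-focal box branch.

Per feature level the head emits, for every grid cell, 4 x ``reg_max``
logits describing discrete distributions over the distances from the cell
centre to the four box edges (in stride units), plus one classification
logit per class.  Box decoding takes the expectation of each softmaxed
distribution ("distribution focal" regression).
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Conv2d, ConvBlock, Module, ModuleList, Sequential
from .nn import tensor as T


class Detect(Module):
    def __init__(self, num_classes: int, channels: tuple, reg_max: int = 16):
        super().__init__()
        self.nc = num_classes
        self.reg_max = reg_max
        self.nl = len(channels)
        c2 = max(16, channels[0] // 4, reg_max * 4)
        c3 = max(channels[0], min(num_classes, 100))
        self.box_branches = ModuleList([
            Sequential(ConvBlock(c, c2, 3), ConvBlock(c2, c2, 3),
                       Conv2d(c2, 4 * reg_max, 1, bias=True))
            for c in channels
        ])
        self.cls_branches = ModuleList([
            Sequential(ConvBlock(c, c3, 3), ConvBlock(c3, c3, 3),
                       Conv2d(c3, num_classes, 1, bias=True))
            for c in channels
        ])

    def initialise_biases(self, strides, img_size=640):
        """Prior-aware bias init: box offsets start near 1 stride unit and
        class logits near the expected object density (~5 objects/image)."""
        for box, cls, s in zip(self.box_branches, self.cls_branches, strides):
            box[-1].bias.data[...] = 1.0
            cls[-1].bias.data[...] = math.log(5 / self.nc / (img_size / s) ** 2)

    def forward(self, feats):
        """feats: list of [N,C,H,W] neck outputs, shallow->deep.
        Returns list of (box_logits [N,4*reg_max,H,W], cls_logits [N,nc,H,W])."""
        return [(self.box_branches[i](f), self.cls_branches[i](f))
                for i, f in enumerate(feats)]


def grid_anchors(shapes, strides):
    """Cell-centre anchor points and per-anchor strides for a set of levels.

    shapes: list of (H, W); returns (points [A,2] in input pixels at cell
    centres, stride [A]).
    """
    pts, strs = [], []
    for (h, w), s in zip(shapes, strides):
        xs = (np.arange(w, dtype=np.float32) + 0.5)
        ys = (np.arange(h, dtype=np.float32) + 0.5)
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1) * s)
        strs.append(np.full(h * w, s, dtype=np.float32))
    return np.concatenate(pts), np.concatenate(strs)


def flatten_head_outputs(raw):
    """Stack per-level head outputs into [N, A, 4*reg_max] and [N, A, nc]."""
    boxes, clss = [], []
    for box, cls in raw:
        n, cb, h, w = box.shape
        boxes.append(T.transpose(box.reshape(n, cb, h * w), (0, 2, 1)))
        n, cc, h, w = cls.shape
        clss.append(T.transpose(cls.reshape(n, cc, h * w), (0, 2, 1)))
    return T.concat(boxes, axis=1), T.concat(clss, axis=1)


def dfl_expectation(box_logits, reg_max=16):
    """Expected edge distances from DFL logits.

    box_logits: Tensor [N, A, 4*reg_max] -> Tensor [N, A, 4] distances
    (l, t, r, b) in stride units.
    """
    n, a, _ = box_logits.shape
    probs = T.softmax(box_logits.reshape(n, a, 4, reg_max), axis=-1)
    proj = np.arange(reg_max, dtype=np.float32).reshape(reg_max, 1)
    return T.matmul(probs, proj).reshape(n, a, 4)


def distances_to_boxes(dist, points, stride):
    """(l,t,r,b) stride-unit distances -> xyxy pixel boxes (numpy)."""
    lt = points - dist[..., :2] * stride[:, None]
    rb = points + dist[..., 2:] * stride[:, None]
    return np.concatenate([lt, rb], axis=-1)
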