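"""Model family assembly: nano-scale anchor-free detector with optional
switchable atrous convolution (SAC), CBAM attention and the stride-4
small-object (SOD) head — eight ablation variants from three flags.

Insertion points (recorded in the variant config):
  * CBAM: one module after every C2f output (backbone and neck) and after
    SPPF.
  * SAC:  the C2f blocks of the backbone stages listed in ``sac_stages``
    (default: stage 4, the deepest) become C2f-SAC, i.e. their bottleneck
    3x3 convolutions are switchable atrous convolutions.
These placements meet the family's parameter budgets at nano scale with
two classes: 3.01 M baseline, 2.93 M with SOD, 3.08 M with CBAM and
3.35 M for the full model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .blocks import C2f, SPPF, scale_channels, scale_depth
from .cbam import CBAM
from .heads import (Detect, dfl_expectation, distances_to_boxes,
                    flatten_head_outputs, grid_anchors)
from .nn import ConvBlock, Identity, Module, set_init_seed
from .nn import tensor as T
from .p2 import NeckLayout, SODNeck
from .sac import build_c2f_sac


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelVariant:
    """Declarative description of one of the eight ablation architectures."""
    use_sac: bool = False
    use_sod: bool = False
    use_cbam: bool = False
    num_classes: int = 2
    depth_multiple: float = 0.33
    width_multiple: float = 0.25
    max_channels: int = 1024
    input_size: int = 640
    sac_rate: int = 3
    sac_stages: tuple = (4,)
    cbam_ratio: int = 8
    cbam_sites: str = "after_every_c2f_and_sppf"

    def __post_init__(self):
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be >= 1")
        if self.depth_multiple <= 0 or self.width_multiple <= 0:
            raise ConfigurationError("scale multipliers must be positive")
        stride = self.required_stride()
        if self.input_size % stride:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by {stride}")
        if self.use_sac and not all(1 <= s <= 4 for s in self.sac_stages):
            raise ConfigurationError("sac_stages must be within backbone stages 1-4")

    def required_stride(self) -> int:
        # the P2 grid must stay integral through the extra up/down path
        return 64 if self.use_sod else 32

    @property
    def name(self) -> str:
        bits = [n for f, n in [(self.use_sac, "sac"), (self.use_sod, "sod"),
                               (self.use_cbam, "cbam")] if f]
        return "baseline" if not bits else "+".join(bits)

    def to_yaml(self, path):
        d = asdict(self)
        d["sac_stages"] = list(self.sac_stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelVariant":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sac_stages" in d:
            d["sac_stages"] = tuple(d["sac_stages"])
        return cls(**d)


@dataclass(frozen=True)
class Detection:
    """One decoded detection in pixel coordinates of the evaluated image."""
    class_id: int
    confidence: float
    box: tuple  # (x_min, y_min, x_max, y_max)

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError("degenerate box")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence outside [0,1]")


class Backbone(Module):
    """Stem + four conv/C2f stages + SPPF; exposes stride-4..32 taps."""

    def __init__(self, v: ModelVariant):
        super().__init__()
        s = lambda c: scale_channels(c, v.width_multiple, v.max_channels)
        d = lambda n: scale_depth(n, v.depth_multiple)
        att = (lambda c: CBAM(c, v.cbam_ratio)) if v.use_cbam else (lambda c: Identity())
        sac_at = set(v.sac_stages) if v.use_sac else set()

        def stage_c2f(idx, c, n):
            if idx in sac_at:
                return build_c2f_sac(c, c, n, shortcut=True, rate=v.sac_rate)
            return C2f(c, c, n, shortcut=True)

        self.stem = ConvBlock(3, s(64), 3, 2)
        self.down1 = ConvBlock(s(64), s(128), 3, 2)
        self.c2f1 = stage_c2f(1, s(128), d(3))
        self.att1 = att(s(128))
        self.down2 = ConvBlock(s(128), s(256), 3, 2)
        self.c2f2 = stage_c2f(2, s(256), d(6))
        self.att2 = att(s(256))
        self.down3 = ConvBlock(s(256), s(512), 3, 2)
        self.c2f3 = stage_c2f(3, s(512), d(6))
        self.att3 = att(s(512))
        self.down4 = ConvBlock(s(512), s(1024), 3, 2)
        self.c2f4 = stage_c2f(4, s(1024), d(3))
        self.att4 = att(s(1024))
        self.sppf = SPPF(s(1024), s(1024))
        self.att5 = att(s(1024))

    def forward(self, x):
        x = self.down1(self.stem(x))
        p2 = self.att1(self.c2f1(x))
        p3 = self.att2(self.c2f2(self.down2(p2)))
        p4 = self.att3(self.c2f3(self.down3(p3)))
        p5 = self.att5(self.sppf(self.att4(self.c2f4(self.down4(p4)))))
        return p2, p3, p4, p5


class PANNeck(Module):
    """Baseline three-level FPN+PAN fusion (strides 8/16/32)."""

    def __init__(self, s, n, attention=None):
        super().__init__()
        att = attention or (lambda c: Identity())
        self.td_p4 = C2f(s(1024) + s(512), s(512), n)
        self.td_p3 = C2f(s(512) + s(256), s(256), n)
        self.att_td_p4 = att(s(512))
        self.att_td_p3 = att(s(256))
        self.down_p3 = ConvBlock(s(256), s(256), 3, 2)
        self.bu_p4 = C2f(s(256) + s(512), s(512), n)
        self.down_p4 = ConvBlock(s(512), s(512), 3, 2)
        self.bu_p5 = C2f(s(512) + s(1024), s(1024), n)
        self.att_bu_p4 = att(s(512))
        self.att_bu_p5 = att(s(1024))
        self.layout = NeckLayout(
            active_levels=("P3", "P4", "P5"),
            channels={"P3": s(256), "P4": s(512), "P5": s(1024)},
        )

    def forward(self, taps):
        _, p3, p4, p5 = taps
        t4 = self.att_td_p4(self.td_p4(T.concat([T.upsample2x(p5), p4], axis=1)))
        t3 = self.att_td_p3(self.td_p3(T.concat([T.upsample2x(t4), p3], axis=1)))
        o4 = self.att_bu_p4(self.bu_p4(T.concat([self.down_p3(t3), t4], axis=1)))
        o5 = self.att_bu_p5(self.bu_p5(T.concat([self.down_p4(o4), p5], axis=1)))
        return {"P3": t3, "P4": o4, "P5": o5}


class DetectorNetwork(Module):
    """Backbone + neck + decoupled head for one ModelVariant."""

    def __init__(self, variant: ModelVariant):
        super().__init__()
        self.variant = variant
        s = lambda c: scale_channels(c, variant.width_multiple, variant.max_channels)
        n = scale_depth(3, variant.depth_multiple)
        att = ((lambda c: CBAM(c, variant.cbam_ratio)) if variant.use_cbam
               else None)
        self.backbone = Backbone(variant)
        self.neck = SODNeck(s, n, att) if variant.use_sod else PANNeck(s, n, att)
        self.layout: NeckLayout = self.neck.layout
        self.levels = self.layout.active_levels
        self.strides = self.layout.head_strides()
        self.head = Detect(variant.num_classes, self.layout.head_channels())
        self.head.initialise_biases(self.strides, variant.input_size)
        self.reg_max = self.head.reg_max

    def _check_input(self, x):
        h, w = x.shape[2], x.shape[3]
        stride = max(self.strides)
        if h % stride or w % stride:
            raise ValueError(f"input {h}x{w} not divisible by stride {stride}")

    def forward_features(self, x) -> dict:
        """Neck outputs per active level, {'P3': Tensor[N,C,H/8,W/8], ...}."""
        x = x if isinstance(x, T.Tensor) else T.Tensor(x)
        self._check_input(x)
        return self.neck(self.backbone(x))

    def forward(self, x):
        feats = self.forward_features(x)
        return self.head([feats[lv] for lv in self.levels])


def build_model(variant: ModelVariant, seed: int = 0) -> DetectorNetwork:
    """Assemble one of the eight ablation variants with seeded init."""
    set_init_seed(seed)
    return DetectorNetwork(variant)


def count_parameters(network: Module) -> int:
    """Exact number of trainable scalar weights."""
    return network.num_parameters()


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two [N,4] / [M,4] xyxy arrays."""
    if len(boxes_a) == 0 or len(boxes_b) == 0:
        return np.zeros((len(boxes_a), len(boxes_b)), dtype=np.float32)
    a = boxes_a[:, None, :]
    b = boxes_b[None, :, :]
    ix0 = np.maximum(a[..., 0], b[..., 0])
    iy0 = np.maximum(a[..., 1], b[..., 1])
    ix1 = np.minimum(a[..., 2], b[..., 2])
    iy1 = np.minimum(a[..., 3], b[..., 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    return (inter / np.maximum(union, 1e-9)).astype(np.float32)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list:
    """Greedy non-maximum suppression by descending score; returns kept idx."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i:i + 1], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return keep


def decode_predictions(raw, strides, shapes, conf_threshold=0.25,
                       iou_threshold=0.7, max_det=300, reg_max=16):
    """Raw head outputs -> per-image lists of Detection.

    raw: list per level of (box_logits, cls_logits) Tensors;
    shapes: list of (H, W) grid sizes matching `raw`.
    """
    if not raw:
        return []
    if not (0 < conf_threshold < 1 and 0 < iou_threshold < 1):
        raise ValueError("thresholds must lie in (0,1)")
    with T.no_grad():
        box_l, cls_l = flatten_head_outputs(raw)
        dist = dfl_expectation(box_l, reg_max).numpy()
        scores = 1.0 / (1.0 + np.exp(-cls_l.numpy()))   # [N,A,nc]
    points, stride = grid_anchors(shapes, strides)
    boxes = distances_to_boxes(dist, points, stride)    # [N,A,4]
    canvas_w = shapes[0][1] * strides[0]
    canvas_h = shapes[0][0] * strides[0]
    results = []
    for bi in range(boxes.shape[0]):
        dets = []
        b = boxes[bi]
        b[:, 0::2] = np.clip(b[:, 0::2], 0, canvas_w)
        b[:, 1::2] = np.clip(b[:, 1::2], 0, canvas_h)
        for ci in range(scores.shape[2]):
            sc = scores[bi, :, ci]
            sel = np.flatnonzero(sc >= conf_threshold)
            if sel.size == 0:
                continue
            kept = nms(b[sel], sc[sel], iou_threshold)
            for k in kept[:max_det]:
                i = sel[k]
                x0, y0, x1, y1 = b[i]
                if x1 - x0 < 1e-3 or y1 - y0 < 1e-3:
                    continue
                dets.append(Detection(ci, float(sc[i]), (float(x0), float(y0),
                                                         float(x1), float(y1))))
        dets.sort(key=lambda d: -d.confidence)
        results.append(dets[:max_det])
    return results


def predict(network: DetectorNetwork, images: np.ndarray, conf_threshold=0.25,
            iou_threshold=0.7):
    """Forward + decode on an [N,3,H,W] float batch in [0,1]."""
    network.eval()
    with T.no_grad():
        raw = network(images)
    shapes = [tuple(b.shape[2:]) for b, _ in raw]
    return decode_predictions(raw, network.strides, shapes,
                              conf_threshold, iou_threshold,
                              reg_max=network.reg_max)


def letterbox(image: np.ndarray, size: int, pad_value: int = 114):
    """Aspect-preserving resize onto a size x size canvas (pad value 114).

    image: HWC uint8 or float array.  Returns (canvas, scale, (dx, dy)):
    source pixel (x, y) maps to (x*scale+dx, y*scale+dy).
    """
    h, w = image.shape[:2]
    scale = min(size / h, size / w)
    nh, nw = max(round(h * scale), 1), max(round(w * scale), 1)
    resized = _resize_bilinear(image, nh, nw)
    canvas = np.full((size, size) + image.shape[2:], pad_value,
                     dtype=resized.dtype)
    dy, dx = (size - nh) // 2, (size - nw) // 2
    canvas[dy:dy + nh, dx:dx + nw] = resized
    return canvas, scale, (dx, dy)


def _resize_bilinear(image: np.ndarray, nh: int, nw: int) -> np.ndarray:
    h, w = image.shape[:2]
    if (nh, nw) == (h, w):
        return image.copy()
    ys = (np.arange(nh) + 0.5) * h / nh - 0.5
    xs = (np.arange(nw) + 0.5) * w / nw - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0, 1)[:, None]
    wx = np.clip(xs - x0, 0, 1)[None, :]
    if image.ndim == 3:
        wy, wx = wy[..., None], wx[..., None]
    img = image.astype(np.float32)
    out = (img[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
           + img[np.ix_(y1, x0)] * wy * (1 - wx)
           + img[np.ix_(y0, x1)] * (1 - wy) * wx
           + img[np.ix_(y1, x1)] * wy * wx)
    return out.astype(image.dtype) if image.dtype == np.uint8 else out
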