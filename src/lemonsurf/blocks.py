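"""Standard building blocks of the nano-scale anchor-free detector:
split-transform-concat C2f blocks and the SPPF pooling pyramid."""

from __future__ import annotations

import math

from .nn import ConvBlock, Module, ModuleList
from .nn import tensor as T


def make_divisible(x: float, divisor: int = 8) -> int:
    return int(math.ceil(x / divisor) * divisor)


def scale_channels(c: int, width_multiple: float, max_channels: int) -> int:
    return make_divisible(min(c, max_channels) * width_multiple, 8)


def scale_depth(n: int, depth_multiple: float) -> int:
    return max(round(n * depth_multiple), 1) if n > 1 else n


class Bottleneck(Module):
    """Two 3x3 convolutions with an optional residual connection."""

    def __init__(self, c1, c2, shortcut=True, e=1.0, conv_cls=ConvBlock):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = conv_cls(c1, c_, 3)
        self.cv2 = conv_cls(c_, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return T.add(x, y) if self.add else y


class C2f(Module):
    """Cross-stage partial block: 1x1 expand, chained bottlenecks on one
    half of the channels, concat of all intermediate halves, 1x1 fuse."""

    def __init__(self, c1, c2, n=1, shortcut=False, bottleneck_conv=ConvBlock):
        super().__init__()
        self.c = int(c2 * 0.5)
        self.cv1 = ConvBlock(c1, 2 * self.c, 1)
        self.cv2 = ConvBlock((2 + n) * self.c, c2, 1)
        self.m = ModuleList([
            Bottleneck(self.c, self.c, shortcut, e=1.0, conv_cls=bottleneck_conv)
            for _ in range(n)
        ])

    def forward(self, x):
        y = self.cv1(x)
        ys = [T.narrow_channels(y, 0, self.c), T.narrow_channels(y, self.c, 2 * self.c)]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(T.concat(ys, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 stride-1 max pools."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBlock(c1, c_, 1)
        self.cv2 = ConvBlock(c_ * 4, c2, 1)
        self.k = k

    def forward(self, x):
        x = self.cv1(x)
        y1 = T.max_pool2d(x, self.k, 1, self.k // 2)
        y2 = T.max_pool2d(y1, self.k, 1, self.k // 2)
        y3 = T.max_pool2d(y2, self.k, 1, self.k // 2)
        return self.cv2(T.concat([x, y1, y2, y3], axis=1))
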