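"""Switchable Atrous Convolution (SAC).

A convolution is converted to SAC by evaluating the *same* kernel at two
atrous rates and blending the results with a learned, spatially varying
switch:

    y = S(x) * Conv(x, w, 1) + (1 - S(x)) * Conv(x, w + dw, r)

The dilated branch never owns an independent kernel: it always uses
``w + dw`` ("weight locking"), so the two branches differ only by the
trainable offset ``dw`` and the atrous rate ``r``.  The switch ``S`` is a
5x5 average pool followed by a 1x1 convolution to one channel and a
sigmoid, so S is strictly inside (0, 1) and the output is an elementwise
interpolation of the two branches.

A full SAC convolution flanks the switched component with two lightweight
global-context modules (global average pool -> channel-preserving 1x1
conv -> broadcast residual add) so the locally switched convolution sees
a globally informed signal.
"""

from __future__ import annotations

import numpy as np

from .blocks import Bottleneck, C2f
from .nn import BatchNorm2d, Conv2d, ConvBlock, Module, Parameter
from .nn import tensor as T


class GlobalContext(Module):
    """Residual global pooling context: x + conv1x1(avgpool_global(x))."""

    def __init__(self, channels: int):
        super().__init__()
        self.fc = Conv2d(channels, channels, 1, bias=True)
        # identity start: zero conv weights/bias leave the input untouched
        self.fc.weight.data[...] = 0.0

    def forward(self, x):
        pooled = T.global_avg_pool(x)
        return T.add(x, self.fc(pooled))


class SwitchableAtrousConv2d(Module):
    """The switched dual-rate component (no flanking context modules).

    Stride is fixed at 1 and padding chosen so both branches preserve the
    spatial size (dilated branch pad = r*(k-1)/2).
    """

    def __init__(self, c1, c2, k=3, rate=3):
        super().__init__()
        if rate < 2 and k > 1:
            raise ValueError("atrous rate must be >= 2")
        self.k, self.rate = k, rate
        from .nn.modules import init_uniform
        self.weight = Parameter(init_uniform((c2, c1, k, k), c1 * k * k))
        # dw starts at zero: training begins from plain-conv behaviour
        self.delta_w = Parameter(np.zeros((c2, c1, k, k), dtype=np.float32))
        # switch: 5x5 avg pool -> 1x1 conv to one channel; zero init -> S=0.5
        self.switch = Conv2d(c1, 1, 1, bias=True)
        self.switch.weight.data[...] = 0.0

    def switch_map(self, x):
        return T.sigmoid(self.switch(T.avg_pool2d(x, 5, 1, 2)))

    def forward(self, x):
        s = self.switch_map(x)
        y1 = T.conv2d(x, self.weight, None, 1, (self.k - 1) // 2, 1)
        w2 = T.add(self.weight, self.delta_w)
        y2 = T.conv2d(x, w2, None, 1, self.rate * (self.k - 1) // 2, self.rate)
        return T.add(T.mul(s, y1), T.mul(T.add(T.mul(s, -1.0), 1.0), y2))


class SAConv2d(Module):
    """Global context -> switched atrous component -> global context."""

    def __init__(self, c1, c2, k=3, rate=3):
        super().__init__()
        self.pre_context = GlobalContext(c1)
        self.sac = SwitchableAtrousConv2d(c1, c2, k, rate)
        self.post_context = GlobalContext(c2)

    def forward(self, x):
        return self.post_context(self.sac(self.pre_context(x)))


class SACBlock(Module):
    """SAConv2d + BatchNorm + SiLU; drop-in replacement for ConvBlock."""

    def __init__(self, c1, c2, k=3, stride=1, padding=None, rate=3):
        super().__init__()
        if stride != 1:
            raise ValueError("SAC blocks are stride-1 only")
        self.conv = SAConv2d(c1, c2, k, rate)
        self.bn = BatchNorm2d(c2)

    def forward(self, x):
        return T.silu(self.bn(self.conv(x)))


def build_c2f_sac(c1, c2, n=1, shortcut=True, rate=3) -> C2f:
    """C2f block whose bottleneck 3x3 convolutions are SAC convolutions.

    The split/concat topology and spatial size of plain C2f are preserved;
    only the bottleneck convolutions change, which is where the block's
    receptive field is formed.
    """
    def sac_conv(ci, co, k=3, stride=1, padding=None):
        return SACBlock(ci, co, k, stride, padding, rate=rate)

    return C2f(c1, c2, n, shortcut, bottleneck_conv=sac_conv)


def neutralise_sac(block: Module):
    """Force every SAC in `block` to its plain-conv limit: dw = 0 and the
    switch saturated to S ~= 1, so outputs reproduce a plain C2f."""
    for m in block.modules():
        if isinstance(m, SwitchableAtrousConv2d):
            m.delta_w.data[...] = 0.0
            m.switch.weight.data[...] = 0.0
            m.switch.bias.data[...] = 50.0  # sigmoid(50) == 1 in float32
        if isinstance(m, GlobalContext):
            m.fc.weight.data[...] = 0.0
            m.fc.bias.data[...] = 0.0
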