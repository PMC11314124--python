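"""Convolutional Block Attention Module (CBAM), the variant used here:
channel attention with reduction ratio 8 and a shared bias-free MLP,
followed by spatial attention with a 3x3 convolution over the pooled
channel-mean / channel-max maps.

Channel gate:   Mc = sigmoid( MLP(avgpool(x)) + MLP(maxpool(x)) )
Spatial gate:   Ms = sigmoid( conv3x3( [mean_c(x'); max_c(x')] ) )
Application:    x' = x (*) Mc ;  out = x' (*) Ms    (channel first)

Both gates are strict sigmoids, so gating never changes the tensor shape
and the output is elementwise bounded by the input in absolute value.
"""

from __future__ import annotations

from .nn import Conv2d, Module
from .nn import tensor as T


class ChannelAttention(Module):
    def __init__(self, channels: int, ratio: int = 8):
        super().__init__()
        hidden = max(channels // ratio, 1)
        self.fc1 = Conv2d(channels, hidden, 1, bias=False)
        self.fc2 = Conv2d(hidden, channels, 1, bias=False)

    def _mlp(self, v):
        return self.fc2(T.relu(self.fc1(v)))

    def forward(self, x):
        avg = T.global_avg_pool(x)
        mx = T.spatial_max(x)
        return T.sigmoid(T.add(self._mlp(avg), self._mlp(mx)))  # [N,C,1,1]


class SpatialAttention(Module):
    def __init__(self, kernel: int = 3):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, bias=True)

    def forward(self, x):
        mean_map = T.reduce_mean(x, axis=1, keepdims=True)
        max_map = T.channel_max(x)
        return T.sigmoid(self.conv(T.concat([mean_map, max_map], axis=1)))


class CBAM(Module):
    def __init__(self, channels: int, ratio: int = 8, spatial_kernel: int = 3):
        super().__init__()
        self.channel = ChannelAttention(channels, ratio)
        self.spatial = SpatialAttention(spatial_kernel)

    def forward(self, x):
        x = T.mul(x, self.channel(x))
        return T.mul(x, self.spatial(x))
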