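"""Stride-4 (P2) small-object extension of the FPN+PAN neck.

The top-down path is extended by one more upsample + concat with the
backbone's stride-4 feature (160x160 pre-scaling width 64 at 640 input),
fused by a C2f into the new stride-4 head input (pre-scaling width 128,
i.e. 160x160x128 at 640), and a bottom-up return convolution re-links the
P2 output into the P3 fusion.  P3-P5 spatial sizes are unchanged; a fourth
detection head consumes the new map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .blocks import C2f
from .nn import ConvBlock, Identity, Module
from .nn import tensor as T


@dataclass(frozen=True)
class NeckLayout:
    """Which pyramid levels the neck emits and their channel widths."""
    active_levels: tuple = ("P3", "P4", "P5")
    channels: dict = field(default_factory=dict)
    strides: dict = field(default_factory=lambda: {"P2": 4, "P3": 8, "P4": 16, "P5": 32})

    def head_channels(self):
        return tuple(self.channels[lv] for lv in self.active_levels)

    def head_strides(self):
        return tuple(self.strides[lv] for lv in self.active_levels)


class SODNeck(Module):
    """FPN+PAN neck with the extra stride-4 fusion path and P2 output.

    ``widths`` maps pre-scaling channel names to scaled widths, e.g. at
    nano scale {128: 32, 256: 64, 512: 128, 1024: 256}.
    """

    def __init__(self, s, n, attention=None):
        # s: channel scaling fn (pre-scaling width -> actual), n: C2f repeats
        super().__init__()
        att = attention or (lambda c: Identity())
        self.td_p4 = C2f(s(1024) + s(512), s(512), n)
        self.td_p3 = C2f(s(512) + s(256), s(256), n)
        self.td_p2 = C2f(s(256) + s(128), s(128), n)
        self.att_td_p4 = att(s(512))
        self.att_td_p3 = att(s(256))
        self.att_td_p2 = att(s(128))
        self.down_p2 = ConvBlock(s(128), s(128), 3, 2)
        self.bu_p3 = C2f(s(128) + s(256), s(256), n)
        self.down_p3 = ConvBlock(s(256), s(256), 3, 2)
        self.bu_p4 = C2f(s(256) + s(512), s(512), n)
        self.down_p4 = ConvBlock(s(512), s(512), 3, 2)
        self.bu_p5 = C2f(s(512) + s(1024), s(1024), n)
        self.att_bu_p3 = att(s(256))
        self.att_bu_p4 = att(s(512))
        self.att_bu_p5 = att(s(1024))
        self.layout = NeckLayout(
            active_levels=("P2", "P3", "P4", "P5"),
            channels={"P2": s(128), "P3": s(256), "P4": s(512), "P5": s(1024)},
        )

    def forward(self, taps):
        p2, p3, p4, p5 = taps  # backbone features at strides 4/8/16/32
        t4 = self.att_td_p4(self.td_p4(T.concat([T.upsample2x(p5), p4], axis=1)))
        t3 = self.att_td_p3(self.td_p3(T.concat([T.upsample2x(t4), p3], axis=1)))
        t2 = self.att_td_p2(self.td_p2(T.concat([T.upsample2x(t3), p2], axis=1)))
        o3 = self.att_bu_p3(self.bu_p3(T.concat([self.down_p2(t2), t3], axis=1)))
        o4 = self.att_bu_p4(self.bu_p4(T.concat([self.down_p3(o3), t4], axis=1)))
        o5 = self.att_bu_p5(self.bu_p5(T.concat([self.down_p4(o4), p5], axis=1)))
        return {"P2": t2, "P3": o3, "P4": o4, "P5": o5}
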