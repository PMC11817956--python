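"""Residual 3D U-net for binary tumor segmentation.

The default configuration maps a 1x128x128x64 volume through five
encoder blocks (the first at stride 1 producing 16 channels, the rest
stride 2 doubling channels) to a 256x8x8x4 bottleneck, then through
four decoder blocks with skip concatenation back to 16x128x128x64, and
a final channel-reducing convolution to 2-class logits.  Every block
carries a residual bypass.  ``base_channels`` is the scale knob:
desk-scale variants keep the same doubling/halving ladder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import tensor as T


@dataclass
class UNetSpec:
    in_channels: int = 1
    base_channels: int = 16
    n_encoder_blocks: int = 5
    n_decoder_blocks: int = 4
    out_channels: int = 2

    def __post_init__(self):
        if self.n_decoder_blocks != self.n_encoder_blocks - 1:
            raise ValueError("need n_decoder_blocks == n_encoder_blocks - 1")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** (self.n_encoder_blocks - 1)

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.n_encoder_blocks - 1)

    def to_dict(self) -> dict:
        return dict(vars(self))


class EncoderBlock(nn.Module):
    """conv(s)+IN+ReLU, conv(1)+IN+ReLU, with a residual bypass."""

    def __init__(self, in_ch, out_ch, stride, rng):
        self.conv1 = nn.Conv3d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.norm1 = nn.InstanceNorm3d(out_ch)
        self.conv2 = nn.Conv3d(out_ch, out_ch, 3, rng=rng)
        self.norm2 = nn.InstanceNorm3d(out_ch)
        self.skip = (None if in_ch == out_ch and stride == 1
                     else nn.Conv3d(in_ch, out_ch, 1, stride=stride,
                                    padding=0, rng=rng))

    def forward(self, x):
        h = nn.relu(self.norm1(self.conv1(x)))
        h = nn.relu(self.norm2(self.conv2(h)))
        return h + (x if self.skip is None else self.skip(x))


class DecoderBlock(nn.Module):
    """stride-2 transposed conv, skip concat, conv+IN+ReLU, residual."""

    def __init__(self, in_ch, out_ch, rng):
        self.up = nn.ConvTranspose3d(in_ch, out_ch, stride=2, rng=rng)
        self.conv = nn.Conv3d(2 * out_ch, out_ch, 3, rng=rng)
        self.norm = nn.InstanceNorm3d(out_ch)
        self.proj = nn.Conv3d(2 * out_ch, out_ch, 1, padding=0, rng=rng)

    def forward(self, x, skip):
        u = self.up(x)
        cat = nn.concat([u, skip], axis=1)
        h = nn.relu(self.norm(self.conv(cat)))
        return h + self.proj(cat)


class UNet3D(nn.Module):
    def __init__(self, spec: UNetSpec | None = None, seed: int = 0):
        self.spec = spec or UNetSpec()
        rng = np.random.default_rng(seed)
        ch = self.spec.base_channels
        self.encoders = []
        in_ch = self.spec.in_channels
        for i in range(self.spec.n_encoder_blocks):
            out_ch = ch * 2 ** i
            self.encoders.append(
                EncoderBlock(in_ch, out_ch, stride=1 if i == 0 else 2, rng=rng))
            in_ch = out_ch
        self.decoders = []
        for i in range(self.spec.n_decoder_blocks):
            self.decoders.append(DecoderBlock(in_ch, in_ch // 2, rng=rng))
            in_ch //= 2
        self.head = nn.Conv3d(in_ch, self.spec.out_channels, 1, padding=0, rng=rng)
        self.bottleneck_shape_: tuple | None = None
        self.stage_shapes_: list[tuple] | None = None

    def validate_input(self, shape):
        _, c, h, w, d = shape
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, got {c}")
        for dim in (h, w, d):
            if dim % 32 != 0:
                raise ValueError(f"input dims must be multiples of 32, got {(h, w, d)}")

    def forward(self, x):
        self.validate_input(x.shape)
        feats = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            feats.append(h)
        self.stage_shapes_ = [tuple(f.shape[1:]) for f in feats]
        self.bottleneck_shape_ = tuple(h.shape[1:])
        for dec, skip in zip(self.decoders, reversed(feats[:-1])):
            h = dec(h, skip)
        return self.head(h)

    def param_groups(self) -> dict[str, list]:
        groups = {"encoder": [], "decoder": [], "bottom_two": [], "head": []}
        for enc in self.encoders:
            groups["encoder"].extend(enc.parameters())
        for dec in self.decoders[:-2]:
            groups["decoder"].extend(dec.parameters())
        for dec in self.decoders[-2:]:
            groups["bottom_two"].extend(dec.parameters())
        groups["head"].extend(self.head.parameters())
        return groups
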