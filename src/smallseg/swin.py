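"""Swin-transformer U-shaped segmentation network.

Encoder: a stride-2 patch partition/embedding followed by five stages
of paired windowed attention blocks (W-MSA then shifted SW-MSA); stages
two through five start with patch merging, which doubles channels and
halves resolution.  With the default feature size 48 the channel ladder
is 48-96-192-384-768 and a 1x128x128x64 input reaches a 768x4x4x2
bottleneck.  Decoder: five blocks of stride-2 transposed convolution,
concatenation with the matching encoder feature passed through a
residual sub-block, and a fusing residual sub-block, ending at
48x128x128x64 before the 2-channel head.

Attention here uses cyclic shifts without the boundary attention mask
and omits relative position bias; window size is clamped per stage to
the available resolution (no shift when the window covers a whole
axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import tensor as T


@dataclass
class SwinSpec:
    in_channels: int = 1
    out_channels: int = 2
    feature_size: int = 48        # embed dim; ladder ends at 16x this
    patch_size: int = 2
    window_size: int = 4
    head_dim: int = 16
    n_encoder_blocks: int = 5
    n_decoder_blocks: int = 5

    @property
    def bottleneck_channels(self) -> int:
        return self.feature_size * 16

    def to_dict(self) -> dict:
        return dict(vars(self))


class WindowAttention(nn.Module):
    def __init__(self, dim: int, heads: int, rng):
        self.dim = dim
        self.heads = heads
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)

    def forward(self, xw):
        # xw: (B, T, C) windows of T tokens
        B, Tn, C = xw.shape
        h = self.heads
        hd = C // h
        qkv = self.qkv(xw).reshape(B, Tn, 3, h, hd)
        q = qkv[:, :, 0].transpose(0, 2, 1, 3)   # (B, h, T, hd)
        k = qkv[:, :, 1].transpose(0, 2, 1, 3)
        v = qkv[:, :, 2].transpose(0, 2, 1, 3)
        scores = T.mul(T.matmul(q, k.transpose(0, 1, 3, 2)), 1.0 / np.sqrt(hd))
        attn = nn.softmax(scores, axis=-1)
        out = T.matmul(attn, v).transpose(0, 2, 1, 3).reshape(B, Tn, C)
        return self.proj(out)


def _window_partition(x, ws):
    """(N,H,W,D,C) -> (N*nW, prod(ws), C) with zero padding to multiples."""
    N, H, W, D, C = x.shape
    pads = [(0, (-H) % ws[0]), (0, (-W) % ws[1]), (0, (-D) % ws[2])]
    if any(p[1] for p in pads):
        x = T.pad(x, ((0, 0), pads[0], pads[1], pads[2], (0, 0)))
    _, Hp, Wp, Dp, _ = x.shape
    n0, n1, n2 = Hp // ws[0], Wp // ws[1], Dp // ws[2]
    x = x.reshape(N, n0, ws[0], n1, ws[1], n2, ws[2], C)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    x = x.reshape(N * n0 * n1 * n2, ws[0] * ws[1] * ws[2], C)
    return x, (N, Hp, Wp, Dp, C, n0, n1, n2)


def _window_reverse(xw, info, ws, orig_hwd):
    N, Hp, Wp, Dp, C, n0, n1, n2 = info
    x = xw.reshape(N, n0, n1, n2, ws[0], ws[1], ws[2], C)
    x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    x = x.reshape(N, Hp, Wp, Dp, C)
    H, W, D = orig_hwd
    if (Hp, Wp, Dp) != (H, W, D):
        x = x[:, :H, :W, :D, :]
    return x


class SwinBlock(nn.Module):
    """LN -> (S)W-MSA -> residual, LN -> MLP -> residual."""

    def __init__(self, dim: int, window: int, heads: int, shifted: bool, rng):
        self.window = window
        self.shifted = shifted
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, 4 * dim, rng=rng)
        self.fc2 = nn.Linear(4 * dim, dim, rng=rng)

    def forward(self, x):
        # x: (N, H, W, D, C)
        N, H, W, D, C = x.shape
        ws = tuple(min(self.window, d) for d in (H, W, D))
        shift = tuple(w // 2 if self.shifted and w < d else 0
                      for w, d in zip(ws, (H, W, D)))
        h = self.norm1(x)
        if any(shift):
            h = T.roll(h, tuple(-s for s in shift), (1, 2, 3))
        hw, info = _window_partition(h, ws)
        hw = self.attn(hw)
        h = _window_reverse(hw, info, ws, (H, W, D))
        if any(shift):
            h = T.roll(h, shift, (1, 2, 3))
        x = x + h
        m = self.fc2(nn.gelu(self.fc1(self.norm2(x))))
        return x + m


class PatchMerging(nn.Module):
    """2x downsampling: gather 2x2x2 neighborhoods, LN, linear 8C -> 2C."""

    def __init__(self, dim: int, rng):
        self.norm = nn.LayerNorm(8 * dim)
        self.reduce = nn.Linear(8 * dim, 2 * dim, bias=False, rng=rng)

    def forward(self, x):
        N, H, W, D, C = x.shape
        x = x.reshape(N, H // 2, 2, W // 2, 2, D // 2, 2, C)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        x = x.reshape(N, H // 2, W // 2, D // 2, 8 * C)
        return self.reduce(self.norm(x))


class SwinEncoder(nn.Module):
    """Patch embedding plus five stages of paired attention blocks."""

    def __init__(self, spec: SwinSpec, rng):
        self.spec = spec
        f = spec.feature_size
        self.patch_embed = nn.Conv3d(spec.in_channels, f, spec.patch_size,
                                     stride=spec.patch_size, padding=0, rng=rng)
        self.stages = []
        self.merges = []
        for i in range(spec.n_encoder_blocks):
            dim = f * 2 ** i
            heads = max(1, dim // spec.head_dim)
            if i > 0:
                self.merges.append(PatchMerging(dim // 2, rng))
            self.stages.append([
                SwinBlock(dim, spec.window_size, heads, shifted=False, rng=rng),
                SwinBlock(dim, spec.window_size, heads, shifted=True, rng=rng),
            ])

    def forward(self, x):
        """x: (N, C, H, W, D) -> list of 5 channels-first stage features."""
        h = self.patch_embed(x)
        h = h.transpose(0, 2, 3, 4, 1)   # channels-last for attention
        feats = []
        for i, pair in enumerate(self.stages):
            if i > 0:
                h = self.merges[i - 1](h)
            for block in pair:
                h = block(h)
            feats.append(h.transpose(0, 4, 1, 2, 3))
        return feats


class ResBlock(nn.Module):
    """Two conv+IN with ReLU and a projected residual."""

    def __init__(self, in_ch, out_ch, rng):
        self.conv1 = nn.Conv3d(in_ch, out_ch, 3, rng=rng)
        self.norm1 = nn.InstanceNorm3d(out_ch)
        self.conv2 = nn.Conv3d(out_ch, out_ch, 3, rng=rng)
        self.norm2 = nn.InstanceNorm3d(out_ch)
        self.skip = (None if in_ch == out_ch
                     else nn.Conv3d(in_ch, out_ch, 1, padding=0, rng=rng))

    def forward(self, x):
        h = nn.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return nn.relu(h + (x if self.skip is None else self.skip(x)))


class UpBlock(nn.Module):
    """Transposed conv upsampling, skip concat, fusing residual block."""

    def __init__(self, in_ch, out_ch, rng):
        self.up = nn.ConvTranspose3d(in_ch, out_ch, stride=2, rng=rng)
        self.fuse = ResBlock(2 * out_ch, out_ch, rng)

    def forward(self, x, skip):
        return self.fuse(nn.concat([self.up(x), skip], axis=1))


class SwinUNETR(nn.Module):
    def __init__(self, spec: SwinSpec | None = None, seed: int = 0):
        self.spec = spec or SwinSpec()
        rng = np.random.default_rng(seed)
        f = self.spec.feature_size
        self.encoder = SwinEncoder(self.spec, rng)
        self.enc_in = ResBlock(self.spec.in_channels, f, rng)
        self.enc_feats = [ResBlock(f * 2 ** i, f * 2 ** i, rng) for i in range(4)]
        self.dec4 = UpBlock(16 * f, 8 * f, rng)
        self.dec3 = UpBlock(8 * f, 4 * f, rng)
        self.dec2 = UpBlock(4 * f, 2 * f, rng)
        self.dec1 = UpBlock(2 * f, f, rng)
        self.dec0 = UpBlock(f, f, rng)
        self.head = nn.Conv3d(f, self.spec.out_channels, 1, padding=0, rng=rng)
        self.bottleneck_shape_: tuple | None = None
        self.stage_shapes_: list[tuple] | None = None
        self.final_decoder_channels_: int | None = None

    def validate_input(self, shape):
        _, c, h, w, d = shape
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, got {c}")
        for dim in (h, w, d):
            if dim % 32 != 0:
                raise ValueError(f"input dims must be multiples of 32, got {(h, w, d)}")

    def forward(self, x):
        self.validate_input(x.shape)
        feats = self.encoder(x)
        self.stage_shapes_ = [tuple(f.shape[1:]) for f in feats]
        self.bottleneck_shape_ = tuple(feats[-1].shape[1:])
        skips = [self.enc_feats[i](feats[i]) for i in range(4)]
        h = self.dec4(feats[4], skips[3])
        h = self.dec3(h, skips[2])
        h = self.dec2(h, skips[1])
        h = self.dec1(h, skips[0])
        h = self.dec0(h, self.enc_in(x))
        self.final_decoder_channels_ = int(h.shape[1])
        return self.head(h)

    def param_groups(self) -> dict[str, list]:
        groups = {"encoder": list(self.encoder.parameters()),
                  "decoder": [], "bottom_two": [], "head": []}
        for mod in [self.enc_in] + self.enc_feats + [self.dec4, self.dec3, self.dec2]:
            groups["decoder"].extend(mod.parameters())
        for mod in (self.dec1, self.dec0):
            groups["bottom_two"].extend(mod.parameters())
        groups["head"].extend(self.head.parameters())
        return groups
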