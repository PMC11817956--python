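"""Cutout-contrastive self-supervised pretraining.

Two corrupted views of each unlabeled volume are built by cutout:
``inner`` views replace six noise-filled rectangles drawn from the
central half of each slice (sides 5..32 by default), ``outer`` views
replace six rectangles touching the border band (sides 20..64).
Rectangles are replicated across a random contiguous slab of slices so
the corruption is 3D-meaningful.  Both views pass through the Swin
transformer encoder; a normalized-temperature cross-entropy contrastive
term compares the two views (on pooled, projected embeddings by
default, or on the reconstructed images) and an L1 term compares the
outer-view reconstruction with the uncorrupted original.  The sum of
both updates the weights.  Downstream, the pretrained encoder is frozen
and only the decoder trains on augmented small-tumor cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn import tensor as T
from .swin import SwinEncoder, SwinSpec
from .models import SwinUNETRSegmenter


@dataclass
class CutoutSpec:
    mode: str                    # inner | outer
    min_size: int
    max_size: int
    n_crops: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("inner", "outer"):
            raise ValueError("mode must be 'inner' or 'outer'")
        if not 1 <= self.min_size <= self.max_size:
            raise ValueError("need 1 <= min_size <= max_size")
        if self.n_crops < 0:
            raise ValueError("n_crops must be >= 0")


def inner_cutout_spec(seed: int = 0, min_size: int = 5, max_size: int = 32,
                      n_crops: int = 6) -> CutoutSpec:
    return CutoutSpec("inner", min_size, max_size, n_crops, seed)


def outer_cutout_spec(seed: int = 0, min_size: int = 20, max_size: int = 64,
                      n_crops: int = 6) -> CutoutSpec:
    return CutoutSpec("outer", min_size, max_size, n_crops, seed)


@dataclass
class PretextPair:
    aug1: np.ndarray             # inner-cutout view
    aug2: np.ndarray             # outer-cutout view
    original: np.ndarray


def make_cutout_view(volume: np.ndarray, spec: CutoutSpec,
                     return_regions: bool = False):
    """Corrupt a (H, W, D) volume with noise-filled cutout rectangles.

    Inner rectangles lie fully inside the central half of each in-plane
    extent; outer rectangles intersect the border band (the outer
    quarter).  Voxels outside the rectangles are bit-identical to the
    input.  With ``return_regions`` the (r0, r1, c0, c1, z0, z1) boxes
    are returned alongside the corrupted volume.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError(f"expected (H, W, D), got {vol.shape}")
    H, W, D = vol.shape
    if H < spec.max_size or W < spec.max_size:
        raise ValueError(
            f"volume in-plane size {(H, W)} smaller than max cutout "
            f"{spec.max_size}")
    out = vol.copy()
    regions: list[tuple[int, int, int, int, int, int]] = []
    if spec.n_crops == 0:
        return (out, regions) if return_regions else out
    rng = np.random.default_rng(spec.seed)
    vmin, vmax = float(vol.min()), float(vol.max())
    if vmax <= vmin:
        vmax = vmin + 1.0
    for _ in range(spec.n_crops):
        sh = int(rng.integers(spec.min_size, spec.max_size + 1))
        sw = int(rng.integers(spec.min_size, spec.max_size + 1))
        z0 = int(rng.integers(0, D))
        z1 = min(D, z0 + int(rng.integers(1, max(2, D // 4) + 1)))
        if spec.mode == "inner":
            sh_c = min(sh, H // 2)
            sw_c = min(sw, W // 2)
            r0 = int(rng.integers(H // 4, 3 * H // 4 - sh_c + 1))
            c0 = int(rng.integers(W // 4, 3 * W // 4 - sw_c + 1))
            r1, c1 = r0 + sh_c, c0 + sw_c
        else:
            while True:
                r0 = int(rng.integers(0, H - sh + 1))
                c0 = int(rng.integers(0, W - sw + 1))
                r1, c1 = r0 + sh, c0 + sw
                if (r0 < H // 4 or r1 > 3 * H // 4 or
                        c0 < W // 4 or c1 > 3 * W // 4):
                    break
        out[r0:r1, c0:c1, z0:z1] = rng.uniform(
            vmin, vmax, size=(r1 - r0, c1 - c0, z1 - z0)).astype(out.dtype)
        regions.append((r0, r1, c0, c1, z0, z1))
    return (out, regions) if return_regions else out


def make_pretext_pair(volume: np.ndarray, seed: int = 0,
                      inner: CutoutSpec | None = None,
                      outer: CutoutSpec | None = None) -> PretextPair:
    inner = inner or inner_cutout_spec(seed=seed)
    outer = outer or outer_cutout_spec(seed=seed + 1)
    return PretextPair(aug1=make_cutout_view(volume, inner),
                       aug2=make_cutout_view(volume, outer),
                       original=np.asarray(volume))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def contrastive_loss(z1, z2, temperature: float = 0.5):
    """Normalized-temperature cross-entropy over in-batch negatives.

    z1[i] and z2[i] are the matched views of sample i.  With all 2N
    embeddings identical the loss is ln(2N - 1).  Returns a scalar
    Tensor (differentiable when the inputs are).
    """
    z1 = z1 if isinstance(z1, T.Tensor) else T.Tensor(np.asarray(z1))
    z2 = z2 if isinstance(z2, T.Tensor) else T.Tensor(np.asarray(z2))
    if z1.shape != z2.shape:
        raise ValueError("embedding batches must share shape")
    n = z1.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs batch size >= 2 (no negatives)")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = nn.concat([z1, z2], axis=0)                       # (2N, d)
    norm = T.power(T.tsum(T.mul(z, z), axis=1, keepdims=True) + 1e-12, -0.5)
    z = T.mul(z, norm)
    sim = T.mul(T.matmul(z, z.transpose(1, 0)), 1.0 / temperature)
    mask = T.Tensor(np.eye(2 * n, dtype=np.float32) * -1e9)
    logp = nn.log_softmax(sim + mask, axis=1)
    rows = np.arange(2 * n)
    cols = np.concatenate([np.arange(n) + n, np.arange(n)])
    return T.tmean(T.mul(logp[rows, cols], -1.0))


def reconstruction_l1(recon, original):
    """Mean absolute difference; zero iff the volumes are equal."""
    recon = recon if isinstance(recon, T.Tensor) else T.Tensor(np.asarray(recon))
    original = (original if isinstance(original, T.Tensor)
                else T.Tensor(np.asarray(original)))
    if recon.shape != original.shape:
        raise ValueError(
            f"shape mismatch: {recon.shape} vs {original.shape}")
    return T.tmean(nn.absolute(recon + T.mul(original, -1.0)))


def combined_loss(contrastive, l1, weight: float = 1.0):
    """contrastive + weight * l1."""
    c = contrastive if isinstance(contrastive, T.Tensor) else T.Tensor(contrastive)
    l = l1 if isinstance(l1, T.Tensor) else T.Tensor(l1)
    return c + T.mul(l, float(weight))


# ---------------------------------------------------------------------------
# pretext model
# ---------------------------------------------------------------------------

class _ReconHead(nn.Module):
    """Upsample the bottleneck back to input resolution, one channel out."""

    def __init__(self, feature_size: int, rng):
        f = feature_size
        chans = [16 * f, 8 * f, 4 * f, 2 * f, f, f]
        self.ups = [nn.ConvTranspose3d(chans[i], chans[i + 1], stride=2, rng=rng)
                    for i in range(5)]
        self.out = nn.Conv3d(f, 1, 1, padding=0, rng=rng)

    def forward(self, x):
        for up in self.ups:
            x = nn.relu(up(x))
        return self.out(x)


class _ProjectionHead(nn.Module):
    """Two-layer MLP on the pooled bottleneck feature."""

    def __init__(self, in_dim: int, proj_dim: int, rng):
        self.fc1 = nn.Linear(in_dim, proj_dim, rng=rng)
        self.fc2 = nn.Linear(proj_dim, proj_dim, rng=rng)

    def forward(self, x):
        return self.fc2(nn.relu(self.fc1(x)))


class _PretextModel(nn.Module):
    def __init__(self, spec: SwinSpec, proj_dim: int, rng_seed: int):
        rng = np.random.default_rng(rng_seed)
        self.encoder = SwinEncoder(spec, rng)
        self.recon = _ReconHead(spec.feature_size, rng)
        self.proj = _ProjectionHead(16 * spec.feature_size, proj_dim, rng)

    def embed_and_recon(self, x):
        feats = self.encoder(x)
        bottleneck = feats[-1]
        pooled = T.tmean(bottleneck, axis=(2, 3, 4))
        return self.proj(pooled), self.recon(bottleneck)


class ContrastivePretrainer(BaseEstimator):
    """Self-supervised pretext trainer for the Swin encoder.

    ``fit(X)`` on unlabeled ``(n, H, W, D)`` volumes; the fitted
    ``encoder_state_`` plugs into :func:`downstream_train`.
    ``contrast_on`` chooses whether the contrastive term sees projected
    embeddings (default) or the reconstructed images themselves.
    """

    def __init__(self, feature_size=8, window_size=4, epochs=5, lr=1e-3,
                 batch_size=2, temperature=0.5, l1_weight=1.0, proj_dim=32,
                 contrast_on="embedding", inner_min=5, inner_max=32,
                 outer_min=20, outer_max=64, n_crops=6, random_state=0):
        self.feature_size = feature_size
        self.window_size = window_size
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.temperature = temperature
        self.l1_weight = l1_weight
        self.proj_dim = proj_dim
        self.contrast_on = contrast_on
        self.inner_min = inner_min
        self.inner_max = inner_max
        self.outer_min = outer_min
        self.outer_max = outer_max
        self.n_crops = n_crops
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_volumes, H, W, D), got {X.shape}")
        if len(X) < 2:
            raise ValueError("pretext training needs >= 2 volumes "
                             "(contrastive loss has no negatives otherwise)")
        if self.contrast_on not in ("embedding", "image"):
            raise ValueError("contrast_on must be 'embedding' or 'image'")
        rng = np.random.default_rng(self.random_state)
        spec = SwinSpec(feature_size=self.feature_size,
                        window_size=self.window_size)
        self.spec_ = spec
        model = _PretextModel(spec, self.proj_dim, rng_seed=self.random_state)
        opt = nn.Adam(model.parameters(), lr=self.lr)
        n = len(X)
        bs = max(2, min(self.batch_size, n))
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n - 1, bs):
                idx = order[start:start + bs]
                if len(idx) < 2:
                    break
                a1, a2 = [], []
                for i in idx:
                    s = int(rng.integers(0, 2 ** 31 - 1))
                    pair = make_pretext_pair(
                        X[i], inner=CutoutSpec("inner", self.inner_min,
                                               self.inner_max, self.n_crops, s),
                        outer=CutoutSpec("outer", self.outer_min,
                                         self.outer_max, self.n_crops, s + 1))
                    a1.append(pair.aug1)
                    a2.append(pair.aug2)
                x1 = T.Tensor(np.stack(a1)[:, None])
                x2 = T.Tensor(np.stack(a2)[:, None])
                z1, r1 = model.embed_and_recon(x1)
                z2, r2 = model.embed_and_recon(x2)
                if self.contrast_on == "image":
                    m = len(idx)
                    c = contrastive_loss(r1.reshape(m, -1), r2.reshape(m, -1),
                                         self.temperature)
                else:
                    c = contrastive_loss(z1, z2, self.temperature)
                l1 = reconstruction_l1(r2, T.Tensor(X[idx][:, None]))
                loss = combined_loss(c, l1, self.l1_weight)
                model.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            self.loss_history_.append(float(np.mean(losses)))
        self.model_ = model
        self.encoder_state_ = model.encoder.state_dict()
        return self


def pretrain(X, **kwargs) -> ContrastivePretrainer:
    """Functional wrapper: fit a ContrastivePretrainer on volumes X."""
    return ContrastivePretrainer(**kwargs).fit(X)


def downstream_train(pretrained, X, y, **segmenter_kwargs) -> SwinUNETRSegmenter:
    """Train the segmentation decoder on labeled data with the
    pretrained encoder loaded and frozen.

    ``pretrained`` is a fitted ContrastivePretrainer or an encoder state
    dict from one.
    """
    if len(np.asarray(X)) == 0:
        raise ValueError("downstream training needs a nonempty labeled set")
    if isinstance(pretrained, ContrastivePretrainer):
        state = pretrained.encoder_state_
        segmenter_kwargs.setdefault("feature_size", pretrained.feature_size)
        segmenter_kwargs.setdefault("window_size", pretrained.window_size)
    else:
        state = pretrained
    init = {f"encoder.{k}": v for k, v in state.items()}
    est = SwinUNETRSegmenter(trainable="decoder_only", init_state=init,
                             **segmenter_kwargs)
    return est.fit(X, y)
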