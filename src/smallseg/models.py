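"""Scikit-learn-style segmentation estimators.

``UNetSegmenter`` and ``SwinUNETRSegmenter`` wrap the two network
architectures behind the familiar ``fit(X, y)`` / ``predict(X)``
surface; ``X`` is an ``(n, H, W, D)`` float array of normalized volumes
and ``y`` the matching binary label array.  Both estimators expose the
layer-freezing policies used for transfer learning (``trainable`` in
{'all', 'bottom_two_only', 'decoder_only'}) and accept pretrained
weights through ``init_state``.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn import tensor as T
from .swin import SwinSpec, SwinUNETR
from .unet import UNet3D, UNetSpec

POLICIES = ("all", "bottom_two_only", "decoder_only")


def set_trainable(net, policy: str):
    """Apply a layer-freezing policy to a network's parameter groups.

    'all' trains everything; 'bottom_two_only' trains only the two
    decoder blocks nearest the output plus the channel-reducing head;
    'decoder_only' freezes the encoder and trains the rest.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    groups = net.param_groups()
    trainable_groups = {
        "all": {"encoder", "decoder", "bottom_two", "head"},
        "bottom_two_only": {"bottom_two", "head"},
        "decoder_only": {"decoder", "bottom_two", "head"},
    }[policy]
    for name, params in groups.items():
        flag = name in trainable_groups
        for p in params:
            p.requires_grad = flag
    return net


def segment(net, image: np.ndarray) -> np.ndarray:
    """Argmax segmentation of one volume; ties favor background.

    Accepts (H, W, D) or (1, H, W, D); returns a (1, H, W, D) binary mask.
    """
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected a single volume, got shape {arr.shape}")
    with nn.no_grad():
        logits = net(T.Tensor(arr[None])).data[0]
    return (logits[1] > logits[0]).astype(np.uint8)[None]


def dice_loss(logits, y_onehot, eps: float = 1e-5):
    """Soft Dice loss averaged over channels and batch."""
    p = nn.softmax(logits, axis=1)
    axes = (2, 3, 4)
    inter = T.tsum(T.mul(p, y_onehot), axis=axes)
    denom = T.tsum(p, axis=axes) + T.tsum(y_onehot, axis=axes)
    dice = T.mul(inter + eps, 1.0) * T.power(denom + 2 * eps, -1.0) * 2.0
    return T.tmean(T.mul(dice, -1.0) + 1.0)


def cross_entropy_loss(logits, y_onehot):
    logp = nn.log_softmax(logits, axis=1)
    return T.tmean(T.tsum(T.mul(T.mul(logp, y_onehot), -1.0), axis=1))


_LOSSES = {"dice": dice_loss, "ce": cross_entropy_loss}


def _onehot(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    return np.stack([(y == 0), (y > 0)], axis=1).astype(np.float32)


class _BaseSegmenter(BaseEstimator):
    """Shared fit/predict machinery; subclasses build the network."""

    def _build_net(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_cases, H, W, D), got {X.shape}")
        for d in X.shape[1:]:
            if d % 32 != 0:
                raise ValueError(f"volume dims must be multiples of 32, got {X.shape[1:]}")
        if y is None:
            return X
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError("y must match X shape")
        if not np.all(np.isin(np.unique(y), [0, 1])):
            raise ValueError("y must be binary")
        return X, y.astype(np.uint8)

    def fit(self, X, y):
        X, y = self._validate(X, y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        rng = np.random.default_rng(self.random_state)
        self.model_ = self._build_net()
        if self.init_state is not None:
            self.model_.load_state_dict(self.init_state, strict=False)
        set_trainable(self.model_, self.trainable)
        loss_fn = _LOSSES[self.loss]
        opt = nn.Adam(self.model_.parameters(), lr=self.lr)
        n = len(X)
        bs = max(1, min(self.batch_size, n))
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb = T.Tensor(X[idx][:, None])
                yb = T.Tensor(_onehot(y[idx]))
                logits = self.model_(xb)
                loss = loss_fn(logits, yb)
                self.model_.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
            self.loss_history_.append(float(np.mean(epoch_losses)))
        self.n_iter_ = self.epochs
        return self

    def predict(self, X) -> np.ndarray:
        X = self._validate(X)
        masks = [segment(self.model_, vol)[0] for vol in X]
        return np.stack(masks, axis=0)

    def score(self, X, y) -> float:
        """Mean per-case Dice."""
        from .metrics import dice as dice_score

        preds = self.predict(X)
        return float(np.mean([dice_score(p, t).dice for p, t in zip(preds, y)]))


class UNetSegmenter(_BaseSegmenter):
    def __init__(self, base_channels=16, epochs=10, lr=1e-3, batch_size=2,
                 loss="dice", trainable="all", init_state=None, random_state=0):
        self.base_channels = base_channels
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.loss = loss
        self.trainable = trainable
        self.init_state = init_state
        self.random_state = random_state

    def _build_net(self):
        return UNet3D(UNetSpec(base_channels=self.base_channels),
                      seed=self.random_state)


class SwinUNETRSegmenter(_BaseSegmenter):
    def __init__(self, feature_size=48, window_size=4, epochs=10, lr=1e-3,
                 batch_size=2, loss="dice", trainable="all", init_state=None,
                 random_state=0):
        self.feature_size = feature_size
        self.window_size = window_size
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.loss = loss
        self.trainable = trainable
        self.init_state = init_state
        self.random_state = random_state

    def _build_net(self):
        return SwinUNETR(SwinSpec(feature_size=self.feature_size,
                                  window_size=self.window_size),
                         seed=self.random_state)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: dict, spec: dict) -> None:
    """Weights + architecture spec in one .npz container."""
    np.savez(path, __spec__=json.dumps(spec),
             **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(path) -> tuple[dict, dict]:
    with np.load(path, allow_pickle=False) as z:
        spec = json.loads(str(z["__spec__"]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    return state, spec
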