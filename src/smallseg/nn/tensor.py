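"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supplies exactly the primitives the 3D segmentation networks
need: broadcast arithmetic, matmul, shape ops, padding/rolling for
windowed attention, reductions, pointwise nonlinearities, and 3D
convolution / transposed convolution with stride support.  Everything is
float32.  A global ``no_grad`` switch turns the tape off for inference so
large forward passes keep no intermediate state.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array with an optional backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float32)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                pid = id(parent)
                if pid in grads:
                    grads[pid] = grads[pid] + pg
                else:
                    grads[pid] = pg


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.astype(np.float32, copy=False)


# -- arithmetic ---------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(out, (a, b), backward)


def mul(a: Tensor, b) -> Tensor:
    a = _wrap(a)
    if np.isscalar(b):
        s = float(b)

        def backward_s(g):
            return (g * s,)

        return _make(a.data * s, (a,), backward_s)
    b = _wrap(b)

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _make(a.data * b.data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    a = _wrap(a)
    out = a.data ** exponent

    def backward(g):
        return (g * exponent * a.data ** (exponent - 1.0),)

    return _make(out, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _make(out, (a, b), backward)


# -- shape manipulation -------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    orig = a.shape

    def backward(g):
        return (g.reshape(orig),)

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward(g):
        return (np.transpose(g, inv),)

    return _make(np.transpose(a.data, axes), (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def getitem(a: Tensor, idx) -> Tensor:
    a = _wrap(a)

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[idx] = g
        return (ga,)

    return _make(a.data[idx], (a,), backward)


def pad(a: Tensor, pad_width) -> Tensor:
    """Zero padding; pad_width as for np.pad."""
    a = _wrap(a)
    slices = tuple(slice(p[0], p[0] + s) for p, s in zip(pad_width, a.shape))

    def backward(g):
        return (g[slices],)

    return _make(np.pad(a.data, pad_width), (a,), backward)


def roll(a: Tensor, shift, axis) -> Tensor:
    a = _wrap(a)
    shift = tuple(np.atleast_1d(shift))
    axis = tuple(np.atleast_1d(axis))
    neg = tuple(-s for s in shift)

    def backward(g):
        return (np.roll(g, neg, axis),)

    return _make(np.roll(a.data, shift, axis), (a,), backward)


# -- reductions ---------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

    def backward(g):
        g = np.asarray(g, dtype=np.float32)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).astype(np.float32, copy=False),)

    return _make(out, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in np.atleast_1d(axis)]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- pointwise nonlinearities -------------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        return (g * mask,)

    return _make(a.data * mask, (a,), backward)


def exp(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = np.exp(a.data)

    def backward(g):
        return (g * out,)

    return _make(out, (a,), backward)


def log(a: Tensor) -> Tensor:
    a = _wrap(a)

    def backward(g):
        return (g / a.data,)

    return _make(np.log(a.data), (a,), backward)


def tanh(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = np.tanh(a.data)

    def backward(g):
        return (g * (1.0 - out * out),)

    return _make(out, (a,), backward)


def absolute(a: Tensor) -> Tensor:
    a = _wrap(a)
    sign = np.sign(a.data)

    def backward(g):
        return (g * sign,)

    return _make(np.abs(a.data), (a,), backward)


def gelu(a: Tensor) -> Tensor:
    # tanh approximation of the Gaussian error linear unit
    c = float(np.sqrt(2.0 / np.pi))
    inner = mul(add(a, mul(power(a, 3.0), 0.044715)), c)
    return mul(mul(a, add(tanh(inner), 1.0)), 0.5)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(a.data, axis=axis, keepdims=True)  # constant shift
    e = exp(add(a, Tensor(-shift)))
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(a.data, axis=axis, keepdims=True)
    shifted = add(a, Tensor(-shift))
    lse = log(tsum(exp(shifted), axis=axis, keepdims=True))
    return add(shifted, mul(lse, -1.0))


# -- 3D convolution -----------------------------------------------------------

def _triple(x):
    if isinstance(x, (tuple, list)):
        return tuple(int(v) for v in x)
    return (int(x),) * 3


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0) -> Tensor:
    """3D convolution, channels-first: x (N,C,H,W,D), w (O,C,kh,kw,kd).

    Implemented as a sum of one batched matmul per kernel offset, which
    keeps peak memory at one output-sized temporary per step.
    """
    x = _wrap(x)
    w = _wrap(w)
    s = _triple(stride)
    p = _triple(padding)
    N, C, H, W, D = x.shape
    O, Cw, kh, kw, kd = w.shape
    if Cw != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight {Cw}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    Hp, Wp, Dp = xp.shape[2:]
    Ho = (Hp - kh) // s[0] + 1
    Wo = (Wp - kw) // s[1] + 1
    Do = (Dp - kd) // s[2] + 1
    P = Ho * Wo * Do

    w2 = w.data.reshape(O, C, kh * kw * kd)
    out = np.zeros((N, O, P), dtype=np.float32)
    for di in range(kh):
        for dj in range(kw):
            for dl in range(kd):
                xs = xp[:, :,
                        di:di + s[0] * (Ho - 1) + 1:s[0],
                        dj:dj + s[1] * (Wo - 1) + 1:s[1],
                        dl:dl + s[2] * (Do - 1) + 1:s[2]]
                k = (di * kw + dj) * kd + dl
                out += np.matmul(w2[None, :, :, k], xs.reshape(N, C, P))
    out = out.reshape(N, O, Ho, Wo, Do)
    if b is not None:
        b = _wrap(b)
        out = out + b.data.reshape(1, O, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = g.reshape(N, O, P)
        gx_p = np.zeros_like(xp) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for di in range(kh):
            for dj in range(kw):
                for dl in range(kd):
                    sl = (slice(None), slice(None),
                          slice(di, di + s[0] * (Ho - 1) + 1, s[0]),
                          slice(dj, dj + s[1] * (Wo - 1) + 1, s[1]),
                          slice(dl, dl + s[2] * (Do - 1) + 1, s[2]))
                    k = (di * kw + dj) * kd + dl
                    if gw is not None:
                        xs = xp[sl].reshape(N, C, P)
                        # sum over batch and positions
                        gw[:, :, di, dj, dl] += np.einsum("nop,ncp->oc", g2, xs)
                    if gx_p is not None:
                        contrib = np.matmul(w2[None, :, :, k].transpose(0, 2, 1), g2)
                        gx_p[sl] += contrib.reshape(N, C, Ho, Wo, Do)
        gx = None
        if gx_p is not None:
            gx = gx_p[:, :, p[0]:p[0] + H, p[1]:p[1] + W, p[2]:p[2] + D]
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3, 4)) if b.requires_grad else None)
        return tuple(grads)

    return _make(out, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed 3D convolution with kernel == stride (non-overlapping).

    x (N,C,H,W,D), w (C,O,k,k,k) -> (N,O,H*k,W*k,D*k).
    """
    x = _wrap(x)
    w = _wrap(w)
    k = int(stride)
    N, C, H, W, D = x.shape
    Cw, O = w.shape[:2]
    if Cw != C:
        raise ValueError(f"conv_transpose3d channel mismatch: input {C}, weight {Cw}")
    P = H * W * D
    xf = x.data.reshape(N, C, P)
    out = np.zeros((N, O, H * k, W * k, D * k), dtype=np.float32)
    for di in range(k):
        for dj in range(k):
            for dl in range(k):
                w2 = w.data[:, :, di, dj, dl]  # (C, O)
                vals = np.matmul(w2.T[None], xf).reshape(N, O, H, W, D)
                out[:, :, di::k, dj::k, dl::k] = vals
    if b is not None:
        b = _wrap(b)
        out = out + b.data.reshape(1, O, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gx = np.zeros_like(x.data) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for di in range(k):
            for dj in range(k):
                for dl in range(k):
                    gs = g[:, :, di::k, dj::k, dl::k].reshape(N, O, P)
                    if gx is not None:
                        w2 = w.data[:, :, di, dj, dl]  # (C, O)
                        gx += np.matmul(w2[None], gs).reshape(N, C, H, W, D)
                    if gw is not None:
                        gw[:, :, di, dj, dl] += np.einsum("nop,ncp->co", gs, xf)
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3, 4)) if b.requires_grad else None)
        return tuple(grads)

    return _make(out, parents, backward)
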