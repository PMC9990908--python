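"""A compact reverse-mode automatic-differentiation engine over numpy.

Provides exactly the tensor operations the segmentation network needs:
broadcast arithmetic, (batched) matmul, shape ops, reductions, softmax,
layer/instance normalization, GELU/leaky-ReLU, 3D convolution with odd
kernels ("same" padding) and 2x-stride-2 transposed convolution.
Convolutions are evaluated as one GEMM per kernel offset on strided views,
which keeps memory flat and routes the arithmetic through BLAS.

Gradients accumulate into ``Tensor.grad``; call ``backward()`` on a scalar.
The engine is dtype-transparent: float64 inputs give float64 graphs, which
the gradient-check tests rely on.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "matmul", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- op construction helper ------------------------------------------


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def _wrap(x, like: Tensor | None = None) -> Tensor:
    """Coerce scalars/arrays to Tensor, matching ``like``'s float dtype so
    python-float constants never upcast a float32 graph to float64."""
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if like is not None and arr.dtype != like.dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(like.dtype)
    return Tensor(arr)


# -- arithmetic -----------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def _mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def _sub(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)),
    )


def _div(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
        ),
    )


Tensor.__add__ = lambda self, o: _add(self, _wrap(o, self))
Tensor.__radd__ = lambda self, o: _add(_wrap(o, self), self)
Tensor.__mul__ = lambda self, o: _mul(self, _wrap(o, self))
Tensor.__rmul__ = lambda self, o: _mul(_wrap(o, self), self)
Tensor.__sub__ = lambda self, o: _sub(self, _wrap(o, self))
Tensor.__rsub__ = lambda self, o: _sub(_wrap(o, self), self)
Tensor.__truediv__ = lambda self, o: _div(self, _wrap(o, self))
Tensor.__rtruediv__ = lambda self, o: _div(_wrap(o, self), self)
Tensor.__neg__ = lambda self: _mul(self, Tensor(np.asarray(-1.0, dtype=self.dtype)))


def _pow(a: Tensor, p: float) -> Tensor:
    return _make(a.data**p, (a,), lambda g: (g * p * a.data ** (p - 1),))


Tensor.__pow__ = _pow


def t_exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    return _make(out_data, (a,), lambda g: (g * out_data,))


def t_log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), lambda g: (g / a.data,))


def t_clip_min(a: Tensor, lo: float) -> Tensor:
    mask = a.data > lo
    return _make(np.maximum(a.data, lo), (a,), lambda g: (g * mask,))


Tensor.exp = t_exp
Tensor.log = t_log
Tensor.clip_min = t_clip_min


# -- shape ops ------------------------------------------------------------

def t_reshape(a: Tensor, *shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    old = a.data.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def t_transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    return _make(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in ts], axis=axis), tuple(ts), back)


Tensor.reshape = t_reshape
Tensor.transpose = t_transpose


# -- reductions -----------------------------------------------------------

def t_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def back(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, a.data.shape).copy(),)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)


def t_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return t_sum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


Tensor.sum = t_sum
Tensor.mean = t_mean


# -- matmul ---------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    def back(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _make(np.matmul(a.data, b.data), (a, b), back)


Tensor.__matmul__ = matmul


# -- nonlinearities -------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a: Tensor) -> Tensor:
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))

    def back(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return (g * (cdf + x * pdf),)

    return _make(x * cdf, (a,), back)


def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    x = a.data
    one = x.dtype.type(1.0) if np.issubdtype(x.dtype, np.floating) else 1.0
    factor = np.where(x > 0, one, x.dtype.type(slope) if np.issubdtype(x.dtype, np.floating) else slope)
    return _make(x * factor, (a,), lambda g: (g * factor,))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    return _make(y, (a,), back)


# -- normalization --------------------------------------------------------

def _norm_axes(a: Tensor, axes: tuple[int, ...], gain: Tensor, bias: Tensor, eps: float) -> Tensor:
    """(x - mean)/sqrt(var + eps) * gain + bias over the given axes."""
    x = a.data
    mu = x.mean(axis=axes, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    n = int(np.prod([x.shape[ax] for ax in axes]))

    def back(g):
        gh = g * gain.data
        mean_gh = gh.mean(axis=axes, keepdims=True)
        mean_ghx = (gh * xhat).mean(axis=axes, keepdims=True)
        gx = inv * (gh - mean_gh - xhat * mean_ghx)
        ggain = _unbroadcast(g * xhat, gain.data.shape)
        gbias = _unbroadcast(g, bias.data.shape)
        return gx, ggain, gbias

    return _make(xhat * gain.data + bias.data, (a, gain, bias), back)


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis (token features)."""
    return _norm_axes(a, (a.data.ndim - 1,), gain, bias, eps)


def instance_norm3d(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each channel of a (C, D, H, W) map over its spatial axes."""
    return _norm_axes(a, (1, 2, 3), gain, bias, eps)


# -- 3D convolution -------------------------------------------------------

def _conv_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 "same" correlation of (Cin,D,H,W) with (Cout,Cin,k,k,k).

    Uses one GEMM per kernel offset; for few input channels the offsets
    are merged into a single column matrix and one GEMM, which is faster
    while the column buffer still fits in cache-friendly territory.
    """
    cin, D, H, W = x.shape
    cout, _, k = w.shape[:3]
    p = k // 2
    N = D * H * W
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
    if cin * k**3 * N * x.itemsize <= 64 << 20:
        col = np.empty((k**3 * cin, N), dtype=x.dtype)
        i = 0
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    col[i * cin:(i + 1) * cin] = xp[:, a:a + D, bb:bb + H, c:c + W].reshape(cin, N)
                    i += 1
        wa = w.transpose(0, 2, 3, 4, 1).reshape(cout, k**3 * cin)
        return (wa @ col).reshape(cout, D, H, W)
    acc = np.zeros((cout, N), dtype=x.dtype)
    for a in range(k):
        for bb in range(k):
            for c in range(k):
                view = xp[:, a:a + D, bb:bb + H, c:c + W].reshape(cin, N)
                acc += w[:, :, a, bb, c] @ view
    return acc.reshape(cout, D, H, W)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 "same" 3D convolution; x (Cin,D,H,W), w (Cout,Cin,k,k,k)."""
    cin, D, H, W = x.data.shape
    cout, cin2, k, _, _ = w.data.shape
    assert cin == cin2 and k % 2 == 1
    p = k // 2
    out = _conv_raw(x.data, w.data) + b.data[:, None, None, None]

    def back(g):
        g = np.ascontiguousarray(g)
        # input gradient = correlation of g with the spatially flipped,
        # channel-swapped kernel (avoids scatter-adds into a padded grid)
        wflip = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        gx = _conv_raw(g, np.ascontiguousarray(wflip))
        gf = g.reshape(cout, -1)
        gw = np.empty_like(w.data)
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    view = xp[:, a:a + D, bb:bb + H, c:c + W].reshape(cin, -1)
                    gw[:, :, a, bb, c] = gf @ view.T
        gb = g.sum(axis=(1, 2, 3))
        return gx, gw, gb

    return _make(out, (x, w, b), back)


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Kernel-2 stride-2 transposed convolution (exact 2x upsampling).

    x (Cin, D, H, W), w (Cin, Cout, 2, 2, 2) -> (Cout, 2D, 2H, 2W).
    """
    cin, D, H, W = x.data.shape
    cin2, cout = w.data.shape[:2]
    assert cin == cin2
    wf = w.data.reshape(cin, cout * 8)
    t = (wf.T @ x.data.reshape(cin, -1)).reshape(cout, 2, 2, 2, D, H, W)
    out = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(cout, 2 * D, 2 * H, 2 * W)
    out = out + b.data[:, None, None, None]

    def back(g):
        gt = (
            g.reshape(cout, D, 2, H, 2, W, 2)
            .transpose(0, 2, 4, 6, 1, 3, 5)
            .reshape(cout * 8, -1)
        )
        gx = (wf @ gt).reshape(cin, D, H, W)
        gw = (x.data.reshape(cin, -1) @ gt.T).reshape(w.data.shape)
        gb = g.sum(axis=(1, 2, 3))
        return gx, gw, gb

    return _make(out, (x, w, b), back)


# -- parameter initialization and optimizer -------------------------------

def kaiming(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    return (rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)).astype(dtype)


def xavier(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype=np.float32) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class AdamW:
    """Decoupled-weight-decay Adam on a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
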