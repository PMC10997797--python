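"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the trainable layers need: broadcasting
arithmetic, matmul, elementwise nonlinearities, reductions, reshaping,
concatenation, 2-D convolution (im2col), nearest-neighbor upsampling, and
custom functions with analytic backward passes (used for the differentiable
pupil→PSF map and FFT convolution).  float64 throughout; gradient
correctness is covered by finite-difference tests.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "concat", "conv2d", "upsample2",
           "custom", "default_dtype"]

_grad_enabled = True
_dtype = np.float64


@contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextmanager
def default_dtype(dtype):
    """Run graph construction in the given float dtype (float32 roughly
    halves the cost of desk-scale training; float64 is the default and is
    what the finite-difference gradient checks assume)."""
    global _dtype
    prev = _dtype
    _dtype = np.dtype(dtype).type
    try:
        yield
    finally:
        _dtype = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_dtype)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ #
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------ #
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def __add__(self, other):
        return _binary(self, other, lambda a, b: a + b,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, lambda a, b: a * b,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, lambda a, b: a - b,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        return _binary(self, other, lambda a, b: a / b,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / b**2)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        return _unary(self, lambda a: a**p, lambda g, a, y: g * p * a ** (p - 1))

    def __matmul__(self, other):
        other = as_tensor(other)
        return _binary(self, other, lambda a, b: a @ b,
                       lambda g, a, b: g @ b.swapaxes(-1, -2),
                       lambda g, a, b: a.swapaxes(-1, -2) @ g)

    def __getitem__(self, idx):
        def bwd(g, a, y):
            out = np.zeros_like(a)
            np.add.at(out, idx, g)
            return out
        return _unary(self, lambda a: a[idx], bwd)

    # elementwise nonlinearities ---------------------------------------- #
    def relu(self):
        return _unary(self, lambda a: np.maximum(a, 0.0),
                      lambda g, a, y: g * (a > 0))

    def leaky_relu(self, slope: float = 0.2):
        return _unary(self, lambda a: np.where(a > 0, a, slope * a),
                      lambda g, a, y: g * np.where(a > 0, 1.0, slope))

    def sigmoid(self):
        return _unary(self, lambda a: 1.0 / (1.0 + np.exp(-a)),
                      lambda g, a, y: g * y * (1.0 - y))

    def tanh(self):
        return _unary(self, np.tanh, lambda g, a, y: g * (1.0 - y**2))

    def exp(self):
        return _unary(self, np.exp, lambda g, a, y: g * y)

    def log(self):
        return _unary(self, np.log, lambda g, a, y: g / a)

    def sqrt(self):
        return _unary(self, np.sqrt, lambda g, a, y: g * 0.5 / np.maximum(y, 1e-300))

    def abs(self):
        return _unary(self, np.abs, lambda g, a, y: g * np.sign(a))

    # reductions / shape ------------------------------------------------ #
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a, y):
            if axis is None:
                return np.broadcast_to(g, a.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, a.shape).copy()
        return _unary(self, lambda a: a.sum(axis=axis, keepdims=keepdims), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _unary(self, lambda a: a.reshape(shape),
                      lambda g, a, y: g.reshape(a.shape))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return _unary(self, lambda a: a.transpose(axes),
                      lambda g, a, y: g.transpose(inv))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unary(x: Tensor, fwd, bwd) -> Tensor:
    out = Tensor(fwd(x.data))
    if _grad_enabled and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def _run(g, x=x, out=out):
            x._accumulate(_unbroadcast(bwd(g, x.data, out.data), x.data.shape))
        out._backward = _run
    return out


def _binary(x: Tensor, y, fwd, bwd_x, bwd_y) -> Tensor:
    y = as_tensor(y)
    out = Tensor(fwd(x.data, y.data))
    if _grad_enabled and (x.requires_grad or y.requires_grad):
        out.requires_grad = True
        out._parents = tuple(t for t in (x, y) if t.requires_grad)

        def _run(g, x=x, y=y):
            if x.requires_grad:
                x._accumulate(_unbroadcast(bwd_x(g, x.data, y.data), x.data.shape))
            if y.requires_grad:
                y._accumulate(_unbroadcast(bwd_y(g, x.data, y.data), y.data.shape))
        out._backward = _run
    return out


def custom(fwd_value: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    """Wrap a numpy forward result with an analytic backward.

    ``backward(grad)`` must return one gradient array per parent (or None
    for parents that do not require grad).
    """
    out = Tensor(fwd_value)
    reqs = [p.requires_grad for p in parents]
    if _grad_enabled and any(reqs):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)

        def _run(g, parents=parents):
            grads = backward(g)
            for p, pg in zip(parents, grads):
                if p.requires_grad and pg is not None:
                    p._accumulate(np.asarray(pg, dtype=p.data.dtype))
        out._backward = _run
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def _run(g, tensors=tensors):
            parts = np.split(g, splits, axis=axis)
            for t, pg in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(pg)
        out._backward = _run
    return out


# --------------------------------------------------------------------------- #
# convolution
# --------------------------------------------------------------------------- #

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, oh*ow) matrix of sliding patches."""
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    buf = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            buf[:, :, i, j] = x[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride]
    return buf.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += cols[:, :, i, j]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``w`` has shape (C_out, C_in, kh, kw); ``pad`` is symmetric zero padding.
    """
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n = xd.shape[0]
    cout, cin, kh, kw = w.shape
    cols, oh, ow = _im2col(xd, kh, kw, stride)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols).reshape(n, cout, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(n, cout, oh * ow)
        gx = gw = gb = None
        if w.requires_grad:
            gw = np.matmul(gmat, cols.swapaxes(1, 2)).sum(axis=0).reshape(w.shape)
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            gpad = _col2im(gcols, xd.shape, kh, kw, stride)
            gx = gpad[:, :, pad:gpad.shape[2] - pad, pad:gpad.shape[3] - pad] if pad else gpad
        if b is not None and b.requires_grad:
            gb = g.sum(axis=(0, 2, 3)).reshape(b.shape)
        return (gx, gw) if b is None else (gx, gw, gb)

    return custom(out, parents, backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling, NCHW."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h, w = g.shape
        return (g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)),)

    return custom(out, (x,), backward)
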