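"""Minimal reverse-mode autodiff and neural-network layers on numpy.

The reconstruction model needs 2D/3D convolutional networks with end-to-end
gradients, including through fixed sparse tomographic operators.  This module
provides exactly that surface and nothing more: a :class:`Tensor` with a
dynamic tape, convolution/normalization/activation primitives implemented as
im2col matrix products, sparse backprojection ("lifting") and fan-beam
projection ops whose gradients are the exact operator transposes, and an Adam
optimizer.  All gradients are validated against finite differences in the
test suite.

Array layout is channels-first with an explicit batch axis:
``(N, C, H, W)`` in 2D and ``(N, C, X, Y, Z)`` in 3D.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import sparse as _sparse


# --------------------------------------------------------------------------- #
# Tensor and tape
# --------------------------------------------------------------------------- #
class Tensor:
    """A numpy array with gradient tracking on a dynamic tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype if self.data.dtype.kind == "f" else np.float64)
        self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-sweep the tape from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(
            self, other, np.multiply, lambda g, a, b: (g * b.data, g * a.data)
        )

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        return _binary(
            self,
            other,
            np.divide,
            lambda g, a, b: (g / b.data, -g * a.data / (b.data**2)),
        )

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = Tensor(self.data**p, requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                self._accumulate(out.grad * p * self.data ** (p - 1))

            out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

            out._backward = _bw
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            src_shape = self.data.shape

            def _bw():
                self._accumulate(out.grad.reshape(src_shape))

            out._backward = _bw
        return out

    def transpose(self, axes: Sequence[int]):
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            inv = np.argsort(axes)

            def _bw():
                self._accumulate(out.grad.transpose(inv))

            out._backward = _bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
        )
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def item(self) -> float:
        return float(self.data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, grads) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(fwd(a.data, b.data), requires_grad=a.requires_grad or b.requires_grad)
    if out.requires_grad:
        out._parents = (a, b)

        def _bw():
            ga, gb = grads(out.grad, a, b)
            if a.requires_grad:
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(gb, b.data.shape))

        out._backward = _bw
    return out


# --------------------------------------------------------------------------- #
# Elementwise nonlinearities
# --------------------------------------------------------------------------- #
def _unary(x: Tensor, y: np.ndarray, dydx: np.ndarray) -> Tensor:
    out = Tensor(y, requires_grad=x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bw():
            x._accumulate(out.grad * dydx)

        out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    return _unary(x, np.maximum(x.data, 0), (x.data > 0).astype(x.data.dtype))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    d = np.where(x.data > 0, 1.0, slope).astype(x.data.dtype)
    return _unary(x, np.where(x.data > 0, x.data, slope * x.data), d)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, y, (y * (1.0 - y)).astype(x.data.dtype))


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    return _unary(x, y, y)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log(x.data), 1.0 / x.data)


def abs_(x: Tensor) -> Tensor:
    return _unary(x, np.abs(x.data), np.sign(x.data))


def sqrt(x: Tensor) -> Tensor:
    y = np.sqrt(x.data)
    return _unary(x, y, 0.5 / np.maximum(y, np.finfo(y.dtype).tiny))


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, requires_grad=x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bw():
            g = out.grad
            x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        out._backward = _bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
    )
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]

        def _bw():
            pieces = np.split(out.grad, np.cumsum(sizes)[:-1], axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(g)

        out._backward = _bw
    return out


# --------------------------------------------------------------------------- #
# Convolution
# --------------------------------------------------------------------------- #
def _pad_spatial(x: np.ndarray, lo: int, hi: int, dims: int) -> np.ndarray:
    if lo == 0 and hi == 0:
        return x
    pads = [(0, 0), (0, 0)] + [(lo, hi)] * dims
    return np.pad(x, pads)


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """N-dimensional convolution (cross-correlation) with exact gradients.

    ``x``: (N, Cin, *spatial); ``w``: (Cout, Cin, *k); optional bias (Cout,).

    Computed as a sum over the k^dims kernel offsets of channel-mixing matrix
    products on regular strided slices (shift-and-add), which keeps memory
    access contiguous; the backward pass reuses the same slices, so the
    input gradient is the exact transpose operation.
    """
    from itertools import product as _product

    dims = x.ndim - 2
    k = w.shape[-1]
    in_sp = x.shape[2:]
    n, cin = x.shape[:2]
    cout = w.shape[0]
    xp = _pad_spatial(x.data, pad, pad, dims)
    out_sp = tuple((xp.shape[2 + d] - k) // stride + 1 for d in range(dims))
    n_pos = int(np.prod(out_sp))
    offsets = list(_product(range(k), repeat=dims))
    slices = [
        tuple(
            slice(o[d], o[d] + (out_sp[d] - 1) * stride + 1, stride)
            for d in range(dims)
        )
        for o in offsets
    ]
    y = np.zeros((n, cout, n_pos), dtype=x.data.dtype)
    for o, sl in zip(offsets, slices):
        xs = xp[(slice(None), slice(None)) + sl].reshape(n, cin, n_pos)
        y += w.data[(slice(None), slice(None)) + o] @ xs
    y = y.reshape((n, cout) + out_sp)
    if b is not None:
        y = y + b.data.reshape((1, -1) + (1,) * dims)
    out = Tensor(y, requires_grad=x.requires_grad or w.requires_grad or (b is not None and b.requires_grad))
    if not out.requires_grad:
        return out
    out._parents = (x, w) if b is None else (x, w, b)

    def _bw():
        g = out.grad
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, 2 + dims))))
        gflat = g.reshape(n, cout, n_pos)
        dw = np.zeros_like(w.data) if w.requires_grad else None
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for o, sl in zip(offsets, slices):
            if w.requires_grad:
                xs = xp[(slice(None), slice(None)) + sl].reshape(n, cin, n_pos)
                dw[(slice(None), slice(None)) + o] = np.tensordot(
                    gflat, xs, axes=([0, 2], [0, 2])
                )
            if x.requires_grad:
                contrib = w.data[(slice(None), slice(None)) + o].T @ gflat
                dxp[(slice(None), slice(None)) + sl] += contrib.reshape(
                    (n, cin) + out_sp
                )
        if w.requires_grad:
            w._accumulate(dw)
        if x.requires_grad:
            if pad:
                crop = (slice(None), slice(None)) + tuple(
                    slice(pad, pad + in_sp[d]) for d in range(dims)
                )
                x._accumulate(dxp[crop])
            else:
                x._accumulate(dxp)

    out._backward = _bw
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbor upsampling of all spatial axes by ``factor``."""
    dims = x.ndim - 2
    y = x.data
    for d in range(dims):
        y = np.repeat(y, factor, axis=2 + d)
    out = Tensor(y, requires_grad=x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        in_sp = x.shape[2:]

        def _bw():
            g = out.grad
            # fold each spatial axis into (size, factor) blocks and sum
            shape = list(g.shape[:2])
            for s in in_sp:
                shape += [s, factor]
            g = g.reshape(shape)
            for d in range(dims):
                g = g.sum(axis=3 + d)
            x._accumulate(g)

        out._backward = _bw
    return out


# --------------------------------------------------------------------------- #
# Fixed sparse tomographic ops
# --------------------------------------------------------------------------- #
def sparse_lift(x: Tensor, weights: _sparse.spmatrix, n_image: int) -> Tensor:
    """Lift 2D feature maps (N, C, D, Z) to 3D (N, C, n, n, Z) through ``weights``.

    ``weights`` is the (n*n, D) backprojection matrix; the gradient applies
    its exact transpose.  Rows at different z never mix.
    """
    W = weights
    n_batch, c, d, z = x.shape
    if W.shape[1] != d:
        raise ValueError(f"feature detector size {d} != matrix columns {W.shape[1]}")
    outs = np.empty((n_batch, c, n_image, n_image, z), dtype=x.data.dtype)
    for i in range(n_batch):
        flat = x.data[i].transpose(1, 0, 2).reshape(d, c * z)
        lifted = W @ flat
        outs[i] = lifted.reshape(n_image, n_image, c, z).transpose(2, 0, 1, 3)
    out = Tensor(outs, requires_grad=x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bw():
            g = out.grad
            dx = np.empty_like(x.data)
            for i in range(n_batch):
                flat = g[i].transpose(1, 2, 0, 3).reshape(n_image * n_image, c * z)
                back = W.T @ flat
                dx[i] = back.reshape(d, c, z).transpose(1, 0, 2)
            x._accumulate(dx)

        out._backward = _bw
    return out


def fan_project(x: Tensor, matrix: _sparse.spmatrix) -> Tensor:
    """Project volumes (N, 1, n, n, n) to (N, 1, D, n) through a sparse projector."""
    n_batch, c, nx, ny, nz = x.shape
    if c != 1 or matrix.shape[1] != nx * ny:
        raise ValueError("fan_project expects (N, 1, n, n, n) matching the projector")
    d = matrix.shape[0]
    outs = np.empty((n_batch, 1, d, nz), dtype=x.data.dtype)
    for i in range(n_batch):
        outs[i, 0] = matrix @ x.data[i, 0].reshape(nx * ny, nz)
    out = Tensor(outs, requires_grad=x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bw():
            g = out.grad
            dx = np.empty_like(x.data)
            for i in range(n_batch):
                dx[i, 0] = (matrix.T @ g[i, 0]).reshape(nx, ny, nz)
            x._accumulate(dx)

        out._backward = _bw
    return out


# --------------------------------------------------------------------------- #
# Modules
# --------------------------------------------------------------------------- #
class Module:
    """Base class: tracks parameters through attributes and sub-modules."""

    def parameters(self) -> list[Tensor]:
        """All parameter tensors, frozen or not (see trainable_parameters)."""
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect_params(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect_params(v) -> list[Tensor]:
    if isinstance(v, Tensor):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect_params(item))
        return out
    return []


class Conv(Module):
    """Strided N-d convolution with He-normal initialization."""

    def __init__(self, dims, cin, cout, k=3, stride=1, pad=None, bias=True, *, rng):
        self.dims = dims
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        fan_in = cin * k**dims
        std = math.sqrt(2.0 / fan_in)
        self.w = Tensor(
            rng.normal(0.0, std, size=(cout, cin) + (k,) * dims).astype(np.float32),
            requires_grad=True,
        )
        self.b = (
            Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.w, self.b, stride=self.stride, pad=self.pad)


class InstanceNorm(Module):
    """Per-sample per-channel normalization over spatial axes, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        dims = tuple(range(2, x.ndim))
        mu = x.mean(axis=dims, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=dims, keepdims=True)
        inv = (var + self.eps) ** -0.5
        shape = (1, -1) + (1,) * (x.ndim - 2)
        return xc * inv * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class Lambda(Module):
    def __init__(self, fn):
        self.fn = fn

    def forward(self, x: Tensor) -> Tensor:
        return self.fn(x)


class Adam:
    """Adam optimizer; GAN-conventional betas are (0.5, 0.999)."""

    def __init__(self, params: Sequence[Tensor], lr: float, betas=(0.9, 0.999), eps=1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(a) for a in state["m"]]
        self.v = [np.array(a) for a in state["v"]]
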