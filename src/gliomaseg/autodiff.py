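"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd style: each operation builds
a :class:`Tensor` holding its value and a closure that routes the
upstream gradient to its parents.  The op set is exactly what the 3D
attention U-Net needs — broadcast arithmetic, elementwise
nonlinearities, axis reductions, channel concatenation, same/valid 3D
convolution (im2col + BLAS), 2x max-pooling, 2x nearest-neighbor
upsampling, and instance normalization.

Feature blocks are laid out ``(C, X, Y, Z)`` without a batch axis;
batching is a loop over cases.  Gradients accumulate in ``float64`` or
``float32`` following the data dtype, so the engine doubles as the
high-precision comparator in the convolution gradient check.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "div",
    "exp",
    "log",
    "relu",
    "sigmoid",
    "sum_all",
    "sum_axis",
    "reshape",
    "concat",
    "conv3d",
    "maxpool3d",
    "upsample_nearest3d",
    "instance_norm",
    "spatial_mean",
    "Adam",
]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo, seen = [], set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


def _needs_tape(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_tape(*parents):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- broadcast arithmetic ----------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(-_unbroadcast(g, b.shape))

    return _node(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.shape))
        b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

    return _node(a.data / b.data, (a, b), backward)


# -- elementwise nonlinearities ----------------------------------------------


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _node(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), backward)


# -- reductions / reshaping --------------------------------------------------


def sum_all(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))

    return _node(np.asarray(a.data.sum()), (a,), backward)


def sum_axis(a: Tensor, axis, keepdims: bool = True) -> Tensor:
    axes = (axis,) if isinstance(axis, int) else tuple(axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))

    return _node(a.data.sum(axis=axes, keepdims=keepdims), (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.shape

    def backward(g):
        a._accumulate(g.reshape(orig))

    return _node(a.data.reshape(shape), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _node(
        np.concatenate([t.data for t in tensors], axis=axis),
        tuple(tensors),
        backward,
    )


# -- spatial ops -------------------------------------------------------------


def _im2col(xp: np.ndarray, k: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    """(Cin, Xp, Yp, Zp) -> (Cin*k^3, V) window matrix.

    Filled by k^3 contiguous slice copies (channels-first layout keeps
    every copy and the subsequent BLAS call cache-friendly).
    """
    cin = xp.shape[0]
    ox, oy, oz = (s - k + 1 for s in xp.shape[1:])
    col = np.empty((cin, k, k, k, ox, oy, oz), dtype=xp.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                col[:, a, b, c] = xp[:, a : a + ox, b : b + oy, c : c + oz]
    return col.reshape(cin * k**3, ox * oy * oz), (ox, oy, oz)


def conv3d(
    x: Tensor, w: Tensor, bias: Tensor | None = None, padding: int | str = "same"
) -> Tensor:
    """3D cross-correlation: x (Cin,X,Y,Z) * w (Cout,Cin,k,k,k).

    ``padding="same"`` zero-pads by ``k//2`` (odd ``k``); ``padding=0``
    is the valid convolution of the reference equations.
    """
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    if x.shape[0] != cin:
        raise ValueError(f"input channels {x.shape[0]} != kernel Cin {cin}")
    pad = k // 2 if padding == "same" else int(padding)
    xp = (
        np.pad(x.data, [(0, 0)] + [(pad, pad)] * 3) if pad else x.data
    )
    col, (ox, oy, oz) = _im2col(xp, k)
    wm = w.data.reshape(cout, cin * k**3)
    out_flat = wm @ col  # (Cout, V)
    if bias is not None:
        out_flat = out_flat + bias.data[:, None]
    out_data = out_flat.reshape(cout, ox, oy, oz)

    parents = (x, w) if bias is None else (x, w, bias)

    def backward(g):
        gm = g.reshape(cout, -1)
        w._accumulate((gm @ col.T).reshape(w.shape))
        if bias is not None:
            bias._accumulate(gm.sum(axis=1))
        dcol = (wm.T @ gm).reshape(cin, k, k, k, ox, oy, oz)
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[:, a : a + ox, b : b + oy, c : c + oz] += dcol[:, a, b, c]
        x._accumulate(
            dxp[:, pad : pad + x.shape[1], pad : pad + x.shape[2],
                pad : pad + x.shape[3]]
            if pad
            else dxp
        )

    return _node(out_data, parents, backward)


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even.  Ties resolve to
    the first (lowest flat index) element, deterministically."""
    c, nx, ny, nz = x.shape
    if nx % 2 or ny % 2 or nz % 2:
        raise ValueError("maxpool3d requires even spatial dims")
    xr = (
        x.data.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, nx // 2, ny // 2, nz // 2, 8)
    )
    idx = np.argmax(xr, axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        dx = (
            gr.reshape(c, nx // 2, ny // 2, nz // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, nx, ny, nz)
        )
        x._accumulate(dx)

    return _node(out_data, (x,), backward)


def upsample_nearest3d(x: Tensor) -> Tensor:
    """2x nearest-neighbor upsampling; adjoint is 2x2x2 block summing."""
    out_data = (
        x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    )
    c, nx, ny, nz = x.shape

    def backward(g):
        x._accumulate(
            g.reshape(c, nx, 2, ny, 2, nz, 2).sum(axis=(2, 4, 6))
        )

    return _node(out_data, (x,), backward)


def instance_norm(
    x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5
) -> Tensor:
    """Per-channel normalization over the spatial axes.

    ``y = gamma * (x - mu_c) / sqrt(var_c + eps) + beta`` with
    ``gamma``/``beta`` shaped ``(C, 1, 1, 1)``.
    """
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True))
        beta._accumulate(g.sum(axis=axes, keepdims=True))
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        x._accumulate(inv_std * (dxhat - m1 - xhat * m2))

    return _node(out_data, (x, gamma, beta), backward)


def spatial_mean(x: Tensor) -> Tensor:
    """Global average pool: (C, X, Y, Z) -> (C, 1, 1, 1)."""
    n = x.data[0].size
    out_data = x.data.mean(axis=(1, 2, 3), keepdims=True)

    def backward(g):
        x._accumulate(np.broadcast_to(g / n, x.shape).astype(x.data.dtype))

    return _node(out_data, (x,), backward)


# -- optimizer ---------------------------------------------------------------


class Adam:
    """Adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
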