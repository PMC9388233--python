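"""Reference 3D convolution layer with handwritten gradients.

Single-channel, stride-1, *valid* cross-correlation, written directly
from the layer equations:

    forward:   x_ijk = sum_{a,b,c} w_abc * y_{(i+a)(j+b)(k+c)},  y' = sigma(x)
    d/dw:      dE/dw_abc = sum_{i,j,k} dE/dx_ijk * y_{(i+a)(j+b)(k+c)}
    d/dy:      dE/dy_ijk = sum_{a,b,c} dE/dx_{(i-a)(j-b)(k-c)} * w_abc

This module is the correctness oracle: the trainable network's
reverse-mode gradients and central finite differences are both checked
against it on small inputs.  No kernel flip — the index convention is
cross-correlation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "conv3d_forward",
    "conv3d_backward_weights",
    "conv3d_backward_input",
    "activation_backward",
    "gradient_check",
    "GradCheckReport",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# name -> (sigma, sigma')
ACTIVATIONS = {
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
    "sigmoid": (_sigmoid, lambda x: _sigmoid(x) * (1.0 - _sigmoid(x))),
    "relu": (
        lambda x: np.maximum(x, 0.0),
        lambda x: (x > 0).astype(np.float64),
    ),
}


def _windows(y: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Sliding-window view: ``win[a,b,c,i,j,k] = y[a+i, b+j, c+k]``."""
    return np.lib.stride_tricks.sliding_window_view(y, shape)


def conv3d_forward(
    y: np.ndarray, w: np.ndarray, activation: str = "identity"
) -> tuple[np.ndarray, np.ndarray]:
    """Valid cross-correlation followed by the activation.

    Returns ``(preactivation x, output sigma(x))`` with output side
    ``N - m + 1`` per axis.
    """
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if y.ndim != 3 or w.ndim != 3:
        raise ValueError("input and kernel must be 3D")
    if any(n < m for n, m in zip(y.shape, w.shape)):
        raise ValueError(f"kernel {w.shape} larger than input {y.shape}")
    x = np.einsum("ijkabc,abc->ijk", _windows(y, w.shape), w)
    sigma, _ = ACTIVATIONS[activation]
    return x, sigma(x)


def conv3d_backward_weights(grad_preact: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Weight gradient: correlate the input with the upstream deltas."""
    g = np.asarray(grad_preact, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m = tuple(n - o + 1 for n, o in zip(y.shape, g.shape))
    if any(v < 1 for v in m):
        raise ValueError("delta shape inconsistent with input shape")
    # win[a,b,c,i,j,k] = y[(i+a)(j+b)(k+c)] with (a,b,c) the window start
    return np.einsum("abcijk,ijk->abc", _windows(y, g.shape), g)


def activation_backward(
    grad_output: np.ndarray, preact: np.ndarray, activation: str = "identity"
) -> np.ndarray:
    """Chain through the activation: ``dE/dx = dE/dy * sigma'(x)``."""
    grad_output = np.asarray(grad_output, dtype=np.float64)
    preact = np.asarray(preact, dtype=np.float64)
    if grad_output.shape != preact.shape:
        raise ValueError("gradient/preactivation shape mismatch")
    _, dsigma = ACTIVATIONS[activation]
    return grad_output * dsigma(preact)


def conv3d_backward_input(
    grad_preact: np.ndarray, w: np.ndarray, input_shape: tuple[int, int, int]
) -> np.ndarray:
    """Input gradient: full correlation of the deltas with the kernel.

    ``dE/dy_ijk = sum_abc dE/dx_{(i-a)(j-b)(k-c)} w_abc`` with
    out-of-range delta terms zero; realized by zero-padding the deltas
    by ``m-1`` per side and correlating with the index-reversed kernel.
    """
    g = np.asarray(grad_preact, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    expect = tuple(n - m + 1 for n, m in zip(input_shape, w.shape))
    if g.shape != expect:
        raise ValueError(f"delta shape {g.shape} inconsistent with {expect}")
    gp = np.pad(g, [(m - 1, m - 1) for m in w.shape])
    return np.einsum(
        "ijkabc,abc->ijk", _windows(gp, w.shape), w[::-1, ::-1, ::-1]
    )


@dataclass
class GradCheckReport:
    """Maximum relative discrepancies of the two verification routes."""

    max_rel_err_weights_fd: float
    max_rel_err_input_fd: float
    max_rel_err_weights_autodiff: float
    max_rel_err_input_autodiff: float

    @property
    def max_rel_err_fd(self) -> float:
        return max(self.max_rel_err_weights_fd, self.max_rel_err_input_fd)

    @property
    def max_rel_err_autodiff(self) -> float:
        return max(
            self.max_rel_err_weights_autodiff, self.max_rel_err_input_autodiff
        )


def _rel(a: np.ndarray, b: np.ndarray) -> float:
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
    return float(np.abs(a - b).max() / denom)


def gradient_check(
    input_shape: tuple[int, int, int] = (6, 6, 6),
    kernel_shape: tuple[int, int, int] = (3, 3, 3),
    activation: str = "sigmoid",
    seed: int = 0,
    fd_step: float = 1e-6,
) -> GradCheckReport:
    """Check the reference gradients against two independent routes.

    Uses the scalar loss ``E = sum(g ⊙ sigma(x))`` with a fixed random
    ``g`` and compares the handwritten backward equations with
    (a) central finite differences and (b) the trainable network's
    reverse-mode engine on identical weights.  Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(input_shape)
    w = rng.standard_normal(kernel_shape)
    out_shape = tuple(n - m + 1 for n, m in zip(input_shape, kernel_shape))
    g = rng.standard_normal(out_shape)
    sigma, _ = ACTIVATIONS[activation]

    def loss() -> float:
        _, out = conv3d_forward(y, w, activation)
        return float(np.sum(g * out))

    x, _ = conv3d_forward(y, w, activation)
    delta = activation_backward(g, x, activation)
    dw_ref = conv3d_backward_weights(delta, y)
    dy_ref = conv3d_backward_input(delta, w, input_shape)

    def fd(arr: np.ndarray) -> np.ndarray:
        grad = np.empty_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + fd_step
            hi = loss()
            arr[idx] = orig - fd_step
            lo = loss()
            arr[idx] = orig
            grad[idx] = (hi - lo) / (2 * fd_step)
        return grad

    dw_fd = fd(w)
    dy_fd = fd(y)

    from . import autodiff as ad

    ty = ad.Tensor(y[None].copy(), requires_grad=True)  # (Cin=1, X, Y, Z)
    tw = ad.Tensor(w[None, None].copy(), requires_grad=True)  # (1, 1, m, m, m)
    tx = ad.conv3d(ty, tw, bias=None, padding=0)
    tout = {"sigmoid": ad.sigmoid, "relu": ad.relu, "identity": lambda t: t}[
        activation
    ](tx)
    ad.sum_all(ad.mul(tout, ad.Tensor(g[None]))).backward()

    return GradCheckReport(
        max_rel_err_weights_fd=_rel(dw_ref, dw_fd),
        max_rel_err_input_fd=_rel(dy_ref, dy_fd),
        max_rel_err_weights_autodiff=_rel(dw_ref, tw.grad[0, 0]),
        max_rel_err_input_autodiff=_rel(dy_ref, ty.grad[0]),
    )
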