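"""Minimal neural-network core: 1D convolution, batch norm, dense layers,
dropout, and an Adam optimizer, in NumPy/Numba with hand-written backprop.

Layers operate on float32 arrays in ``(batch, length, channels)`` layout,
which keeps the convolution im2col buffers and the per-channel batch-norm
reductions contiguous. When ``stride == kernel`` (the spectral CNN's
halving convolutions) the im2col windows tile the input exactly, so the
column matrix is a plain reshape rather than a gather. The heavy
elementwise work (Adam moments, batch-norm normalization) runs through
fused single-pass Numba kernels; matrix products go through BLAS with
preallocated outputs.

Gradient semantics: ``backward`` *assigns* each parameter's gradient (one
backward pass per optimizer step), so no ``zero_grad`` call is needed
between steps.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _kernels

DTYPE = np.float32


class Parameter:
    """A trainable tensor with its gradient buffer."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class; stateless layers override forward/backward only."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1D convolution on (B, L, C_in) input via im2col + GEMM.

    The weight is stored as (C_out, kernel * C_in) with tap-major column
    order (all channels of tap 0, then tap 1, ...), matching the layout of
    the zero-copy reshape used when ``stride == kernel``. He-normal
    initialized. The first layer of a network can set ``input_grad=False``
    to skip the (unused) gradient with respect to the network input.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
        input_grad: bool = True,
    ) -> None:
        if kernel < 1 or stride < 1 or padding < 0:
            raise ValueError("kernel/stride must be >=1 and padding >=0")
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.input_grad = input_grad
        fan_in = c_in * kernel
        w = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(w, "conv.weight")
        self.bias = Parameter(np.zeros(c_out), "conv.bias")
        self._cols: np.ndarray | None = None
        self._in_length = 0

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    @property
    def _tiled(self) -> bool:
        return self.stride == self.kernel and self.padding == 0

    def output_length(self, length_in: int) -> int:
        eff = length_in + 2 * self.padding
        if eff < self.kernel:
            raise ValueError(
                f"input length {length_in} (+2*{self.padding} padding) shorter "
                f"than kernel {self.kernel}"
            )
        return (eff - self.kernel) // self.stride + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        k = self.kernel
        if self._tiled:
            used = (L // k) * k
            block = x if used == L else x[:, :used]
            return np.ascontiguousarray(block).reshape(B, -1, k * C)
        if self.padding:
            x = np.pad(x, ((0, 0), (self.padding, self.padding), (0, 0)))
        win = sliding_window_view(x, k, axis=1)[:, :: self.stride]  # (B,Lo,C,k)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            B, win.shape[1], k * C
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_length = x.shape[1]
        cols = self._im2col(x)
        self._cols = cols if training else None
        y = cols @ self.weight.data.T
        y += self.bias.data
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols = self._cols
        assert cols is not None, "backward before forward(training=True)"
        B, L_out, _ = dy.shape
        k, s, C = self.kernel, self.stride, self.c_in
        dy2 = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        np.matmul(dy2.T, cols.reshape(-1, C * k), out=self.weight.grad)
        self.bias.grad[...] = dy2.sum(axis=0)
        self._cols = None
        if not self.input_grad:
            return np.empty(0, dtype=DTYPE)
        dcols = dy @ self.weight.data  # (B, L_out, k*C) tap-major
        L_pad = self._in_length + 2 * self.padding
        if self._tiled:
            dx = np.empty((B, L_pad, C), dtype=DTYPE)
            dx[:, : L_out * k] = dcols.reshape(B, L_out * k, C)
            dx[:, L_out * k :] = 0.0  # tail positions the windows never cover
        else:
            dx = np.zeros((B, L_pad, C), dtype=DTYPE)
            dtap = dcols.reshape(B, L_out, k, C)
            for t in range(k):
                # scatter-add each tap; windows overlap when stride < kernel
                dx[:, t : t + L_out * s : s] += dtap[:, :, t]
        if self.padding:
            dx = dx[:, self.padding : dx.shape[1] - self.padding]
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the (batch, length) axes.

    Training normalizes with batch statistics and updates running
    mean/variance (exponential average with momentum 0.1, unbiased variance
    for the running estimate — the common deep-learning convention);
    inference uses the running statistics, making prediction deterministic.
    With ``relu=True`` the activation is fused into the same kernel pass
    (the conv stages always pair batch norm with ReLU).
    """

    def __init__(
        self,
        channels: int,
        eps: float = 1e-5,
        momentum: float = 0.1,
        relu: bool = False,
    ) -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.relu = relu
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        shape = x.shape
        x2 = np.ascontiguousarray(x, dtype=DTYPE).reshape(-1, shape[-1])
        if training:
            n = x2.shape[0]
            mean = np.empty(self.channels, dtype=DTYPE)
            var = np.empty(self.channels, dtype=DTYPE)
            _kernels.bn_stats(x2, mean, var)
            m = DTYPE(self.momentum)
            self.running_mean *= 1 - m
            self.running_mean += m * mean
            self.running_var *= 1 - m
            self.running_var += m * var * (n / max(n - 1, 1))
            inv_std = 1.0 / np.sqrt(var + DTYPE(self.eps))
            xhat = np.empty_like(x2)
            out = np.empty_like(x2)
            fwd = _kernels.bn_relu_forward if self.relu else _kernels.bn_forward
            fwd(x2, mean, inv_std, self.gamma.data, self.beta.data, xhat, out)
            self._xhat, self._inv_std = xhat, inv_std
            return out.reshape(shape)
        inv_std = 1.0 / np.sqrt(self.running_var + DTYPE(self.eps))
        scale = self.gamma.data * inv_std
        shift = self.beta.data - self.running_mean * scale
        out = (x * scale + shift).astype(DTYPE, copy=False)
        if self.relu:
            out = np.maximum(out, DTYPE(0.0))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        assert xhat is not None and inv_std is not None
        shape = dy.shape
        dy2 = np.ascontiguousarray(dy, dtype=DTYPE).reshape(-1, shape[-1])
        dx2 = np.empty_like(dy2)
        if self.relu:
            _kernels.bn_relu_backward(
                dy2, xhat, self.gamma.data, self.beta.data, inv_std,
                self.gamma.grad, self.beta.grad, dx2,
            )
        else:
            _kernels.bn_backward(
                dy2, xhat, self.gamma.data, inv_std,
                self.gamma.grad, self.beta.grad, dx2,
            )
        self._xhat = self._inv_std = None
        return dx2.reshape(shape)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, DTYPE(0.0))
        self._mask = (x > 0.0) if training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        assert mask is not None
        self._mask = None
        return dy * mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        mask, self._mask = self._mask, None
        return dy * mask


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] = ()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    """Dense layer; weight stored (n_in, n_out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.weight = Parameter(w, "linear.weight")
        self.bias = Parameter(np.zeros(n_out), "linear.bias")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        y = x @ self.weight.data
        y += self.bias.data
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        dy = np.ascontiguousarray(dy)
        np.matmul(x.T, dy, out=self.weight.grad)
        self.bias.grad[...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.weight.data.T


class Network:
    """A simple sequential container."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.parameters()):
                state[f"layer{i}.param{j}"] = p.data
            if isinstance(layer, BatchNorm1d):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.parameters()):
                p.data[...] = state[f"layer{i}.param{j}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]


class Adam:
    """Adam with L2 weight decay folded into the gradient (the classic
    formulation: biased moment estimates, bias correction through the step
    size). Updates run through a fused single-pass kernel."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        lr_t = DTYPE(
            self.lr * np.sqrt(1.0 - self.b2**self.t) / (1.0 - self.b1**self.t)
        )
        b1, b2 = DTYPE(self.b1), DTYPE(self.b2)
        eps2 = DTYPE(self.eps * self.eps)
        wd = DTYPE(self.weight_decay)
        for p, m, v in zip(self.params, self._m, self._v):
            _kernels.adam_update(
                p.data.ravel(), p.grad.ravel(), m.ravel(), v.ravel(),
                lr_t, b1, b2, eps2, wd,
            )


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred.astype(np.float64) - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(DTYPE, copy=False)
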