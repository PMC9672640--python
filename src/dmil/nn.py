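"""Lightweight NumPy neural-network layers with explicit reverse-mode gradients.

The whole model (conv backbone, MIL pooling head, bag classifier) is small
enough that hand-derived backward passes over ``numpy`` arrays are practical
and keep training bit-reproducible: every source of randomness is a
``numpy.random.Generator`` passed in explicitly, and no layer holds hidden
state beyond the caches written during a ``train=True`` forward pass.

Conventions
-----------
* Image tensors are ``(N, C, H, W)``; embedding matrices are ``(K, D)``.
* ``forward(x, train=True)`` caches what ``backward`` needs; inference calls
  use ``train=False`` and cache nothing.
* Gradients accumulate into ``Parameter.grad``; optimizers read/write
  ``Parameter.value`` in place.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    """Base class: parameter discovery by attribute walk, gradient zeroing."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in self.__dict__.values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col + one GEMM.

    Weights use He initialization, suited to the ReLU blocks they feed.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in))
        self.weight = Parameter(w.astype(dtype), "conv.weight")
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype), "conv.bias")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        out = cols @ self.weight.value.T + self.bias.value
        if train:
            self._cache = (cols, x.shape, ho, wo)
        else:
            self._cache = None
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        cols, xshape, ho, wo = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = xshape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.weight.grad += dmat.T @ cols
        self.bias.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.weight.value).reshape(n, ho, wo, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, ho, wo, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ]
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Module):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Module):
    """2x2, stride-2 max pooling; ties resolve to the first (row-major) max."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        n, c, h, w = xshape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._cache = None
        return dx


class Adam:
    """Adam optimizer with bias-corrected first/second moments."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # piecewise-stable logistic
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss with respect to each logit. Computed in the numerically stable
    ``max(l,0) - l*y + log(1 + exp(-|l|))`` form.
    """
    logits = np.atleast_1d(np.asarray(logits, dtype=float))
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    if logits.shape != targets.shape:
        raise ValueError("logits and targets must have matching shapes")
    loss = np.maximum(logits, 0) - logits * targets + np.log1p(
        np.exp(-np.abs(logits))
    )
    dlogits = (sigmoid(logits) - targets) / logits.size
    return float(loss.mean()), dlogits
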