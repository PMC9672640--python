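"""MIL pooling operators: max, convolutional and attention aggregation.

A bag of K instance embeddings ``H = {h_1, ..., h_K}`` (rows of a K x D
matrix) is reduced to a single bag representation ``z`` in one of three ways:

* **max** — ``z[d] = max_k h_k[d]``, a per-feature maximum across instances;
* **conv** — ``z = sum_k u[k] h_k``, a learned K x 1 kernel applied across the
  instance axis, one kernel shared by all D feature channels, no bias;
* **attention** — a learned convex combination ``z = sum_k a_k h_k`` with

  .. math:: a_k = \\frac{\\exp\\{w^T \\tanh(V h_k)\\}}
                       {\\sum_j \\exp\\{w^T \\tanh(V h_j)\\}}

  so the weights are positive and sum to one; the softmax is stabilized by
  subtracting the maximum score.

The bag representation is scored by a fully connected layer with a sigmoid,
giving a response probability in [0, 1].

Pure functions here define the operators; the ``*Head`` modules at the bottom
wrap the same math with gradients for training.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from . import nn

DEFAULT_ATTENTION_DIM = 128  # hidden size L of the attention score network

__all__ = [
    "AttentionParams",
    "ConvPoolParams",
    "ClassifierHead",
    "max_pool_bag",
    "conv_pool_bag",
    "attention_pool_bag",
    "classify_bag",
    "MaxPoolHead",
    "ConvPoolHead",
    "AttentionPoolHead",
    "BagClassifier",
    "make_pooling_head",
    "export_attention_csv",
    "DEFAULT_ATTENTION_DIM",
]


@dataclass
class AttentionParams:
    """Parameters of the two-layer attention score network: s_k = w . tanh(V h_k)."""

    V: np.ndarray  # (L, D)
    w: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.V.ndim != 2 or self.w.ndim != 1 or self.V.shape[0] != self.w.shape[0]:
            raise ValueError("V must be (L, D) and w (L,) with matching L")
        if self.V.shape[0] < 1:
            raise ValueError("attention hidden size L must be positive")
        if not (np.all(np.isfinite(self.V)) and np.all(np.isfinite(self.w))):
            raise ValueError("attention parameters must be finite")


@dataclass
class ConvPoolParams:
    """The K x 1 kernel applied across instances in convolutional pooling."""

    u: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 1 or not np.all(np.isfinite(self.u)):
            raise ValueError("u must be a finite vector")


@dataclass
class ClassifierHead:
    """Fully connected bag classifier: p = sigmoid(weight . z + bias)."""

    weight: np.ndarray  # (D,)
    bias: float = 0.0

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.bias = float(self.bias)
        if self.weight.ndim != 1 or not np.all(np.isfinite(self.weight)):
            raise ValueError("weight must be a finite vector")


def _check_embeddings(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[0] < 1:
        raise ValueError("embeddings must be a non-empty (K, D) matrix")
    if not np.all(np.isfinite(E)):
        raise ValueError("embeddings must be finite")
    return E


def max_pool_bag(E: np.ndarray) -> np.ndarray:
    """Per-feature maximum across instances: z[d] = max_k E[k, d]."""
    E = _check_embeddings(E)
    return E.max(axis=0)


def conv_pool_bag(E: np.ndarray, params: ConvPoolParams) -> np.ndarray:
    """Instance-axis convolution: z[d] = sum_k u[k] E[k, d] (no bias)."""
    E = _check_embeddings(E)
    if params.u.shape[0] != E.shape[0]:
        raise ValueError(
            f"kernel length {params.u.shape[0]} != bag size {E.shape[0]}"
        )
    return E.T @ params.u


def attention_pool_bag(
    E: np.ndarray, params: AttentionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Attention pooling: returns (z, a) with z = sum_k a_k h_k.

    Scores ``s_k = w . tanh(V h_k)`` pass through a softmax stabilized by
    subtracting ``max_k s_k``, so the weights are positive, sum to one, and
    survive score magnitudes far beyond floating-point exp range.
    """
    E = _check_embeddings(E)
    if params.V.shape[1] != E.shape[1]:
        raise ValueError(
            f"attention expects D={params.V.shape[1]}, got embeddings with D={E.shape[1]}"
        )
    scores = np.tanh(E @ params.V.T) @ params.w  # (K,)
    shifted = scores - scores.max()
    expw = np.exp(shifted)
    a = expw / expw.sum()
    z = E.T @ a
    return z, a


def classify_bag(z: np.ndarray, head: ClassifierHead) -> float:
    """Sigmoid score of the bag representation: p = sigmoid(w . z + b)."""
    z = np.asarray(z, dtype=float)
    if z.shape != head.weight.shape:
        raise ValueError("bag representation and head weight sizes differ")
    return float(nn.sigmoid(float(head.weight @ z) + head.bias))


def export_attention_csv(records, path) -> None:
    """Write per-instance attention weights as `bag_id, instance_index, weight`.

    ``records`` is an iterable of ``(bag_id, weights)`` pairs.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bag_id", "instance_index", "weight"])
        for bag_id, weights in records:
            for k, w in enumerate(np.asarray(weights, dtype=float)):
                writer.writerow([bag_id, k, repr(float(w))])


# ---------------------------------------------------------------------------
# trainable heads (forward caches -> hand-derived backward)
# ---------------------------------------------------------------------------


class MaxPoolHead(nn.Module):
    """Trainable wrapper around max pooling (no parameters).

    The gradient routes each feature's upstream derivative to the first
    instance attaining the maximum.
    """

    def __init__(self) -> None:
        self._cache = None

    def forward(self, E: np.ndarray, train: bool = False) -> np.ndarray:
        idx = E.argmax(axis=0)
        if train:
            self._cache = (idx, E.shape)
        return np.take_along_axis(E, idx[None, :], axis=0)[0]

    def backward(self, dz: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        dE = np.zeros(shape, dtype=dz.dtype)
        dE[idx, np.arange(shape[1])] = dz
        self._cache = None
        return dE


class ConvPoolHead(nn.Module):
    """Trainable K x 1 instance-axis convolution.

    The kernel starts as the uniform averaging kernel 1/K, i.e. pooling
    begins as mean pooling and training reweights instances from there.
    """

    def __init__(self, bag_size: int) -> None:
        if bag_size < 1:
            raise ValueError("bag_size must be positive")
        self.bag_size = int(bag_size)
        self.u = nn.Parameter(np.full(bag_size, 1.0 / bag_size), "convpool.u")
        self._cache = None

    def forward(self, E: np.ndarray, train: bool = False) -> np.ndarray:
        if E.shape[0] != self.bag_size:
            raise ValueError(
                f"conv pooling built for K={self.bag_size}, got bag of {E.shape[0]}"
            )
        if train:
            self._cache = E
        return E.T @ self.u.value

    def backward(self, dz: np.ndarray) -> np.ndarray:
        E = self._cache
        self.u.grad += E @ dz
        dE = np.outer(self.u.value, dz)
        self._cache = None
        return dE

    def params_view(self) -> ConvPoolParams:
        return ConvPoolParams(self.u.value.copy())


class AttentionPoolHead(nn.Module):
    """Trainable attention pooling.

    ``V`` is Xavier-initialized; ``w`` starts at zero so every bag begins with
    uniform attention (mean pooling) and the score network learns departures
    from uniformity rather than starting from an arbitrary random ranking.
    """

    def __init__(
        self,
        feature_dim: int,
        attention_dim: int = DEFAULT_ATTENTION_DIM,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.V = nn.Parameter(
            rng.normal(0.0, np.sqrt(1.0 / feature_dim), (attention_dim, feature_dim)),
            "attn.V",
        )
        self.w = nn.Parameter(np.zeros(attention_dim), "attn.w")
        self._cache = None
        self.last_weights: np.ndarray | None = None

    def forward(self, E: np.ndarray, train: bool = False) -> np.ndarray:
        z, a = attention_pool_bag(E, AttentionParams(self.V.value, self.w.value))
        t = np.tanh(E @ self.V.value.T)
        if train:
            self._cache = (E, t, a)
        self.last_weights = a
        return z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        E, t, a = self._cache
        da = E @ dz  # (K,)
        ds = a * (da - a @ da)  # softmax Jacobian
        self.w.grad += t.T @ ds
        du = ds[:, None] * self.w.value[None, :] * (1.0 - t**2)  # (K, L)
        self.V.grad += du.T @ E
        dE = du @ self.V.value + np.outer(a, dz)
        self._cache = None
        return dE

    def params_view(self) -> AttentionParams:
        return AttentionParams(self.V.value.copy(), self.w.value.copy())


class BagClassifier(nn.Module):
    """Fully connected layer + sigmoid producing the bag logit.

    Zero-initialized so untrained models score every bag at 0.5 and the first
    optimizer step moves the weight along the class-mean difference.
    """

    def __init__(self, feature_dim: int) -> None:
        self.weight = nn.Parameter(np.zeros(feature_dim), "head.weight")
        self.bias = nn.Parameter(np.zeros(()), "head.bias")
        self._cache = None

    def forward(self, z: np.ndarray, train: bool = False) -> float:
        if train:
            self._cache = z
        return float(self.weight.value @ z) + float(self.bias.value)

    def backward(self, dlogit: float) -> np.ndarray:
        z = self._cache
        self.weight.grad += dlogit * z
        self.bias.grad += dlogit
        self._cache = None
        return dlogit * self.weight.value

    def params_view(self) -> ClassifierHead:
        return ClassifierHead(self.weight.value.copy(), float(self.bias.value))


def make_pooling_head(
    pooling: str,
    feature_dim: int,
    bag_size: int = 32,
    attention_dim: int = DEFAULT_ATTENTION_DIM,
    rng: np.random.Generator | None = None,
) -> nn.Module:
    """Build a pooling head from its config string: max | conv | attention."""
    if pooling == "max":
        return MaxPoolHead()
    if pooling == "conv":
        return ConvPoolHead(bag_size)
    if pooling == "attention":
        return AttentionPoolHead(feature_dim, attention_dim, rng)
    raise ValueError(f"unknown pooling {pooling!r}; expected max, conv or attention")
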