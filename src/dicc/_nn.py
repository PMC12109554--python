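"""Minimal dense-network machinery: layers, SGD with momentum, cross-entropy.

Everything trained in this package is a stack of affine layers with ReLU
nonlinearities, so a small explicit-backprop implementation keeps the whole
training loop inspectable and bit-reproducible from a seed.  Gradients are
accumulated into ``Param.grad`` by ``backward`` and consumed by ``SGD.step``.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Param",
    "Linear",
    "ReLU",
    "Identity",
    "Sequential",
    "SGD",
    "softmax",
    "log_softmax",
    "softmax_cross_entropy",
    "param_checksum",
    "make_mlp",
]


class Param:
    """A trainable tensor with its gradient and momentum buffer."""

    __slots__ = ("data", "grad", "vel")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.vel = np.zeros_like(self.data)


class Linear:
    """Affine layer ``x @ W + b``.

    Hidden layers use He-normal initialisation (``init="he"``); output layers
    use a deliberately small scale (``init="head"``, std ``0.01/sqrt(n_in)``)
    so a freshly initialised classifier emits near-zero logits and its first
    cross-entropy sits at the uniform value ``ln K``.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, init: str = "he"):
        if init == "he":
            std = np.sqrt(2.0 / n_in)
        elif init == "head":
            std = 0.01 / np.sqrt(n_in)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.W = Param(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    @property
    def n_in(self) -> int:
        return self.W.data.shape[0]

    @property
    def n_out(self) -> int:
        return self.W.data.shape[1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before forward")
        self.W.grad += self._x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.W.data.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, 0.0)

    def params(self) -> list[Param]:
        return []


class Identity:
    """Parameter-free passthrough (a backbone that exposes raw features)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out

    def params(self) -> list[Param]:
        return []


class Sequential:
    def __init__(self, layers: Iterable):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def input_dim(self) -> int:
        for layer in self.layers:
            if isinstance(layer, Linear):
                return layer.n_in
        raise AttributeError("network has no affine layer")

    @property
    def output_dim(self) -> int:
        for layer in reversed(self.layers):
            if isinstance(layer, Linear):
                return layer.n_out
        raise AttributeError("network has no affine layer")


class SGD:
    """Stochastic gradient descent with classical momentum.

    Update rule: ``v <- momentum * v + grad; p <- p - lr * v``.
    """

    def __init__(self, params: Sequence[Param], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p in self.params:
            p.vel = self.momentum * p.vel + p.grad
            p.data -= self.lr * p.vel


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits.

    With ``class_weights`` the per-sample losses are weighted by the weight of
    the sample's class and normalised by the total weight in the batch (the
    usual weighted-CE convention), so unit weights reproduce the plain mean.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels must be a vector matching the batch size")
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    logp = log_softmax(logits)
    p = np.exp(logp)
    nll = -logp[np.arange(n), labels]
    onehot = np.zeros_like(logits)
    onehot[np.arange(n), labels] = 1.0
    if class_weights is None:
        loss = float(nll.mean())
        grad = (p - onehot) / n
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
        total = w.sum()
        loss = float((w * nll).sum() / total)
        grad = (p - onehot) * (w / total)[:, None]
    return loss, grad


def param_checksum(params: Sequence[Param]) -> str:
    """SHA-256 over the concatenated raw bytes of all parameters.

    Bit-identical parameters (and only those) yield equal checksums, which is
    what the freeze/reduction contracts of the training loop assert.
    """
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def make_mlp(dims: Sequence[int], rng: np.random.Generator) -> Sequential:
    """Build ``Linear/ReLU/.../Linear`` for the given layer widths."""
    if len(dims) < 2:
        raise ValueError("need at least input and output widths")
    layers: list = []
    for i in range(len(dims) - 1):
        last = i == len(dims) - 2
        layers.append(Linear(dims[i], dims[i + 1], rng, init="head" if last else "he"))
        if not last:
            layers.append(ReLU())
    return Sequential(layers)
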