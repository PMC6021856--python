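"""Minimal reverse-mode automatic differentiation over numpy arrays.

The habit-clustering autoencoders need gradients of a binary-log-loss
reconstruction objective through recurrent (GRU) and 1-D convolutional
graphs.  No deep-learning framework is available in the target
environment, so this module provides the small set of differentiable
primitives those models need: broadcasting arithmetic, matmul, sigmoid,
tanh, ReLU, reshape, reductions, temporal convolution, max-pooling and a
numerically-stable binary cross-entropy on logits.

Gradients are checked against central finite differences in the test
suite.  Desk-scale only: float64, no GPU, no kernel fusion.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv1d", "maxpool1d", "bce_with_logits", "Adam", "RMSProp", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the graph leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        out._backward = backward
        return out

    # -- elementwise nonlinearities --------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g * s * (1.0 - s)

        out._backward = backward
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g * (1.0 - t * t)

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g * mask

        out._backward = backward
        return out

    # -- shape / reduction ------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        out._backward = backward
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g * np.ones_like(self.data)

        out._backward = backward
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g * np.ones_like(self.data) / n

        out._backward = backward
        return out


def slice_time(x: Tensor, t: int) -> Tensor:
    """Select step ``t`` from a (batch, T, dim) tensor -> (batch, dim)."""
    out = Tensor(x.data[:, t, :], parents=(x,))

    def backward(g):
        if x.requires_grad:
            x.grad[:, t, :] += g

    out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid cross-correlation along the time axis.

    ``x``: (batch, T, C_in); ``w``: (K, C_in, C_out); ``b``: (C_out,).
    Output: (batch, T - K + 1, C_out).
    """
    x = Tensor._wrap(x)
    K = w.data.shape[0]
    if x.data.shape[1] < K:
        raise ValueError("kernel longer than the input sequence")
    windows = sliding_window_view(x.data, K, axis=1)  # (B, To, Ci, K)
    out_data = np.einsum("btik,kic->btc", windows, w.data) + b.data
    out = Tensor(out_data, parents=(x, w, b))

    def backward(g):  # g: (B, To, Co)
        if w.requires_grad:
            w.grad += np.einsum("btik,btc->kic", windows, g)
        if b.requires_grad:
            b.grad += g.sum(axis=(0, 1))
        if x.requires_grad:
            To = g.shape[1]
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, k : k + To, :] += np.einsum("btc,kic->bti", g, w.data[k : k + 1])
            x.grad += gx

    out._backward = backward
    return out


def maxpool1d(x: Tensor, width: int) -> Tensor:
    """Non-overlapping max-pool of ``width`` along time; remainder truncated."""
    B, T, C = x.data.shape
    To = T // width
    view = x.data[:, : To * width, :].reshape(B, To, width, C)
    arg = view.argmax(axis=2)  # (B, To, C)
    out = Tensor(view.max(axis=2), parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros((B, To, width, C))
            bi, ti, ci = np.meshgrid(
                np.arange(B), np.arange(To), np.arange(C), indexing="ij"
            )
            gx[bi, ti, arg, ci] = g
            x.grad += np.pad(
                gx.reshape(B, To * width, C), ((0, 0), (0, T - To * width), (0, 0))
            )

    out._backward = backward
    return out


def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of logits ``z`` against targets ``y``.

    Stable formulation ``max(z,0) - z*y + log(1 + exp(-|z|))``; equals the
    binary log loss evaluated at sigmoid(z).
    """
    y = np.asarray(y, dtype=np.float64)
    zd = z.data
    loss = np.maximum(zd, 0.0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    out = Tensor(loss.mean(), parents=(z,))

    def backward(g):
        if z.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(zd, -60, 60)))
            z.grad += g * (s - y) / y.size

    out._backward = backward
    return out


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 0.1):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.data -= self.lr * p.grad


class RMSProp:
    def __init__(self, params: list[Tensor], lr: float = 0.005, rho: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            v *= self.rho
            v += (1 - self.rho) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(v) + self.eps)


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 0.005,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
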