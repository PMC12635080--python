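"""Numerical primitives for the miniature transformer.

Dense layers, layer normalization, GELU, softmax attention and Adam,
implemented directly in numpy with analytic forward/backward passes. The
backward passes also expose gradients with respect to the input token
embeddings, which the interpretation module integrates along baseline paths.
"""

from __future__ import annotations

import numpy as np

_C = np.sqrt(2.0 / np.pi)


def gelu_forward(x: np.ndarray):
    """GELU, tanh approximation (the form used by BERT-family models);
    returns the activation plus the cached tanh for the backward pass."""
    t = np.tanh(_C * (x + 0.044715 * x**3))
    return 0.5 * x * (1.0 + t), t


def gelu(x: np.ndarray) -> np.ndarray:
    return gelu_forward(x)[0]


def gelu_backward(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    du = _C * (1.0 + 0.134145 * x * x)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return gelu_backward(x, np.tanh(_C * (x + 0.044715 * x**3)))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm_forward(x, gain, bias, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * gain + bias, (xhat, inv, gain)


def layer_norm_backward(dy, cache):
    xhat, inv, gain = cache
    d = xhat.shape[-1]
    dgain = (dy * xhat).reshape(-1, d).sum(axis=0)
    dbias = dy.reshape(-1, d).sum(axis=0)
    dxhat = dy * gain
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dgain, dbias


def dense_forward(x, W, b):
    return x @ W + b, x


def dense_backward(dy, W, cache):
    x = cache
    din = x.shape[-1]
    dW = x.reshape(-1, din).T @ dy.reshape(-1, dy.shape[-1])
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    dx = dy @ W.T
    return dx, dW, db


class Adam:
    """Standard Adam over a dict of parameter arrays (updates in place)."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / c1) / (
                np.sqrt(self.v[k] / c2) + self.eps
            )
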