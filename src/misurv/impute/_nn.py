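"""Minimal NumPy neural-network primitives (dense layers, Adam, MLP).

Hand-rolled backpropagation sized for the small tabular networks used by the
adversarial and attentive imputers; everything is deterministic given the
generator that initialises the weights.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense:
    def __init__(self, rng, fan_in, fan_out):
        self.W = _glorot(rng, fan_in, fan_out)
        self.b = np.zeros(fan_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class Relu:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, g):
        return g * self._m


class Sigmoid:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class MLP:
    """Stack of layers with shared forward/backward and flat param lists."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def zero_grads(self):
        for g in self.grads:
            g[...] = 0.0


def mlp(rng, sizes, out_activation=None):
    layers = []
    for i in range(len(sizes) - 1):
        layers.append(Dense(rng, sizes[i], sizes[i + 1]))
        if i < len(sizes) - 2:
            layers.append(Relu())
    if out_activation is not None:
        layers.append(out_activation)
    return MLP(layers)


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params, self.grads = params, grads
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
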