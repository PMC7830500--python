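"""Minimal dense-network building blocks with explicit backprop and Adam.

The two bespoke classifiers (five-block FCDNN and the joint
autoencoder-classifier DCAE) need only fully connected layers, ReLU/tanh
activations, inverted dropout and the Adam optimiser, so the machinery is
written directly in NumPy: each layer caches what its backward pass needs,
and gradients are accumulated module by module.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "ReLU", "Tanh", "Dropout", "Sequential", "Adam",
    "softmax", "cross_entropy_loss", "cross_entropy_grad",
    "mse_loss", "mse_grad", "one_hot",
]


class Dense:
    """Affine layer y = xW + b with He-style seeded initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # in-place so optimizer-held gradient references stay valid
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class Tanh:
    def forward(self, x, train: bool = False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)

    def params(self):
        return []


class Dropout:
    """Inverted dropout: active only when ``train`` is True."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    """Adam with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def cross_entropy_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean softmax cross-entropy in nats; ``y`` holds integer labels."""
    p = softmax(logits)
    return float(-np.log(p[np.arange(len(y)), y] + 1e-12).mean())


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = softmax(logits)
    return (p - one_hot(y, logits.shape[1])) / len(y)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    return float(((pred - target) ** 2).mean())


def mse_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return 2.0 * (pred - target) / pred.size
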