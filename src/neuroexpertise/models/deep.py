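"""The two bespoke deep classifiers: FCDNN and the joint DCAE.

FCDNN: five FC -> ReLU -> dropout blocks followed by a linear map to the
three expertise classes, trained with Adam on softmax cross-entropy.

DCAE: an autoencoder (input -> h1 -> code -> h1 -> input, ReLU between
affine layers) whose latent code also feeds a classifier head
(FC -> dropout -> tanh -> FC -> tanh).  Encoder, decoder and classifier
are learned *jointly*: per step the reconstruction MSE and the
classification cross-entropy are summed and the combined gradient is
back-propagated through all three parts by one Adam optimiser.  Following
the reference architecture, the final tanh output is treated as the logits
of a softmax cross-entropy (a config flag drops that tanh).

Inputs are standardised per feature with training-set statistics inside
``fit``; both models are full-batch by default (cohorts are a few hundred
trials), with an optional minibatch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    Dense,
    Dropout,
    ReLU,
    Sequential,
    Tanh,
    cross_entropy_grad,
    cross_entropy_loss,
    mse_grad,
    mse_loss,
    softmax,
)

__all__ = [
    "FcdnnSpec", "DcaeSpec", "TrainState",
    "FCDNN", "DCAE", "FCDNN_SPECS", "DCAE_SPECS", "plateau_stop",
]


@dataclass
class TrainState:
    """Per-epoch loss history of one training run."""

    mse: list = field(default_factory=list)
    ce: list = field(default_factory=list)
    total: list = field(default_factory=list)
    epochs_run: int = 0
    seed: int = 0


def plateau_stop(history: list, window: int = 100, tol: float = 1e-5) -> bool:
    """Terminate when loss reduction over the last ``window`` epochs < tol.

    A trial whose loss never moves is stopped right at epoch ``window``.
    """
    if len(history) < window:
        return False
    return history[-window] - history[-1] < tol


@dataclass(frozen=True)
class FcdnnSpec:
    """Five-block fully connected architecture."""

    block_sizes: tuple[int, ...] = (244, 313, 160, 149, 65)
    dropouts: tuple[float, ...] = (0.333, 0.344, 0.453, 0.346, 0.395)
    out_classes: int = 3
    lr: float = 3.95e-5
    epochs: int = 1000


@dataclass(frozen=True)
class DcaeSpec:
    """Encoder/decoder/classifier widths of the joint autoencoder."""

    hidden: int = 517          # FC1/FC3 width
    code: int = 328            # FC2 width (encoder output)
    clf_hidden: int = 104      # FC5 width
    clf_dropout: float = 0.3922
    out_classes: int = 3
    lr: float = 4.14e-5
    epochs: int = 1000
    final_tanh: bool = True


#: Printed per-variant optima (brain-only DS1 vs fused DS2).
FCDNN_SPECS = {
    "DS1": FcdnnSpec(),
    "DS2": FcdnnSpec(
        block_sizes=(244, 148, 119, 102, 182),
        dropouts=(0.231, 0.433, 0.265, 0.391, 0.691),
        lr=8.28e-5,
    ),
}
DCAE_SPECS = {
    "DS1": DcaeSpec(),
    "DS2": DcaeSpec(hidden=551, code=306, clf_hidden=165,
                    clf_dropout=0.4996, lr=4.87e-5),
}


class _Standardizer:
    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sd


class FCDNN:
    """Five-block fully connected deep classifier."""

    def __init__(self, spec: FcdnnSpec | None = None, seed: int = 0,
                 epochs: int | None = None, batch_size: int | None = None,
                 early_stop: bool = False):
        self.spec = spec or FcdnnSpec()
        self.seed = seed
        self.epochs = epochs if epochs is not None else self.spec.epochs
        self.batch_size = batch_size
        self.early_stop = early_stop
        self.net: Sequential | None = None
        self.state = TrainState(seed=seed)

    def _build(self, n_in: int, rng: np.random.Generator) -> None:
        layers = []
        prev = n_in
        for width, rate in zip(self.spec.block_sizes, self.spec.dropouts):
            layers += [Dense(prev, width, rng), ReLU(), Dropout(rate, rng)]
            prev = width
        layers.append(Dense(prev, self.spec.out_classes, rng))
        self.net = Sequential(layers)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FCDNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        self.scaler = _Standardizer().fit(X)
        Xs = self.scaler.transform(X)
        self._build(X.shape[1], rng)
        opt = Adam(self.net.params(), lr=self.spec.lr)
        n = len(Xs)
        bs = self.batch_size or n
        for _ in range(self.epochs):
            order = rng.permutation(n) if bs < n else np.arange(n)
            epoch_loss = 0.0
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                logits = self.net.forward(Xs[idx], train=True)
                loss = cross_entropy_loss(logits, y[idx])
                self.net.backward(cross_entropy_grad(logits, y[idx]))
                opt.step()
                epoch_loss += loss * len(idx)
            self.state.ce.append(epoch_loss / n)
            self.state.total.append(epoch_loss / n)
            self.state.epochs_run += 1
            if self.early_stop and plateau_stop(self.state.total):
                break
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("model is not fitted")
        Xs = self.scaler.transform(np.asarray(X, dtype=float))
        return softmax(self.net.forward(Xs, train=False))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


class DCAE:
    """Deep classifier autoencoder with jointly learned heads."""

    def __init__(self, spec: DcaeSpec | None = None, seed: int = 0,
                 epochs: int | None = None, batch_size: int | None = None,
                 early_stop: bool = False):
        self.spec = spec or DcaeSpec()
        self.seed = seed
        self.epochs = epochs if epochs is not None else self.spec.epochs
        self.batch_size = batch_size
        self.early_stop = early_stop
        self.state = TrainState(seed=seed)
        self.encoder: Sequential | None = None

    def _build(self, n_in: int, rng: np.random.Generator) -> None:
        s = self.spec
        self.encoder = Sequential(
            [Dense(n_in, s.hidden, rng), ReLU(), Dense(s.hidden, s.code, rng)]
        )
        self.decoder = Sequential(
            [Dense(s.code, s.hidden, rng), ReLU(), Dense(s.hidden, n_in, rng)]
        )
        clf_layers = [
            Dense(s.code, s.clf_hidden, rng),
            Dropout(s.clf_dropout, rng),
            Tanh(),
            Dense(s.clf_hidden, s.out_classes, rng),
        ]
        if s.final_tanh:
            clf_layers.append(Tanh())
        self.classifier = Sequential(clf_layers)

    def _params(self):
        return (
            self.encoder.params()
            + self.decoder.params()
            + self.classifier.params()
        )

    def _joint_step(self, Xb: np.ndarray, yb: np.ndarray, train: bool = True):
        """Forward both heads; return (mse, ce) and backprop the summed loss."""
        code = self.encoder.forward(Xb, train=train)
        recon = self.decoder.forward(code, train=train)
        logits = self.classifier.forward(code, train=train)
        mse = mse_loss(recon, Xb)
        ce = cross_entropy_loss(logits, yb)
        if train:
            g_code = self.decoder.backward(mse_grad(recon, Xb))
            g_code = g_code + self.classifier.backward(
                cross_entropy_grad(logits, yb)
            )
            self.encoder.backward(g_code)
        return mse, ce

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DCAE":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        self.scaler = _Standardizer().fit(X)
        Xs = self.scaler.transform(X)
        self._build(X.shape[1], rng)
        opt = Adam(self._params(), lr=self.spec.lr)
        n = len(Xs)
        bs = self.batch_size or n
        for _ in range(self.epochs):
            order = rng.permutation(n) if bs < n else np.arange(n)
            e_mse = e_ce = 0.0
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                mse, ce = self._joint_step(Xs[idx], y[idx], train=True)
                opt.step()
                e_mse += mse * len(idx)
                e_ce += ce * len(idx)
            self.state.mse.append(e_mse / n)
            self.state.ce.append(e_ce / n)
            self.state.total.append((e_mse + e_ce) / n)
            self.state.epochs_run += 1
            if self.early_stop and plateau_stop(self.state.total):
                break
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(np.asarray(X, dtype=float))
        return self.encoder.forward(Xs, train=False)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encode(X), train=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.encoder is None:
            raise RuntimeError("model is not fitted")
        code = self.encode(X)
        return softmax(self.classifier.forward(code, train=False))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
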