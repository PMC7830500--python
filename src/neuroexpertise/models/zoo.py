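"""The seven-classifier zoo plus the zero-rule baseline.

Classical models (RF, SVM, kNN, GNB, XGB) delegate to scikit-learn and
xgboost at the reference hyperparameter settings; FCDNN and DCAE are the
package's own NumPy implementations.  Every model is wrapped to expose
fit/predict on string class labels with all randomness pinned to the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ..synthdata import CLASSES
from .deep import DCAE, DCAE_SPECS, FCDNN, FCDNN_SPECS, DcaeSpec, FcdnnSpec

__all__ = ["ClassifierConfig", "make_classifier", "ZeroRule", "StratifiedRandom",
           "CLASSIFIER_NAMES", "encode_labels", "decode_labels"]

CLASSIFIER_NAMES = ("RF", "SVM", "kNN", "GNB", "XGB", "FCDNN", "DCAE")

_CLASS_TO_INT = {c: i for i, c in enumerate(CLASSES)}


def encode_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "iu":
        return y.astype(int)
    bad = set(np.unique(y)) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}")
    return np.array([_CLASS_TO_INT[c] for c in y])


def decode_labels(y: np.ndarray) -> np.ndarray:
    return np.array([CLASSES[i] for i in y])


@dataclass
class ClassifierConfig:
    """Name + parameter overrides + seed for one classifier instance."""

    name: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        valid = CLASSIFIER_NAMES + ("baseline", "baseline_stratified")
        if self.name not in valid:
            raise ValueError(
                f"unknown classifier {self.name!r}; valid names: {valid}"
            )


class ZeroRule:
    """Majority-class (zero-rule) baseline predictor."""

    def fit(self, X, y):
        y = encode_labels(y)
        vals, counts = np.unique(y, return_counts=True)
        self.majority_ = int(vals[counts.argmax()])
        return self

    def predict(self, X):
        return np.full(len(X), self.majority_, dtype=int)


class StratifiedRandom:
    """Chance baseline: predicts labels drawn from the training frequencies.

    Unlike the zero-rule predictor its macro-averaged scores match a
    chance-level classifier's, which makes it the right reference for
    type-I-error calibration of the baseline-comparison test.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X, y):
        y = encode_labels(y)
        vals, counts = np.unique(y, return_counts=True)
        self.classes_, self.p_ = vals, counts / counts.sum()
        return self

    def predict(self, X):
        rng = np.random.default_rng(self.seed)
        return rng.choice(self.classes_, size=len(X), p=self.p_)


class _SkWrapper:
    """Adapter exposing integer-label fit/predict around an estimator."""

    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self.est.fit(np.asarray(X, dtype=float), encode_labels(y))
        return self

    def predict(self, X):
        return np.asarray(self.est.predict(np.asarray(X, dtype=float)), dtype=int)


def _variant_of(params: dict) -> str:
    return params.get("variant", "DS1")


def make_classifier(cfg: ClassifierConfig):
    """Instantiate a trainable model at the reference settings.

    ``cfg.params`` may override any constructor argument; for FCDNN/DCAE a
    ``variant`` ("DS1"/"DS2") selects the per-variant architecture and
    ``epochs``/``batch_size``/``early_stop`` control training.
    """
    p = dict(cfg.params)
    seed = cfg.seed
    if cfg.name == "baseline":
        return ZeroRule()
    if cfg.name == "baseline_stratified":
        return StratifiedRandom(seed=seed)
    if cfg.name == "RF":
        return _SkWrapper(RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 30),
            max_depth=p.pop("max_depth", 10),
            random_state=seed, **p,
        ))
    if cfg.name == "SVM":
        return _SkWrapper(SVC(
            kernel=p.pop("kernel", "rbf"), gamma=p.pop("gamma", "auto"),
            random_state=seed, **p,
        ))
    if cfg.name == "kNN":
        return _SkWrapper(KNeighborsClassifier(
            n_neighbors=p.pop("n_neighbors", 3), **p,
        ))
    if cfg.name == "GNB":
        return _SkWrapper(GaussianNB(**p))
    if cfg.name == "XGB":
        return _SkWrapper(XGBClassifier(
            objective="multi:softmax",
            num_class=p.pop("num_class", 3),
            colsample_bytree=p.pop("colsample_bytree", 0.3),
            learning_rate=p.pop("learning_rate", 0.1),
            max_depth=p.pop("max_depth", 3),
            reg_alpha=p.pop("reg_alpha", 5),
            n_estimators=p.pop("n_estimators", 15),
            random_state=seed, verbosity=0, **p,
        ))
    if cfg.name == "FCDNN":
        variant = p.pop("variant", "DS1")
        spec = p.pop("spec", None) or FCDNN_SPECS[variant]
        if "lr" in p or "block_sizes" in p or "dropouts" in p:
            spec = FcdnnSpec(
                block_sizes=tuple(p.pop("block_sizes", spec.block_sizes)),
                dropouts=tuple(p.pop("dropouts", spec.dropouts)),
                lr=p.pop("lr", spec.lr),
                epochs=spec.epochs,
            )
        return FCDNN(spec=spec, seed=seed, **p)
    if cfg.name == "DCAE":
        variant = p.pop("variant", "DS1")
        spec = p.pop("spec", None) or DCAE_SPECS[variant]
        if any(k in p for k in ("lr", "hidden", "code", "clf_hidden",
                                "clf_dropout", "final_tanh")):
            spec = DcaeSpec(
                hidden=p.pop("hidden", spec.hidden),
                code=p.pop("code", spec.code),
                clf_hidden=p.pop("clf_hidden", spec.clf_hidden),
                clf_dropout=p.pop("clf_dropout", spec.clf_dropout),
                lr=p.pop("lr", spec.lr),
                epochs=spec.epochs,
                final_tanh=p.pop("final_tanh", spec.final_tanh),
            )
        return DCAE(spec=spec, seed=seed, **p)
    raise ValueError(f"unknown classifier {cfg.name!r}")
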