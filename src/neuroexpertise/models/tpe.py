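"""Sequential model-based hyperparameter search (tree-structured Parzen).

A compact TPE: after a random start-up phase the observed trials are split
at the gamma-quantile of the objective into "good" and "bad" sets; each
numeric dimension gets a Parzen (Gaussian-mixture) density per set, and
the next candidate maximises the good/bad density ratio over a sampled
batch.  Log-scaled dimensions (learning rates) are modelled in log space;
integer dimensions are rounded; categorical dimensions use re-weighted
category counts.

Deep-model objectives are expected to apply the plateau termination rule
(stop a trial when loss reduction is below 1e-5 per 100 epochs) via the
models' ``early_stop`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

__all__ = ["SearchDim", "TpeResult", "tpe_minimize", "tune"]


@dataclass(frozen=True)
class SearchDim:
    """One search dimension: uniform / loguniform / int / choice."""

    kind: str
    low: float = 0.0
    high: float = 1.0
    choices: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "loguniform", "int", "choice"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "choice" and not self.choices:
            raise ValueError("choice dimension needs at least one option")


@dataclass
class TpeResult:
    best_params: dict[str, Any]
    best_value: float
    trials: list = field(default_factory=list)  # (params, value) pairs


def _sample_prior(dim: SearchDim, rng: np.random.Generator):
    if dim.kind == "uniform":
        return float(rng.uniform(dim.low, dim.high))
    if dim.kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(dim.low), np.log(dim.high))))
    if dim.kind == "int":
        return int(rng.integers(int(dim.low), int(dim.high) + 1))
    return dim.choices[rng.integers(len(dim.choices))]


def _to_unit(dim: SearchDim, v):
    if dim.kind == "loguniform":
        return (np.log(v) - np.log(dim.low)) / (np.log(dim.high) - np.log(dim.low))
    if dim.kind in ("uniform", "int"):
        return (float(v) - dim.low) / (dim.high - dim.low)
    return v  # categorical handled separately


def _from_unit(dim: SearchDim, u: float):
    u = float(np.clip(u, 0.0, 1.0))
    if dim.kind == "loguniform":
        return float(np.exp(np.log(dim.low) + u * (np.log(dim.high) - np.log(dim.low))))
    v = dim.low + u * (dim.high - dim.low)
    return int(round(v)) if dim.kind == "int" else float(v)


def _parzen_logpdf(x: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Log density of a unit-interval Parzen mixture centred on ``obs``."""
    if obs.size == 0:
        return np.zeros_like(x)
    bw = max(1.0 / (1 + obs.size), obs.std() * obs.size ** (-0.2), 1e-3)
    d = (x[:, None] - obs[None, :]) / bw
    log_k = -0.5 * d**2 - np.log(bw * np.sqrt(2 * np.pi))
    m = log_k.max(axis=1, keepdims=True)
    return (m[:, 0] + np.log(np.exp(log_k - m).mean(axis=1)))


def tpe_minimize(
    objective: Callable[[dict[str, Any]], float],
    space: dict[str, SearchDim],
    n_trials: int = 30,
    seed: int = 0,
    n_startup: int = 10,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> TpeResult:
    """Minimise ``objective`` over ``space`` with seeded TPE."""
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float]] = []

    for t in range(n_trials):
        if t < n_startup or len(trials) < 2:
            params = {k: _sample_prior(d, rng) for k, d in space.items()}
        else:
            values = np.array([v for _, v in trials])
            cut = np.quantile(values, gamma)
            good = [p for p, v in trials if v <= cut]
            bad = [p for p, v in trials if v > cut] or good
            params = {}
            for k, dim in space.items():
                if dim.kind == "choice":
                    counts_g = np.ones(len(dim.choices))
                    counts_b = np.ones(len(dim.choices))
                    for p in good:
                        counts_g[dim.choices.index(p[k])] += 1
                    for p in bad:
                        counts_b[dim.choices.index(p[k])] += 1
                    score = counts_g / counts_g.sum() / (counts_b / counts_b.sum())
                    params[k] = dim.choices[int(score.argmax())]
                else:
                    obs_g = np.array([_to_unit(dim, p[k]) for p in good])
                    obs_b = np.array([_to_unit(dim, p[k]) for p in bad])
                    cand = rng.random(n_candidates)
                    if obs_g.size:
                        bw = max(1.0 / (1 + obs_g.size), 1e-3)
                        cand = np.clip(
                            obs_g[rng.integers(obs_g.size, size=n_candidates)]
                            + bw * rng.standard_normal(n_candidates),
                            0.0, 1.0,
                        )
                    ratio = _parzen_logpdf(cand, obs_g) - _parzen_logpdf(cand, obs_b)
                    params[k] = _from_unit(dim, cand[int(ratio.argmax())])
        value = float(objective(params))
        trials.append((params, value))

    best_params, best_value = min(trials, key=lambda pv: pv[1])
    return TpeResult(best_params=best_params, best_value=best_value,
                     trials=trials)


def tune(
    model_family: str,
    search_space: dict[str, SearchDim],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    budget: int = 30,
    seed: int = 0,
    fit_epochs: int = 300,
):
    """TPE search over a classifier family; returns the best config.

    Each trial fits the model on the training split (deep trials run with
    the plateau-termination rule active) and is scored by validation error
    (1 - accuracy).  Returns a :class:`ClassifierConfig`.
    """
    from .zoo import ClassifierConfig, encode_labels, make_classifier

    y_val_i = encode_labels(y_val)

    def objective(params: dict[str, Any]) -> float:
        p = dict(params)
        if model_family in ("FCDNN", "DCAE"):
            p.setdefault("epochs", fit_epochs)
            p.setdefault("early_stop", True)
        model = make_classifier(
            ClassifierConfig(name=model_family, params=p, seed=seed)
        )
        model.fit(X_train, y_train)
        pred = model.predict(X_val)
        return float((pred != y_val_i).mean())

    result = tpe_minimize(objective, search_space, n_trials=budget, seed=seed)
    best = dict(result.best_params)
    if model_family in ("FCDNN", "DCAE"):
        best.setdefault("epochs", fit_epochs)
    return ClassifierConfig(name=model_family, params=best, seed=seed), result
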