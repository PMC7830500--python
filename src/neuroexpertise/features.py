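"""Feature families: 8-statistic battery and random convolutional kernels.

Two design-matrix families are produced from each preprocessed trial:

* ``statistical`` — mean, sample SD, max, min, range, OLS slope, Fisher
  skewness and zero-crossing count, computed on the {All, Left, Right}
  passed-channel aggregates (24 columns), and for the fused variant also
  on each of the 7 per-emotion time series (80 columns).
* ``rocket`` — the random convolutional kernel transform: 100 random
  dilated kernels per series, each pooled with a maximum operator and a
  proportion-of-positive-values (PPV) operator, giving 16 x 100 x 2 =
  3200 columns from the fNIRS channels alone and 4600 once the 7 emotion
  series are appended.

Dataset variants: DS1 = brain-only; DS2 = brain + emotion fusion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import skew

from .fnirs_prep import HaemoTrial
from .synthdata import (
    CLASSES,
    EMOTIONS,
    LEFT_CHANNELS,
    N_CHANNELS,
    RIGHT_CHANNELS,
    EmotionTrack,
)

__all__ = [
    "KernelSpec",
    "FeatureMatrix",
    "statistical_features",
    "aggregate_channels",
    "sample_kernels",
    "apply_kernel",
    "rocket_transform",
    "build_dataset",
    "STAT_NAMES",
]

STAT_NAMES = (
    "mean", "sd", "max", "min", "range", "slope", "skewness", "zero_crossings",
)


def statistical_features(series: np.ndarray) -> np.ndarray:
    """The 8-statistic battery for one series.

    Returns (mean, sample SD, max, min, range, OLS slope against the sample
    index, Fisher skewness with 0 for zero-variance input, and the count of
    sign changes of the mean-centred series ignoring exact zeros).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with length >= 3")
    mu = x.mean()
    xmax, xmin = x.max(), x.min()
    if xmax == xmin:  # constant series: all shape statistics degenerate
        sd = 0.0
        slope = 0.0
        skw = 0.0
        zc = 0
    else:
        sd = x.std(ddof=1)
        t = np.arange(x.size)
        slope = float(np.polyfit(t, x, 1)[0])
        skw = float(skew(x))
        centred = x - mu
        signs = np.sign(centred)
        signs = signs[signs != 0]
        zc = int(np.count_nonzero(np.diff(signs)))
    return np.array([mu, sd, xmax, xmin, xmax - xmin, slope, skw, zc])


def aggregate_channels(trial: HaemoTrial) -> dict[str, np.ndarray]:
    """Sample-wise mean oxyHb over passed channels: All / Left / Right.

    An aggregate with zero passed channels is flagged missing (absent from
    the returned dict, with a warning); callers exclude such trials from
    the statistical feature matrix.
    """
    out: dict[str, np.ndarray] = {}
    groups = {
        "All": np.arange(N_CHANNELS),
        "Left": np.array(LEFT_CHANNELS),
        "Right": np.array(RIGHT_CHANNELS),
    }
    for name, idx in groups.items():
        sel = idx[trial.mask.passed[idx]]
        if sel.size == 0:
            warnings.warn(
                f"trial P{trial.participant_id}/T{trial.trial_id}: no passed "
                f"channels for aggregate {name!r}",
                stacklevel=2,
            )
            continue
        out[name] = trial.oxy[sel].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Random convolutional kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """One random convolution kernel: weights, bias, dilation, padding."""

    length: int
    weights: tuple[float, ...]
    bias: float
    dilation: int
    padding: int

    def __post_init__(self) -> None:
        if len(self.weights) != self.length:
            raise ValueError("weights length must equal kernel length")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")

    @property
    def span(self) -> int:
        return (self.length - 1) * self.dilation + 1


def sample_kernels(
    n_kernels: int,
    input_length: int,
    rng: np.random.Generator,
    lengths: tuple[int, ...] = (7, 9, 11),
) -> list[KernelSpec]:
    """Sample random kernels per the standard random-kernel recipe.

    length uniform over {7, 9, 11}; weights N(0, 1) then mean-centred;
    bias U(-1, 1); dilation 2**x with x ~ U(0, log2((input_length-1) /
    (length-1))); padding on/off with probability 1/2.
    """
    if input_length < min(lengths):
        raise ValueError(
            f"input_length {input_length} too small for any kernel "
            f"(min length {min(lengths)})"
        )
    feasible = [l for l in lengths if l <= input_length]
    specs = []
    for _ in range(n_kernels):
        length = int(rng.choice(feasible))
        w = rng.standard_normal(length)
        w = w - w.mean()
        bias = float(rng.uniform(-1.0, 1.0))
        x_max = np.log2((input_length - 1) / (length - 1))
        dilation = int(np.floor(2.0 ** rng.uniform(0.0, x_max)))
        padding = ((length - 1) * dilation) // 2 if rng.random() < 0.5 else 0
        specs.append(
            KernelSpec(
                length=length,
                weights=tuple(w),
                bias=bias,
                dilation=dilation,
                padding=padding,
            )
        )
    return specs


def apply_kernel(series: np.ndarray, k: KernelSpec) -> tuple[float, float]:
    """Dilated sliding dot-product + bias; pool with (max, PPV).

    PPV is the fraction of convolution outputs strictly greater than zero.
    """
    x = np.asarray(series, dtype=float)
    if k.padding:
        x = np.concatenate([np.zeros(k.padding), x, np.zeros(k.padding)])
    n_out = x.size - (k.length - 1) * k.dilation
    if n_out < 1:
        raise ValueError(
            f"kernel span {k.span} exceeds padded series length {x.size}"
        )
    out = np.full(n_out, k.bias)
    for j, w in enumerate(k.weights):
        out += w * x[j * k.dilation : j * k.dilation + n_out]
    return float(out.max()), float((out > 0).mean())


def rocket_transform(
    channels: list[np.ndarray] | np.ndarray, kernels: list[KernelSpec]
) -> np.ndarray:
    """Concatenate (max, ppv) per kernel per series, in channel order."""
    lengths = {np.asarray(c).shape[-1] for c in channels}
    if len(lengths) > 1:
        raise ValueError(f"ragged series lengths {sorted(lengths)}")
    X = np.asarray(channels, dtype=float)          # (n_series, L)
    n_series = X.shape[0]
    feats = np.empty((n_series, len(kernels), 2))
    for ki, k in enumerate(kernels):
        if k.padding:
            Xp = np.pad(X, ((0, 0), (k.padding, k.padding)))
        else:
            Xp = X
        n_out = Xp.shape[1] - (k.length - 1) * k.dilation
        if n_out < 1:
            raise ValueError(
                f"kernel span {k.span} exceeds padded series length {Xp.shape[1]}"
            )
        out = np.full((n_series, n_out), k.bias)
        for j, w in enumerate(k.weights):
            out += w * Xp[:, j * k.dilation : j * k.dilation + n_out]
        feats[:, ki, 0] = out.max(axis=1)
        feats[:, ki, 1] = (out > 0).mean(axis=1)
    return feats.reshape(-1)


# ---------------------------------------------------------------------------
# Design-matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Tagged design matrix: one row per trial, labels aligned."""

    X: np.ndarray
    y: np.ndarray            # class strings from CLASSES
    variant: str             # "DS1" | "DS2"
    kind: str                # "statistical" | "rocket"
    column_names: list[str]
    seed: int = 0
    participant_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names must match X width")
        if self.X.shape[0] != len(self.y):
            raise ValueError("y must match X rows")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "label", self.y)
        df.to_csv(path, index=False)
        sidecar = {
            "variant": self.variant,
            "kind": self.kind,
            "seed": self.seed,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def _imputed_oxy(trial: HaemoTrial) -> np.ndarray:
    """OxyHb with failed channels mean-imputed from passed ones per hemisphere."""
    oxy = trial.oxy.copy()
    passed = trial.mask.passed
    halves = (np.array(LEFT_CHANNELS), np.array(RIGHT_CHANNELS))
    global_ok = np.flatnonzero(passed)
    for idx in halves:
        ok = idx[passed[idx]]
        bad = idx[~passed[idx]]
        if bad.size == 0:
            continue
        if ok.size > 0:
            fill = oxy[ok].mean(axis=0)
        elif global_ok.size > 0:
            fill = oxy[global_ok].mean(axis=0)
        else:
            fill = np.zeros(trial.L)
        oxy[bad] = fill
    return oxy


def _emotion_series(track: EmotionTrack) -> list[np.ndarray]:
    return [track.scores[:, j] for j in range(len(EMOTIONS))]


def build_dataset(
    cohort_pre: list[tuple[HaemoTrial, EmotionTrack]],
    variant: str = "DS1",
    kind: str = "rocket",
    n_kernels: int = 100,
    seed: int = 0,
    flatten_emotion_scores: bool = False,
) -> FeatureMatrix:
    """Assemble a tagged design matrix from a preprocessed cohort.

    DS1 uses the fNIRS features alone; DS2 appends emotion-track features
    of the same family (statistical battery on each of the 7 per-emotion
    series, or a separate kernel bank sampled for the 18-frame grid).
    ``flatten_emotion_scores`` switches the DS2-statistical branch to raw
    flattened 18x7 scores (126 extra columns) instead of the battery.
    """
    if variant not in ("DS1", "DS2"):
        raise ValueError("variant must be DS1 or DS2")
    if kind not in ("statistical", "rocket"):
        raise ValueError("kind must be statistical or rocket")
    if not cohort_pre:
        raise ValueError("empty cohort")
    if variant == "DS2":
        for h, e in cohort_pre:
            if e is None:
                raise ValueError(
                    f"missing emotion track for trial "
                    f"P{h.participant_id}/T{h.trial_id}"
                )

    rows, labels, pids = [], [], []
    names: list[str] = []

    if kind == "rocket":
        ss = np.random.SeedSequence(seed)
        s_fnirs, s_emo = ss.spawn(2)
        L = cohort_pre[0][0].L
        bank_fnirs = sample_kernels(n_kernels, L, np.random.default_rng(s_fnirs))
        bank_emo = (
            sample_kernels(n_kernels, 18, np.random.default_rng(s_emo))
            if variant == "DS2"
            else None
        )
        names = [
            f"ch{c + 1}_k{k + 1}_{op}"
            for c in range(N_CHANNELS)
            for k in range(n_kernels)
            for op in ("max", "ppv")
        ]
        if variant == "DS2":
            names += [
                f"emo_{e.lower()}_k{k + 1}_{op}"
                for e in EMOTIONS
                for k in range(n_kernels)
                for op in ("max", "ppv")
            ]
        for h, e in cohort_pre:
            feats = rocket_transform(list(_imputed_oxy(h)), bank_fnirs)
            if variant == "DS2":
                feats = np.concatenate(
                    [feats, rocket_transform(_emotion_series(e), bank_emo)]
                )
            rows.append(feats)
            labels.append(h.label.cls)
            pids.append(h.participant_id)
    else:
        names = [f"{agg}_{s}" for agg in ("All", "Left", "Right") for s in STAT_NAMES]
        if variant == "DS2":
            if flatten_emotion_scores:
                names += [
                    f"emo_{e.lower()}_f{f + 1}"
                    for f in range(18)
                    for e in EMOTIONS
                ]
            else:
                names += [
                    f"emo_{e.lower()}_{s}" for e in EMOTIONS for s in STAT_NAMES
                ]
        for h, e in cohort_pre:
            aggs = aggregate_channels(h)
            if len(aggs) < 3:
                warnings.warn(
                    f"excluding trial P{h.participant_id}/T{h.trial_id}: "
                    "missing aggregate",
                    stacklevel=2,
                )
                continue
            feats = np.concatenate(
                [statistical_features(aggs[a]) for a in ("All", "Left", "Right")]
            )
            if variant == "DS2":
                if flatten_emotion_scores:
                    extra = e.scores.ravel()
                else:
                    extra = np.concatenate(
                        [statistical_features(s) for s in _emotion_series(e)]
                    )
                feats = np.concatenate([feats, extra])
            rows.append(feats)
            labels.append(h.label.cls)
            pids.append(h.participant_id)

    return FeatureMatrix(
        X=np.vstack(rows),
        y=np.array(labels),
        variant=variant,
        kind=kind,
        column_names=names,
        seed=seed,
        participant_ids=np.array(pids),
    )
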