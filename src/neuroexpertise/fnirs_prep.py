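"""Three-stage fNIRS preprocessing.

Stage 1: per-channel quality control (saturation, low signal, light
leakage).  Stage 2: zero-phase 0.14 Hz low-pass on each wavelength's
intensity series, then conversion of optical-density change against the
trial baseline to oxy/deoxy-haemoglobin concentration changes via the
modified Beer-Lambert law.  Stage 3: 3-SD outlier removal on each
haemoglobin series.  Trials are finally resampled onto a fixed-length grid
so that every downstream feature extractor sees equal dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .synthdata import (
    ADC_CEILING,
    DPF,
    EXTINCTION_CM_PER_UM,
    N_CHANNELS,
    SOURCE_DETECTOR_CM,
    EmotionTrack,
    RawFnirsTrial,
)

__all__ = [
    "QCThresholds",
    "QualityMask",
    "Geometry",
    "HaemoTrial",
    "qc_channels",
    "lowpass",
    "beer_lambert",
    "remove_outliers",
    "preprocess_trial",
    "preprocess_cohort",
    "FIXED_GRID_LEN",
]

#: Fixed grid length for all haemodynamic series (30 s at 2 Hz).
FIXED_GRID_LEN = 60

QC_REASONS = ("ok", "light_leakage", "low_signal", "saturated")


@dataclass(frozen=True)
class QCThresholds:
    """Pass criteria for channel QC, in detector units."""

    saturation_level: float = ADC_CEILING
    low_signal_floor: float = 20.0
    leakage_cv_max: float = 0.10
    #: fraction of samples at/above saturation_level that flags a channel
    saturation_frac: float = 0.01

    def __post_init__(self) -> None:
        if not (self.saturation_level > self.low_signal_floor > 0):
            raise ValueError(
                "require saturation_level > low_signal_floor > 0, got "
                f"{self.saturation_level} / {self.low_signal_floor}"
            )
        if self.leakage_cv_max <= 0:
            raise ValueError("leakage_cv_max must be positive")


@dataclass
class QualityMask:
    """Per-channel QC verdicts; ``passed[c]`` iff ``reason[c] == 'ok'``."""

    passed: np.ndarray  # (16,) bool
    reason: list[str]   # (16,) strings from QC_REASONS

    def __post_init__(self) -> None:
        self.passed = np.asarray(self.passed, dtype=bool)
        for p, r in zip(self.passed, self.reason):
            if p != (r == "ok"):
                raise ValueError("passed[c] must match reason[c] == 'ok'")


@dataclass(frozen=True)
class Geometry:
    """Optode geometry and chromophore optics for Beer-Lambert inversion."""

    source_detector_cm: float = SOURCE_DETECTOR_CM
    dpf: float = DPF
    extinction: np.ndarray = field(
        default_factory=lambda: EXTINCTION_CM_PER_UM.copy()
    )


@dataclass
class HaemoTrial:
    """Per-channel haemoglobin concentration changes on the fixed grid."""

    oxy: np.ndarray     # (16, L) ΔHbO in uM
    deoxy: np.ndarray   # (16, L) ΔHbR in uM
    mask: QualityMask
    L: int
    participant_id: int
    trial_id: int
    label: object
    fs: float


def qc_channels(trial: RawFnirsTrial, thr: QCThresholds) -> QualityMask:
    """Classify each channel as ok / saturated / low_signal / light_leakage.

    Rule order is saturated -> low_signal -> light_leakage; the first rule
    that fires on either wavelength wins.  A channel is saturated when at
    least ``thr.saturation_frac`` of samples sit at or above the saturation
    level, low-signal when the median intensity falls below the floor, and
    leaking when the within-channel coefficient of variation exceeds the
    ceiling.
    """
    passed = np.ones(N_CHANNELS, dtype=bool)
    reasons = []
    for ch in range(N_CHANNELS):
        series = trial.intensities[ch]  # (2, T)
        reason = "ok"
        if (series >= thr.saturation_level).mean(axis=1).max() >= thr.saturation_frac:
            reason = "saturated"
        elif np.median(series, axis=1).min() < thr.low_signal_floor:
            reason = "low_signal"
        else:
            means = series.mean(axis=1)
            cv = series.std(axis=1) / np.where(means > 0, means, np.inf)
            if cv.max() > thr.leakage_cv_max:
                reason = "light_leakage"
        reasons.append(reason)
        passed[ch] = reason == "ok"
    return QualityMask(passed=passed, reason=reasons)


def lowpass(
    series: np.ndarray, fs: float, cutoff: float = 0.14, order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward-backward).

    DC gain is exactly 1; output length equals input length.
    """
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    x = np.asarray(series, dtype=float)
    padlen = min(3 * max(len(a), len(b)), x.shape[axis] - 1)
    return filtfilt(b, a, x, axis=axis, padlen=padlen)


def beer_lambert(
    trial: RawFnirsTrial,
    geometry: Geometry | None = None,
    filtered: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert (filtered) intensities to ΔHbO/ΔHbR via modified Beer-Lambert.

    ΔOD_λ(t) = log10(mean baseline intensity_λ / intensity_λ(t)); the 2x2
    extinction system scaled by source-detector distance x DPF is solved
    per sample.  Returns (oxy, deoxy) arrays of shape (16, T) in uM.
    """
    geometry = geometry or Geometry()
    eps = np.asarray(geometry.extinction, dtype=float)
    if abs(np.linalg.det(eps)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    inten = trial.intensities if filtered is None else filtered
    lo, hi = trial.baseline_window
    if hi <= lo:
        raise ValueError("baseline_window is empty")
    baseline = inten[:, :, lo:hi].mean(axis=2, keepdims=True)  # (16, 2, 1)
    if (baseline <= 0).any():
        raise ValueError("non-positive baseline intensities")
    safe = np.clip(inten, 1e-12, None)
    dod = np.log10(baseline / safe)  # (16, 2, T)
    pathlength = geometry.source_detector_cm * geometry.dpf
    inv = np.linalg.inv(eps) / pathlength
    conc = np.einsum("kw,cwt->ckt", inv, dod)  # (16, 2, T): (HbO, HbR)
    return conc[:, 0, :], conc[:, 1, :]


def remove_outliers(
    series: np.ndarray, k: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Replace samples beyond ``k`` SDs of the (single-pass) mean.

    Flagged samples are linearly interpolated from the nearest retained
    neighbours (edge outliers take the nearest retained value), so the
    series keeps its length.  Zero-variance input is returned unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return x.copy(), np.zeros(x.size, dtype=bool)
    mask = np.abs(x - mu) > k * sd
    out = x.copy()
    if mask.any():
        good = np.flatnonzero(~mask)
        if good.size == 0:
            return np.full_like(x, mu), mask
        out[mask] = np.interp(np.flatnonzero(mask), good, x[good])
    return out, mask


def _resample_to_grid(series: np.ndarray, n_out: int) -> np.ndarray:
    """Linear resample of a 1-D series onto ``n_out`` evenly spaced points."""
    n_in = series.shape[-1]
    if n_in == n_out:
        return series.copy()
    src = np.linspace(0.0, 1.0, n_in)
    dst = np.linspace(0.0, 1.0, n_out)
    return np.interp(dst, src, series)


def preprocess_trial(
    trial: RawFnirsTrial,
    thr: QCThresholds | None = None,
    geometry: Geometry | None = None,
    cutoff_hz: float = 0.14,
    grid_len: int = FIXED_GRID_LEN,
    outlier_k: float = 3.0,
) -> HaemoTrial:
    """Run the full stage-1..3 pipeline and land on the fixed grid.

    Order: QC -> per-wavelength low-pass -> Beer-Lambert -> 3-SD outlier
    removal -> fixed-grid resampling.  Failed channels stay in the arrays
    (flagged by the mask) so downstream shapes are constant.
    """
    thr = thr or QCThresholds()
    mask = qc_channels(trial, thr)
    filtered = lowpass(trial.intensities, trial.fs, cutoff=cutoff_hz, axis=2)
    filtered = np.clip(filtered, 1e-9, None)
    oxy, deoxy = beer_lambert(trial, geometry=geometry, filtered=filtered)
    L = grid_len
    oxy_out = np.empty((N_CHANNELS, L))
    deoxy_out = np.empty((N_CHANNELS, L))
    for ch in range(N_CHANNELS):
        o, _ = remove_outliers(oxy[ch], k=outlier_k)
        d, _ = remove_outliers(deoxy[ch], k=outlier_k)
        oxy_out[ch] = _resample_to_grid(o, L)
        deoxy_out[ch] = _resample_to_grid(d, L)
    return HaemoTrial(
        oxy=oxy_out,
        deoxy=deoxy_out,
        mask=mask,
        L=L,
        participant_id=trial.participant_id,
        trial_id=trial.trial_id,
        label=trial.label,
        fs=trial.fs,
    )


def preprocess_cohort(
    cohort: list[tuple[RawFnirsTrial, EmotionTrack]],
    thr: QCThresholds | None = None,
    geometry: Geometry | None = None,
    cutoff_hz: float = 0.14,
    grid_len: int = FIXED_GRID_LEN,
) -> list[tuple[HaemoTrial, EmotionTrack]]:
    """Preprocess every trial of a generated or loaded cohort."""
    return [
        (
            preprocess_trial(
                f, thr=thr, geometry=geometry, cutoff_hz=cutoff_hz,
                grid_len=grid_len,
            ),
            e,
        )
        for f, e in cohort
    ]


def qc_report(
    cohort_pre: list[tuple[HaemoTrial, EmotionTrack]]
) -> pd.DataFrame:
    """Long-format QC report: one row per (participant, trial, channel)."""
    rows = [
        {
            "participant_id": h.participant_id,
            "trial_id": h.trial_id,
            "channel": ch,
            "reason": h.mask.reason[ch],
        }
        for h, _ in cohort_pre
        for ch in range(N_CHANNELS)
    ]
    return pd.DataFrame(rows)


def write_qc_report(
    cohort_pre: list[tuple[HaemoTrial, EmotionTrack]], path: str | Path
) -> None:
    qc_report(cohort_pre).to_csv(path, index=False)
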