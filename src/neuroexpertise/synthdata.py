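"""Seeded synthetic cohort generator.

Emulates the study design the analysis pipeline assumes: 30 participants
(10 novices, 9 intermediates, 11 experts) each watching 15 gameplay videos,
yielding 450 trials. Each trial carries (a) raw two-wavelength fNIRS
intensities for 16 prefrontal channels produced by a forward modified
Beer-Lambert model driven by an HRF-shaped oxyhaemoglobin time course whose
amplitude and left/right asymmetry depend on expertise class, and (b) an
18-frame x 7-emotion probability track drawn from a class-dependent
Dirichlet.

The generator is a forward model of the *statistical structure* of such an
experiment, not of any particular recording: trials are independent given
the class label (no participant-level random effects), so chance-level
performance is recovered exactly when the class effect is switched off.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import truncnorm

__all__ = [
    "EMOTIONS",
    "CLASSES",
    "ExpertiseLabel",
    "RawFnirsTrial",
    "EmotionTrack",
    "CohortConfig",
    "generate_cohort",
    "generate_fnirs_trial",
    "generate_emotion_track",
    "write_cohort",
    "read_cohort",
]

#: Fixed emotion ordering used everywhere downstream.
EMOTIONS = ("Anger", "Disgust", "Fear", "Happiness", "Sadness", "Surprise", "Neutral")

#: Expertise classes: novice, intermediate, expert.
CLASSES = ("NV", "IT", "EX")

#: Wavelengths of the two-wavelength continuous-wave device model, nm.
WAVELENGTHS_NM = (730.0, 850.0)

#: Molar extinction coefficients, cm^-1 per uM, rows = wavelengths,
#: columns = (HbO, HbR).  Values follow the standard compiled spectra
#: (0.390/1.102 and 1.058/0.691 cm^-1 mM^-1 at 730 and 850 nm).
EXTINCTION_CM_PER_UM = np.array(
    [[0.390e-3, 1.102e-3],
     [1.058e-3, 0.691e-3]]
)

#: Source-detector separation (cm) and differential pathlength factor.
SOURCE_DETECTOR_CM = 2.5
DPF = 6.0

#: Detector saturation ceiling, arbitrary ADC units.
ADC_CEILING = 4095.0

N_CHANNELS = 16
LEFT_CHANNELS = tuple(range(0, 8))
RIGHT_CHANNELS = tuple(range(8, 16))


@dataclass(frozen=True)
class ExpertiseLabel:
    """Class label plus the cosmetic recruitment metadata bands."""

    cls: str
    victory_points: int
    hours_per_week: float

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"class must be one of {CLASSES}, got {self.cls!r}")


@dataclass
class RawFnirsTrial:
    """Raw detector intensities for one trial.

    ``intensities`` has shape (16 channels, 2 wavelengths, T samples) in
    arbitrary detector units; ``baseline_window`` is the sample-index slice
    used as the I0 reference for optical-density conversion.
    """

    intensities: np.ndarray
    fs: float
    baseline_window: tuple[int, int]
    participant_id: int
    trial_id: int
    label: ExpertiseLabel
    duration_s: float

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]


@dataclass
class EmotionTrack:
    """18 x 7 matrix of per-frame emotion probabilities (rows on the simplex)."""

    scores: np.ndarray
    emotion_order: tuple[str, ...] = EMOTIONS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (18, 7):
            raise ValueError(f"expected 18x7 scores, got {self.scores.shape}")
        if not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("emotion rows must sum to 1 within 1e-6")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError("emotion scores must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    ``effect_size`` is the between-adjacent-class separation of the
    haemodynamic response amplitude, in units of the 1/f noise SD;
    0 gives the null generator.  ``emotion_effect_size`` defaults to
    ``effect_size`` and controls the emotion-track class bias separately,
    so fusion-only signals can be constructed.
    """

    n_participants: int = 30
    n_trials: int = 15
    class_counts: tuple[int, int, int] = (10, 9, 11)
    effect_size: float = 2.0
    emotion_effect_size: float | None = None
    channel_fail_rate: float = 0.12
    duration_mean_s: float = 30.26
    duration_sd_s: float = 14.33
    fs: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_counts) != self.n_participants:
            raise ValueError(
                f"class_counts {self.class_counts} must sum to "
                f"n_participants={self.n_participants}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.channel_fail_rate < 1):
            raise ValueError("channel_fail_rate must be in [0, 1)")

    @property
    def emotion_effect(self) -> float:
        return (
            self.effect_size
            if self.emotion_effect_size is None
            else self.emotion_effect_size
        )


# ---------------------------------------------------------------------------
# Haemodynamic forward model
# ---------------------------------------------------------------------------

# 1/f noise SD in the oxyHb series, uM; the effect_size unit.
NOISE_SD_UM = 0.25
# Baseline activation amplitude (uM) shared by all classes.
BASE_AMPLITUDE_UM = 0.8
# Stimulus onset after trial start, s (pre-onset samples form the baseline).
ONSET_S = 2.0
# Relative multiplicative detector (shot) noise.
SHOT_NOISE_REL = 0.002
# Hemispheric asymmetry per class step per unit effect_size.
ASYMMETRY_STEP = 0.08

# Table-style recruitment metadata bands per class: (vp_lo, vp_hi, h_lo, h_hi).
_METADATA_BANDS = {
    "NV": (0, 400, 0.0, 1.0),
    "IT": (200, 1000, 1.0, 5.0),
    "EX": (1001, 3000, 5.0, 30.0),
}


def hrf_double_gamma(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s), unit peak."""
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    under = gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - under / 6.0
    m = h.max()
    return h / m if m > 0 else h


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise with the given marginal SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec = spec / np.sqrt(freqs)
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _draw_duration(config: CohortConfig, rng: np.random.Generator) -> float:
    lo, hi = 5.0, np.inf
    a = (lo - config.duration_mean_s) / config.duration_sd_s
    b = (hi - config.duration_mean_s) / config.duration_sd_s
    return float(
        truncnorm.rvs(
            a, b, loc=config.duration_mean_s, scale=config.duration_sd_s,
            random_state=rng,
        )
    )


def _class_amplitude(cls: str, effect_size: float) -> float:
    idx = CLASSES.index(cls)
    return BASE_AMPLITUDE_UM + effect_size * NOISE_SD_UM * (idx - 1)


def generate_fnirs_trial(
    label: ExpertiseLabel,
    config: CohortConfig,
    rng: np.random.Generator,
    participant_id: int = 0,
    trial_id: int = 0,
) -> RawFnirsTrial:
    """Forward-model one raw fNIRS trial.

    The oxyHb course is an HRF convolved with a boxcar spanning the trial
    from stimulus onset, with class-dependent amplitude and left/right
    asymmetry (both scaled by ``config.effect_size``) plus 1/f noise.  The
    paired deoxyHb course is an inverted, attenuated copy.  Concentration
    changes are pushed through the modified Beer-Lambert law to per-
    wavelength optical densities, then to detector intensities around a
    per-channel baseline level; a fraction of channels is corrupted into
    exactly one QC failure mode.
    """
    fs = config.fs
    duration = _draw_duration(config, rng)
    n = max(int(round(duration * fs)), int(round((ONSET_S + 5.0) * fs)))
    t = np.arange(n) / fs

    onset_idx = int(round(ONSET_S * fs))
    boxcar = np.zeros(n)
    boxcar[onset_idx:] = 1.0
    kernel = hrf_double_gamma(np.arange(0, 30.0, 1.0 / fs))
    drive = np.convolve(boxcar, kernel)[:n]
    drive /= max(drive.max(), 1e-12)

    amp = _class_amplitude(label.cls, config.effect_size)
    asym = ASYMMETRY_STEP * config.effect_size * (CLASSES.index(label.cls) - 1)

    pathlength = SOURCE_DETECTOR_CM * DPF
    intensities = np.empty((N_CHANNELS, 2, n))
    for ch in range(N_CHANNELS):
        side = 1.0 + asym if ch in LEFT_CHANNELS else 1.0 - asym
        ch_gain = 1.0 + 0.05 * rng.standard_normal()
        oxy = amp * side * ch_gain * drive + _pink_noise(rng, n, NOISE_SD_UM)
        deoxy = -0.3 * amp * side * ch_gain * drive + _pink_noise(
            rng, n, 0.4 * NOISE_SD_UM
        )
        # ΔOD_λ = (ε_HbO ΔHbO + ε_HbR ΔHbR) · d · DPF  (concentrations in uM)
        dod = EXTINCTION_CM_PER_UM @ np.vstack([oxy, deoxy]) * pathlength
        i0 = rng.uniform(800.0, 1200.0, size=(2, 1))
        series = i0 * 10.0 ** (-dod)
        series *= 1.0 + SHOT_NOISE_REL * rng.standard_normal(series.shape)
        intensities[ch] = np.clip(series, 1e-6, ADC_CEILING)

    # Channel corruption: exactly one failure mode per corrupted channel.
    for ch in range(N_CHANNELS):
        if rng.random() < config.channel_fail_rate:
            mode = rng.integers(3)
            if mode == 0:  # near-zero signal
                intensities[ch] *= 1e-3
            elif mode == 1:  # saturation clamp
                intensities[ch] = np.minimum(intensities[ch] * 8.0, ADC_CEILING)
            else:  # light leakage: high-variance multiplicative noise
                leak = 1.0 + 0.4 * rng.standard_normal(intensities[ch].shape)
                intensities[ch] = np.clip(
                    intensities[ch] * np.abs(leak), 1e-6, ADC_CEILING
                )

    return RawFnirsTrial(
        intensities=intensities,
        fs=fs,
        baseline_window=(0, max(onset_idx, 1)),
        participant_id=participant_id,
        trial_id=trial_id,
        label=label,
        duration_s=duration,
    )


# Class-preferred emotion under a positive effect: novices neutral,
# intermediates surprised, experts happy.
_CLASS_EMOTION = {"NV": "Neutral", "IT": "Surprise", "EX": "Happiness"}
_BASE_CONCENTRATION = 3.0
_EMOTION_BIAS_STEP = 2.0


def generate_emotion_track(
    label: ExpertiseLabel,
    config: CohortConfig,
    rng: np.random.Generator,
) -> EmotionTrack:
    """Draw an 18-frame emotion track from a class-dependent Dirichlet."""
    conc = np.full(7, _BASE_CONCENTRATION)
    eff = config.emotion_effect
    if eff > 0:
        conc[EMOTIONS.index(_CLASS_EMOTION[label.cls])] += _EMOTION_BIAS_STEP * eff
    scores = rng.dirichlet(conc, size=18)
    return EmotionTrack(scores=scores)


def _make_label(cls: str, rng: np.random.Generator) -> ExpertiseLabel:
    vp_lo, vp_hi, h_lo, h_hi = _METADATA_BANDS[cls]
    return ExpertiseLabel(
        cls=cls,
        victory_points=int(rng.integers(vp_lo, vp_hi + 1)),
        hours_per_week=float(rng.uniform(h_lo, h_hi)),
    )


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[RawFnirsTrial, EmotionTrack]]:
    """Generate the full paired cohort, reproducible from ``config.seed``.

    Returns ``n_participants * n_trials`` (RawFnirsTrial, EmotionTrack)
    pairs; the label is fixed per participant across that participant's
    trials.
    """
    root = np.random.SeedSequence(config.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    classes = [
        cls for cls, cnt in zip(CLASSES, config.class_counts) for _ in range(cnt)
    ]

    records: list[tuple[RawFnirsTrial, EmotionTrack]] = []
    trial_seeds = root.spawn(config.n_participants * config.n_trials)
    k = 0
    for pid, cls in enumerate(classes):
        label = _make_label(cls, label_rng)
        for tid in range(config.n_trials):
            rng = np.random.default_rng(trial_seeds[k])
            k += 1
            fnirs = generate_fnirs_trial(
                label, config, rng, participant_id=pid, trial_id=tid
            )
            emo = generate_emotion_track(label, config, rng)
            records.append((fnirs, emo))
    return records


# ---------------------------------------------------------------------------
# Cohort container I/O (plain CSV, one file per trial + manifest)
# ---------------------------------------------------------------------------

def _trial_stem(t: RawFnirsTrial) -> str:
    return f"P{t.participant_id:02d}_T{t.trial_id:02d}"


def write_cohort(
    cohort: list[tuple[RawFnirsTrial, EmotionTrack]],
    outdir: str | Path,
    config: CohortConfig | None = None,
) -> Path:
    """Write the cohort as long-format fNIRS CSVs, emotion CSVs and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for fnirs, emo in cohort:
        stem = _trial_stem(fnirs)
        n = fnirs.n_samples
        idx = np.repeat(np.arange(n), N_CHANNELS * 2)
        ch = np.tile(np.repeat(np.arange(N_CHANNELS), 2), n)
        wl = np.tile(np.tile([0, 1], N_CHANNELS), n)
        inten = fnirs.intensities.transpose(2, 0, 1).ravel()
        pd.DataFrame(
            {
                "sample_index": idx,
                "channel": ch,
                "wavelength": wl,
                "intensity": inten,
            }
        ).to_csv(outdir / f"{stem}_fnirs.csv", index=False)
        emo_df = pd.DataFrame(emo.scores, columns=[e.lower() for e in EMOTIONS])
        emo_df.insert(0, "t_s", np.arange(18) * 0.5)
        emo_df.to_csv(outdir / f"{stem}_emotion.csv", index=False)
        rows.append(
            {
                "participant_id": fnirs.participant_id,
                "trial_id": fnirs.trial_id,
                "class": fnirs.label.cls,
                "victory_points": fnirs.label.victory_points,
                "hours_per_week": fnirs.label.hours_per_week,
                "duration_s": fnirs.duration_s,
                "fs": fnirs.fs,
                "baseline_lo": fnirs.baseline_window[0],
                "baseline_hi": fnirs.baseline_window[1],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    if config is not None:
        (outdir / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2)
        )
    return outdir


def read_cohort(indir: str | Path) -> list[tuple[RawFnirsTrial, EmotionTrack]]:
    """Inverse of :func:`write_cohort`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    cohort = []
    for _, row in manifest.iterrows():
        stem = f"P{int(row['participant_id']):02d}_T{int(row['trial_id']):02d}"
        long = pd.read_csv(indir / f"{stem}_fnirs.csv")
        n = int(long["sample_index"].max()) + 1
        inten = np.empty((N_CHANNELS, 2, n))
        inten[
            long["channel"].to_numpy(),
            long["wavelength"].to_numpy(),
            long["sample_index"].to_numpy(),
        ] = long["intensity"].to_numpy()
        label = ExpertiseLabel(
            cls=str(row["class"]),
            victory_points=int(row["victory_points"]),
            hours_per_week=float(row["hours_per_week"]),
        )
        trial = RawFnirsTrial(
            intensities=inten,
            fs=float(row["fs"]),
            baseline_window=(int(row["baseline_lo"]), int(row["baseline_hi"])),
            participant_id=int(row["participant_id"]),
            trial_id=int(row["trial_id"]),
            label=label,
            duration_s=float(row["duration_s"]),
        )
        emo_df = pd.read_csv(indir / f"{stem}_emotion.csv")
        emo = EmotionTrack(
            scores=emo_df[[e.lower() for e in EMOTIONS]].to_numpy()
        )
        cohort.append((trial, emo))
    return cohort
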