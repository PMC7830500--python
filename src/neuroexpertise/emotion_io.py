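"""Ingestion of externally produced per-frame emotion score tracks.

Emotion scores arrive as CSVs of per-frame probabilities over the seven
basic expressions (one row per sampled video frame, twice per second).
They are validated, renormalised within a small tolerance (upstream
networks emit rows summing to ~0.999x), and reduced to the fixed 18-frame
grid by uniform nearest-timestamp frame selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import EMOTIONS, EmotionTrack

__all__ = [
    "RawEmotionFrames", "load_emotion_csv", "to_fixed_grid",
    "dominant_emotion", "write_emotion_csv",
]

logger = logging.getLogger(__name__)

#: Renormalisation tolerance for rows that do not sum exactly to 1.
ROW_SUM_TOL = 1e-3

_COLUMNS = tuple(e.lower() for e in EMOTIONS)


@dataclass
class RawEmotionFrames:
    """Variable-length emotion frames before grid fixing."""

    timestamps: np.ndarray   # seconds from trial start, strictly increasing
    scores: np.ndarray       # (n_frames, 7)
    emotion_order: tuple[str, ...] = EMOTIONS

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")


def load_emotion_csv(path: str | Path) -> RawEmotionFrames:
    """Parse a per-trial emotion CSV (`t_s` + the 7 named score columns).

    Rows whose probabilities do not sum to 1 are renormalised with a logged
    warning; negative scores or missing columns are errors.
    """
    df = pd.read_csv(path)
    for col in _COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing emotion column {col!r} in {path}")
    scores = df[list(_COLUMNS)].to_numpy(dtype=float)
    if (scores < 0).any():
        raise ValueError(f"negative emotion score in {path}")
    sums = scores.sum(axis=1)
    off = np.abs(sums - 1.0) > 1e-9
    if off.any():
        logger.warning(
            "%s: %d/%d rows renormalised (max deviation %.2e)",
            path, int(off.sum()), len(sums), float(np.abs(sums - 1).max()),
        )
        if (np.abs(sums - 1.0) > ROW_SUM_TOL).any():
            warnings.warn(
                f"{path}: row sums deviate beyond tolerance {ROW_SUM_TOL}",
                stacklevel=2,
            )
        scores = scores / sums[:, None]
    if "t_s" in df.columns:
        t = df["t_s"].to_numpy(dtype=float)
    else:
        t = 0.5 * np.arange(len(df))  # sampled twice per second
    return RawEmotionFrames(timestamps=t, scores=scores)


def to_fixed_grid(frames: RawEmotionFrames, n_out: int = 18) -> EmotionTrack:
    """Select ``n_out`` frames uniformly across the trial span.

    Uses nearest-timestamp selection (frames are *selected*, not
    interpolated); selected rows are renormalised.  Requires >= 2 frames.
    """
    n_in = len(frames.timestamps)
    if n_in < 2:
        raise ValueError("need at least 2 frames to fix the grid")
    targets = np.linspace(frames.timestamps[0], frames.timestamps[-1], n_out)
    idx = np.abs(frames.timestamps[None, :] - targets[:, None]).argmin(axis=1)
    scores = frames.scores[idx]
    scores = scores / scores.sum(axis=1, keepdims=True)
    return EmotionTrack(scores=scores)


def dominant_emotion(track_row: np.ndarray) -> str:
    """Emotion with the highest score; ties break to the first index."""
    row = np.asarray(track_row, dtype=float)
    if row.shape != (7,) or not np.isfinite(row).all():
        raise ValueError("expected 7 finite scores")
    i = int(row.argmax())
    if (row == row[i]).sum() > 1:
        logger.info("dominant_emotion tie broken to first index %d", i)
    return EMOTIONS[i]


def write_emotion_csv(track: EmotionTrack, path: str | Path,
                      fs_frames: float = 2.0) -> None:
    """Write an EmotionTrack in the canonical CSV schema."""
    df = pd.DataFrame(track.scores, columns=list(_COLUMNS))
    df.insert(0, "t_s", np.arange(len(df)) / fs_frames)
    df.to_csv(path, index=False)
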