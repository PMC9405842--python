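"""Binocular gaze recordings: container, CSV I/O, gap handling.

A recording is a pair of horizontal eye-position time series (left and right
eye, in degrees, positive rightward) on a shared, strictly increasing
timestamp grid (seconds).  Video-oculography at a nominal 200 Hz is the
expected source; timestamps may jitter and are used as-is (no resampling).

Samples with non-finite positions are *gaps* (typically blinks or tracking
dropouts).  Gaps never enter any computation: recordings are split into
gap-free sub-recordings before analysis (:func:`split_on_gaps`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinocularRecording",
    "CohortManifest",
    "RecordingError",
    "read_recording",
    "write_recording",
    "split_on_gaps",
    "read_manifest",
    "write_manifest",
]

#: Column names of the on-disk CSV format.
CSV_COLUMNS = ("timestamp_s", "left_x_deg", "right_x_deg")

VALID_LABELS = ("control", "dyslexic", "unknown")


class RecordingError(ValueError):
    """Malformed, non-monotone or too-short gaze recording."""


@dataclasses.dataclass
class BinocularRecording:
    """Timestamped left/right horizontal gaze positions.

    Parameters
    ----------
    t : ndarray, shape (n,)
        Timestamps in seconds, strictly increasing, n >= 2.
    left_x, right_x : ndarray, shape (n,)
        Horizontal position of the left / right eye in degrees; increasing
        values mean rightward gaze.  Non-finite entries mark gaps.
    nominal_rate : float
        Nominal sampling rate per eye in Hz.
    subject, label, stimulus : metadata
        Subject identifier, group label (``control``/``dyslexic``/``unknown``)
        and stimulus (painting) identifier.
    """

    t: np.ndarray
    left_x: np.ndarray
    right_x: np.ndarray
    nominal_rate: float = 200.0
    subject: str = ""
    label: str = "unknown"
    stimulus: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left_x = np.asarray(self.left_x, dtype=float)
        self.right_x = np.asarray(self.right_x, dtype=float)
        if not (self.t.shape == self.left_x.shape == self.right_x.shape):
            raise RecordingError("timestamps and positions must have equal length")
        if self.t.ndim != 1 or self.t.size < 2:
            raise RecordingError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(self.t)):
            raise RecordingError("timestamps must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise RecordingError("timestamps must be strictly increasing")
        if self.label not in VALID_LABELS:
            raise RecordingError(f"label must be one of {VALID_LABELS}")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def span(self) -> float:
        """Total duration T[n-1] - T[0] in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def gap_mask(self) -> np.ndarray:
        """Boolean mask of samples flagged as gaps (non-finite position)."""
        return ~(np.isfinite(self.left_x) & np.isfinite(self.right_x))

    @property
    def n_gaps(self) -> int:
        return int(self.gap_mask.sum())

    def inferred_rate(self) -> float:
        """Sampling rate estimated as 1 / median inter-sample interval."""
        return float(1.0 / np.median(np.diff(self.t)))

    def time_scaled(self, k: float) -> "BinocularRecording":
        """Copy with all timestamps multiplied by k > 0 (rate scales by 1/k)."""
        if k <= 0:
            raise ValueError("k must be positive")
        return dataclasses.replace(self, t=self.t * k, nominal_rate=self.nominal_rate / k)


@dataclasses.dataclass
class CohortManifest:
    """Table linking recording files to subject, group label and painting.

    One row per (subject, painting).  Labels are binary: 0 control,
    1 dyslexic.  Painting ids are small positive integers (1..7 in the
    seven-painting free-viewing design).
    """

    table: pd.DataFrame  # columns: path, subject, label, painting

    REQUIRED = ("path", "subject", "label", "painting")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise RecordingError(f"manifest missing columns: {missing}")
        lab = self.table["label"]
        if not lab.isin((0, 1)).all():
            raise RecordingError("manifest labels must be 0 (control) or 1 (dyslexic)")
        if (self.table["painting"].astype(int) < 1).any():
            raise RecordingError("painting ids must be positive integers")
        dup = self.table.duplicated(subset=["subject", "painting"])
        if dup.any():
            raise RecordingError("manifest has duplicate (subject, painting) rows")

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[pd.Series]:
        return (row for _, row in self.table.iterrows())

    @property
    def paintings(self) -> list[int]:
        return sorted(self.table["painting"].astype(int).unique())


def read_recording(
    path: str | Path,
    *,
    nominal_rate: float | None = None,
    subject: str = "",
    label: str = "unknown",
    stimulus: str = "",
) -> BinocularRecording:
    """Read a gaze CSV (columns ``timestamp_s, left_x_deg, right_x_deg``).

    Rows with missing or non-finite positions are kept and flagged as gaps;
    optional vertical-channel columns are accepted and ignored.  The nominal
    rate defaults to ``1 / median(dt)`` rounded to the nearest Hz.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingError(f"{path}: missing required columns {missing}")
    t = df["timestamp_s"].to_numpy(float)
    if len(t) < 2:
        raise RecordingError(f"{path}: fewer than 2 samples")
    meta = {}
    for key, col in (("subject", "subject"), ("label", "label"), ("stimulus", "painting")):
        if col in df.columns and df[col].notna().any():
            meta[key] = str(df[col].iloc[0])
    if nominal_rate is None:
        nominal_rate = float(np.round(1.0 / np.median(np.diff(t))))
    return BinocularRecording(
        t=t,
        left_x=df["left_x_deg"].to_numpy(float),
        right_x=df["right_x_deg"].to_numpy(float),
        nominal_rate=nominal_rate,
        subject=subject or meta.get("subject", ""),
        label=label if label != "unknown" else meta.get("label", "unknown"),
        stimulus=stimulus or meta.get("stimulus", ""),
    )


def write_recording(rec: BinocularRecording, path: str | Path) -> None:
    """Write a recording as CSV; ``read_recording(write_recording(rec))``
    round-trips timestamps and positions to float precision."""
    df = pd.DataFrame(
        {
            "timestamp_s": rec.t,
            "left_x_deg": rec.left_x,
            "right_x_deg": rec.right_x,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def split_on_gaps(
    rec: BinocularRecording, max_gap: float | None = None
) -> list[BinocularRecording]:
    """Split a recording into gap-free, temporally contiguous sub-recordings.

    A split occurs at every flagged (non-finite) sample and at every
    inter-sample interval longer than ``max_gap`` seconds (default: 3x the
    nominal sample period).  Sub-recordings shorter than 2 samples are
    dropped; an empty list is possible.
    """
    if max_gap is None:
        max_gap = 3.0 / rec.nominal_rate
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    good = ~rec.gap_mask
    # breakpoints: after sample i if i or i+1 is bad, or dt > max_gap
    out: list[BinocularRecording] = []
    idx = np.flatnonzero(good)
    if idx.size == 0:
        return out
    # group consecutive good indices whose gaps are short
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(rec.t[idx]) > max_gap)
    )
    for chunk in np.split(idx, breaks + 1):
        if chunk.size >= 2:
            out.append(
                dataclasses.replace(
                    rec,
                    t=rec.t[chunk].copy(),
                    left_x=rec.left_x[chunk].copy(),
                    right_x=rec.right_x[chunk].copy(),
                )
            )
    return out


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path)
    return CohortManifest(df)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)
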