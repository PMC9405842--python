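"""Disconjugacy Global Index (DGI): opposite-direction binocular segments.

The two eyes normally move together (conjugately).  Brief periods in which
the left and right eye travel in *opposite* horizontal directions —
micro-convergence or micro-divergence, mostly during fixations — are
detected here from the sign of the product of the two eyes' instantaneous
velocities:

* disparity signal  ``D[i]  = Xl[i] - Xr[i]``  (degrees),
* velocity product  ``DV[i] = vl[i] * vr[i]``  ((deg/s)^2), where
  ``vl[i] = (Xl[i+1]-Xl[i]) / (T[i+1]-T[i])`` and likewise for the right eye.

``DV < 0`` on an interval means the eyes moved in opposite directions during
that interval.  Candidate segments are maximal runs of consecutive
``DV < 0`` intervals; each run is split into sub-segments wherever the sign
of ``D`` changes (a ``D == 0`` sample acts as a boundary), each sub-segment
is labelled converging (|D| shrinking) or diverging (|D| growing), and
sub-segments spanning fewer than ``min_samples`` position samples (default
3) are discarded as tracker noise.

The DGI of a recording is the retained segment count divided by the total
analyzed duration (segments per second); the mean segment duration (ms) and
mean segment amplitude (degrees, ``|D[end] - D[start]|``) complete the
three-descriptor set.

Velocities here are raw first differences over the actual timestamps — no
smoothing — because the target events are 1–4 interval micro-movements that
any low-pass filter would erase.  The saccade analysis in
:mod:`oculodex.saccades` uses a smoothed differentiator instead; the two
modules deliberately do not share one.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .recording import BinocularRecording, RecordingError, split_on_gaps

__all__ = [
    "DisconjugacySeries",
    "DisconjugacySegment",
    "DGIResult",
    "compute_series",
    "find_candidate_segments",
    "split_by_direction",
    "filter_segments",
    "compute_dgi",
    "amplitude_histogram",
    "DisconjugacyIndexTransformer",
    "DGI_FEATURE_NAMES",
]

DGI_FEATURE_NAMES = ("dgi", "mean_duration_ms", "mean_amplitude_deg")


@dataclasses.dataclass
class DisconjugacySeries:
    """Per-sample disparity D and per-interval velocity product DV."""

    t: np.ndarray  # (n,) seconds
    d: np.ndarray  # (n,) degrees, Xl - Xr
    dv: np.ndarray  # (n-1,) (deg/s)^2, vl * vr


@dataclasses.dataclass
class DisconjugacySegment:
    """One opposite-direction micro-movement of the two eyes.

    Indices are inclusive sample indices into the analyzed (sub-)recording;
    a segment spanning samples ``a..b`` covers ``b - a`` velocity intervals
    and ``b - a + 1`` position samples.
    """

    start_index: int
    end_index: int
    start_time: float  # s
    end_time: float  # s
    duration_ms: float
    amplitude_deg: float  # |D[end] - D[start]|
    direction: str  # "converging" | "diverging"

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1


@dataclasses.dataclass
class DGIResult:
    """DGI descriptor set for one recording.

    ``dgi = count / total_duration_s`` (segments per second); the means are
    arithmetic means over retained segments (0 when there are none).
    """

    dgi: float
    mean_duration_ms: float
    mean_amplitude_deg: float
    count: int
    total_duration_s: float
    segments: list[DisconjugacySegment]
    subject: str = ""
    label: str = "unknown"
    stimulus: str = ""

    def amplitudes(self) -> np.ndarray:
        return np.array([s.amplitude_deg for s in self.segments], dtype=float)

    def features(self) -> np.ndarray:
        """The (dgi, mean_duration_ms, mean_amplitude_deg) vector."""
        return np.array([self.dgi, self.mean_duration_ms, self.mean_amplitude_deg])

    def to_dict(self) -> dict:
        return {
            "dgi": self.dgi,
            "count": self.count,
            "mean_duration_ms": self.mean_duration_ms,
            "mean_amplitude_deg": self.mean_amplitude_deg,
            "total_duration_s": self.total_duration_s,
            "segments": [dataclasses.asdict(s) for s in self.segments],
        }


def compute_series(rec: BinocularRecording) -> DisconjugacySeries:
    """Disparity D = Xl - Xr and velocity product DV from raw differences."""
    if rec.n < 2:
        raise RecordingError("need at least 2 samples")
    dt = np.diff(rec.t)
    vl = np.diff(rec.left_x) / dt
    vr = np.diff(rec.right_x) / dt
    return DisconjugacySeries(t=rec.t, d=rec.left_x - rec.right_x, dv=vl * vr)


def find_candidate_segments(series: DisconjugacySeries) -> list[tuple[int, int]]:
    """Maximal runs of consecutive strictly negative DV intervals.

    Returns inclusive ``(first, last)`` interval-index pairs, ordered and
    disjoint.  ``DV == 0`` (one eye momentarily static) is not
    opposite-direction motion and terminates a run; runs touching the
    recording boundary are kept.
    """
    neg = series.dv < 0
    if not neg.any():
        return []
    padded = np.concatenate(([False], neg, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def _split_run(
    d: np.ndarray, t: np.ndarray, s: int, l: int
) -> list[tuple[int, int]]:
    """Partition run samples ``s..l`` into constant-sign(D) blocks.

    An interior ``D == 0`` sample closes the current block *and* starts the
    next (shared boundary sample); a zero at a block start adopts the sign of
    the next nonzero sample; a direct sign flip between adjacent samples
    closes the block at the earlier sample.
    """
    blocks: list[tuple[int, int]] = []
    start = s
    cur = _sign(d[s])
    for j in range(s + 1, l + 1):
        sj = _sign(d[j])
        if sj == 0:
            blocks.append((start, j))
            start = j
            cur = 0
        elif cur == 0:
            cur = sj
        elif sj != cur:
            blocks.append((start, j - 1))
            start = j
            cur = sj
    if start < l or not blocks or blocks[-1][1] < l:
        blocks.append((start, l))
    return blocks


def split_by_direction(
    runs: Sequence[tuple[int, int]], series: DisconjugacySeries
) -> list[DisconjugacySegment]:
    """Split candidate runs at sign changes of D and label each sub-segment.

    A run over intervals ``p..q`` spans position samples ``p..q+1``.  A
    sub-segment is *converging* when it shrinks the disparity magnitude
    (|D| at its end below |D| at its start) and *diverging* otherwise.
    """
    d, t = series.d, series.t
    out: list[DisconjugacySegment] = []
    for p, q in runs:
        for a, b in _split_run(d, t, p, q + 1):
            converging = abs(d[b]) < abs(d[a])
            out.append(
                DisconjugacySegment(
                    start_index=int(a),
                    end_index=int(b),
                    start_time=float(t[a]),
                    end_time=float(t[b]),
                    duration_ms=float((t[b] - t[a]) * 1e3),
                    amplitude_deg=float(abs(d[b] - d[a])),
                    direction="converging" if converging else "diverging",
                )
            )
    return out


def filter_segments(
    segments: Iterable[DisconjugacySegment], min_samples: int = 3
) -> list[DisconjugacySegment]:
    """Retain segments spanning at least ``min_samples`` position samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    return [s for s in segments if s.n_samples >= min_samples]


def compute_dgi(
    rec: BinocularRecording,
    min_samples: int = 3,
    *,
    max_gap: float | None = None,
) -> DGIResult:
    """Full DGI pipeline for one recording.

    Gap-flagged samples and long dropouts split the recording first; segment
    detection runs on each gap-free piece and the DGI denominator is the sum
    of analyzed piece durations, so blinks neither create spurious velocity
    spikes nor inflate the rate.
    """
    pieces = split_on_gaps(rec, max_gap=max_gap)
    if not pieces:
        raise RecordingError("no usable samples after gap handling")
    total = sum(p.span for p in pieces)
    if total <= 0:
        raise RecordingError("zero usable duration")
    segments: list[DisconjugacySegment] = []
    for piece in pieces:
        series = compute_series(piece)
        runs = find_candidate_segments(series)
        segments.extend(filter_segments(split_by_direction(runs, series), min_samples))
    count = len(segments)
    return DGIResult(
        dgi=count / total,
        mean_duration_ms=(
            float(np.mean([s.duration_ms for s in segments])) if count else 0.0
        ),
        mean_amplitude_deg=(
            float(np.mean([s.amplitude_deg for s in segments])) if count else 0.0
        ),
        count=count,
        total_duration_s=total,
        segments=segments,
        subject=rec.subject,
        label=rec.label,
        stimulus=rec.stimulus,
    )


def amplitude_histogram(
    results: Sequence[DGIResult], bins: int = 100
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Pooled segment-amplitude histogram, per group label.

    All segment amplitudes are pooled to fix ``bins`` equal-width bin edges
    over the common range; counts are then tallied separately for each group
    label present.  Returns ``(edges, {label: counts})``.
    """
    if not results:
        raise ValueError("need at least one DGIResult")
    pooled = np.concatenate([r.amplitudes() for r in results]) if results else np.array([])
    if pooled.size == 0:
        raise ValueError("no segments to histogram")
    edges = np.histogram_bin_edges(pooled, bins=bins)
    counts: dict[str, np.ndarray] = {}
    for label in sorted({r.label for r in results}):
        amps = np.concatenate(
            [r.amplitudes() for r in results if r.label == label]
            or [np.array([])]
        )
        counts[label], _ = np.histogram(amps, bins=edges)
    return edges, counts


class DisconjugacyIndexTransformer(TransformerMixin, BaseEstimator):
    """Sklearn transformer: recordings -> (dgi, mean duration, mean amplitude).

    Stateless (``fit`` only validates); ``transform`` accepts a sequence of
    :class:`BinocularRecording` and returns an ``(n, 3)`` float array with
    columns :data:`DGI_FEATURE_NAMES`.

    Parameters
    ----------
    min_samples : int
        Minimum position-sample span of a retained segment.
    max_gap : float or None
        Dropout-split threshold in seconds (None: 3x nominal sample period).
    """

    def __init__(self, min_samples: int = 3, max_gap: float | None = None):
        self.min_samples = min_samples
        self.max_gap = max_gap

    def fit(self, X: Sequence[BinocularRecording], y=None):
        self._validate(X)
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[BinocularRecording]) -> np.ndarray:
        check_is_fitted(self)
        self._validate(X)
        rows = [
            compute_dgi(rec, self.min_samples, max_gap=self.max_gap).features()
            for rec in X
        ]
        return np.vstack(rows) if rows else np.empty((0, 3))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(DGI_FEATURE_NAMES, dtype=object)

    @staticmethod
    def _validate(X) -> None:
        for rec in X:
            if not isinstance(rec, BinocularRecording):
                raise TypeError(
                    "expected a sequence of BinocularRecording, "
                    f"got element of type {type(rec).__name__}"
                )

    def _more_tags(self):
        return {"X_types": ["list"], "no_validation": True}
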