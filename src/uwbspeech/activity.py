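"""Two-stage automatic silent-speech activity detection.

Stage one (general motion): frame-to-frame amplitude differences are
normalized to unit sum per frame pair; the variance of that normalized
profile about its forced mean ``1/N`` spikes whenever the differences
concentrate in a few range bins, i.e. whenever something in front of the
radar moves.  The variance series is smoothed with an exponential moving
average and thresholded; a segment closes only after the smoothed variance
has stayed below threshold for a gap interval, and fixed margins are added
so the filter lag does not clip the articulation.

Stage two (articulator confirmation): a detected segment is accepted only
if every detection in it stays within a distance gate around the rest
distance (default −4 cm toward / +3 cm away from the radar) — larger
excursions indicate head or body motion rather than articulation, and the
segment is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clean import CleanMap
from .clutter import ClutterReducedMatrix

__all__ = [
    "MotionTrace",
    "SpeechSegment",
    "amplitude_diff",
    "motion_variance",
    "smooth_variance",
    "motion_trace",
    "apply_margins",
    "detect_general_motion",
    "rest_distance",
    "confirm_articulator_motion",
]

DEFAULT_ALPHA = 0.1
DEFAULT_MOTION_THRESHOLD = 1e-5
DEFAULT_END_GAP_S = 0.4
DEFAULT_PRE_MARGIN_S = 0.2
DEFAULT_POST_MARGIN_S = 0.1
DEFAULT_GATE_LO_M = -0.04
DEFAULT_GATE_HI_M = 0.03


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame-pair motion statistic, raw and smoothed.

    Entry ``i`` compares scans ``i`` and ``i + 1`` and is timestamped at
    the later scan, ``(i + 1) * scan_interval_s``.
    """

    raw_variance: np.ndarray
    smoothed_variance: np.ndarray
    alpha: float
    n_bins: int
    scan_interval_s: float

    def times(self) -> np.ndarray:
        return (np.arange(self.raw_variance.size) + 1) * self.scan_interval_s


@dataclass(frozen=True)
class SpeechSegment:
    """A detected speech candidate with raw crossings and margined window."""

    raw_start_s: float
    raw_end_s: float
    start_s: float
    end_s: float
    confirmed: bool = True

    def __post_init__(self) -> None:
        if not (self.start_s <= self.raw_start_s < self.raw_end_s <= self.end_s):
            raise ValueError(
                f"segment ordering violated: start {self.start_s} <= raw_start "
                f"{self.raw_start_s} < raw_end {self.raw_end_s} <= end {self.end_s}"
            )
        if self.start_s < 0:
            raise ValueError("segment start must be >= 0")


def amplitude_diff(reduced: ClutterReducedMatrix, m: int) -> np.ndarray:
    """Normalized absolute amplitude difference between scans m and m-1.

    ``x[n] = |Y[m,n] - Y[m-1,n]| / sum_k |Y[m,k] - Y[m-1,k]|``; the result
    sums to one.  Identical consecutive scans (zero denominator) mean no
    motion at all; the uniform profile ``1/N`` is returned, which has zero
    variance.
    """
    if m < 1 or m >= reduced.m_scans:
        raise ValueError(f"m must be in [1, {reduced.m_scans}), got {m}")
    diff = np.abs(reduced.values[m] - reduced.values[m - 1])
    denom = diff.sum()
    if denom == 0.0:
        return np.full(reduced.n_bins, 1.0 / reduced.n_bins)
    return diff / denom


def motion_variance(x: np.ndarray) -> float:
    """Population variance of the normalized difference profile about 1/N."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return float(np.mean((x - 1.0 / n) ** 2))


def smooth_variance(raw: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Exponential moving average, initialized at the first raw value."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    raw = np.asarray(raw, dtype=float)
    out = np.empty_like(raw)
    if raw.size == 0:
        return out
    out[0] = raw[0]
    for i in range(1, raw.size):
        out[i] = alpha * raw[i] + (1.0 - alpha) * out[i - 1]
    return out


def motion_trace(
    reduced: ClutterReducedMatrix, alpha: float = DEFAULT_ALPHA
) -> MotionTrace:
    """Raw and smoothed motion variance for every consecutive scan pair."""
    diffs = np.abs(np.diff(reduced.values, axis=0))
    sums = diffs.sum(axis=1, keepdims=True)
    n = reduced.n_bins
    x = np.where(sums == 0.0, 1.0 / n, diffs / np.where(sums == 0.0, 1.0, sums))
    raw = np.mean((x - 1.0 / n) ** 2, axis=1)
    return MotionTrace(
        raw_variance=raw,
        smoothed_variance=smooth_variance(raw, alpha),
        alpha=alpha,
        n_bins=n,
        scan_interval_s=reduced.scan_interval_s,
    )


def apply_margins(
    raw_start_s: float,
    raw_end_s: float,
    pre_margin_s: float = DEFAULT_PRE_MARGIN_S,
    post_margin_s: float = DEFAULT_POST_MARGIN_S,
) -> tuple[float, float]:
    """Extend a raw threshold-crossing window by the storage margins.

    The smoothing filter lags the true articulation, so the stored window
    starts ``pre_margin_s`` before the upward crossing and ends
    ``post_margin_s`` after the downward crossing; the start is clipped at
    zero.
    """
    return max(0.0, raw_start_s - pre_margin_s), raw_end_s + post_margin_s


def detect_general_motion(
    trace: MotionTrace,
    threshold: float = DEFAULT_MOTION_THRESHOLD,
    end_gap_s: float = DEFAULT_END_GAP_S,
    pre_margin_s: float = DEFAULT_PRE_MARGIN_S,
    post_margin_s: float = DEFAULT_POST_MARGIN_S,
) -> list[SpeechSegment]:
    """Threshold the smoothed variance into candidate speech segments.

    A segment opens at the first frame whose smoothed variance is at or
    above ``threshold`` and closes once the trace has stayed below
    threshold for ``end_gap_s`` (briefer dips — e.g. the pause between the
    forward and backward lip strokes of a word — do not split a segment).
    ``raw_end_s`` is the time of the first below-threshold frame after the
    segment's last above-threshold frame; storage margins are then applied.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    times = trace.times()
    smoothed = trace.smoothed_variance
    dt = trace.scan_interval_s

    segments: list[SpeechSegment] = []
    open_start: float | None = None
    last_above: float | None = None
    for t, value in zip(times, smoothed):
        if value >= threshold:
            if open_start is None:
                open_start = t
            last_above = t
        elif open_start is not None and t - last_above >= end_gap_s:
            segments.append(_make_segment(open_start, last_above + dt,
                                          pre_margin_s, post_margin_s))
            open_start = None
            last_above = None
    if open_start is not None:
        segments.append(_make_segment(open_start, last_above + dt,
                                      pre_margin_s, post_margin_s))
    return segments


def _make_segment(
    raw_start: float, raw_end: float, pre_margin_s: float, post_margin_s: float
) -> SpeechSegment:
    start, end = apply_margins(raw_start, raw_end, pre_margin_s, post_margin_s)
    return SpeechSegment(
        raw_start_s=raw_start, raw_end_s=raw_end, start_s=start, end_s=end
    )


def rest_distance(
    clean_map: CleanMap,
    segment: SpeechSegment,
    pre_window_s: float = 0.5,
) -> int:
    """Median detection bin over the no-motion window preceding a segment.

    The window is the ``pre_window_s`` seconds ending at the segment's raw
    start (exclusive); per-scan primary detections inside it vote by
    median, which is robust to occasional spurious detections.
    """
    times, bins, _ = clean_map.primary_arrays()
    lo = segment.raw_start_s - pre_window_s
    mask = (times >= lo) & (times < segment.raw_start_s)
    if not np.any(mask):
        raise ValueError(
            "no detections in the pre-speech window; capture more rest data "
            "before the articulation or widen pre_window_s"
        )
    return int(round(float(np.median(bins[mask]))))


def confirm_articulator_motion(
    clean_map: CleanMap,
    segment: SpeechSegment,
    rest_bin: int,
    lo_m: float = DEFAULT_GATE_LO_M,
    hi_m: float = DEFAULT_GATE_HI_M,
) -> bool:
    """Check that every in-segment detection stays inside the distance gate.

    The gate is ``[rest + lo_m, rest + hi_m]`` around the rest distance
    (negative = toward the radar).  A single excursion beyond it indicates
    non-articulator motion (e.g. the head) and rejects the whole segment.
    """
    if lo_m >= hi_m:
        raise ValueError(f"gate bounds must satisfy lo < hi, got {lo_m}, {hi_m}")
    times, bins, _ = clean_map.primary_arrays()
    mask = (times >= segment.start_s) & (times <= segment.end_s)
    if not np.any(mask):
        return False
    lo_bin = rest_bin + lo_m / clean_map.bin_size_m
    hi_bin = rest_bin + hi_m / clean_map.bin_size_m
    inside = (bins[mask] >= lo_bin) & (bins[mask] <= hi_bin)
    return bool(np.all(inside))
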