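"""Clutter reduction by background averaging.

Echoes from the static environment (and the direct antenna-coupling
leakage) are estimated by averaging scans of a background capture taken
with nothing in front of the radar, and subtracted from every scan of the
live session.  The estimate uses the first ``m_b`` scans (100 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import RadarFrameMatrix

__all__ = [
    "BackgroundModel",
    "ClutterReducedMatrix",
    "estimate_background",
    "reduce_clutter",
]

DEFAULT_M_B = 100


@dataclass(frozen=True)
class BackgroundModel:
    """Per-bin mean of the background capture."""

    mean_row: np.ndarray
    m_scans_used: int

    def __post_init__(self) -> None:
        mean_row = np.asarray(self.mean_row, dtype=float)
        if mean_row.ndim != 1 or not np.all(np.isfinite(mean_row)):
            raise ValueError("background mean_row must be a finite 1-D vector")
        if self.m_scans_used < 1:
            raise ValueError("m_scans_used must be >= 1")
        object.__setattr__(self, "mean_row", mean_row)


@dataclass(frozen=True)
class ClutterReducedMatrix:
    """Clutter-reduced signal matrix Y[m, n]; same shape/metadata as its source."""

    values: np.ndarray
    scan_interval_s: float
    bin_size_m: float

    @property
    def m_scans(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.values.shape[1])

    def scan_times(self) -> np.ndarray:
        return np.arange(self.m_scans) * self.scan_interval_s


def estimate_background(
    background_session: RadarFrameMatrix, m_b: int = DEFAULT_M_B
) -> BackgroundModel:
    """Average the first ``m_b`` scans of a background capture.

    Raises an error when the capture is shorter than ``m_b`` scans rather
    than silently averaging fewer.
    """
    if m_b < 1:
        raise ValueError(f"m_b must be >= 1, got {m_b}")
    if background_session.m_scans < m_b:
        raise ValueError(
            f"background capture has {background_session.m_scans} scans; "
            f"{m_b} are required (reduce m_b or record a longer background)"
        )
    mean_row = background_session.values[:m_b].mean(axis=0)
    return BackgroundModel(mean_row=mean_row, m_scans_used=m_b)


def background_from_session(
    session: RadarFrameMatrix, m_b: int = DEFAULT_M_B
) -> BackgroundModel:
    """Fallback: estimate the background from the live session's own first scans.

    Usable when no empty-room capture exists; valid only if the first
    ``m_b`` scans are free of articulation.
    """
    return estimate_background(session, m_b=m_b)


def reduce_clutter(
    session: RadarFrameMatrix, background: BackgroundModel
) -> ClutterReducedMatrix:
    """Subtract the background mean row from every scan."""
    if session.n_bins != background.mean_row.size:
        raise ValueError(
            f"session has {session.n_bins} bins but background model has "
            f"{background.mean_row.size}"
        )
    return ClutterReducedMatrix(
        values=session.values - background.mean_row[None, :],
        scan_interval_s=session.scan_interval_s,
        bin_size_m=session.bin_size_m,
    )
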