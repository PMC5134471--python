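"""Target detection: conventional CLEAN and short-template CLEAN.

Both detectors correlate a clutter-reduced scan with a pulse template.
Conventional CLEAN iterates: find the strongest correlation, record an
impulse (bin, amplitude), subtract the scaled full template from the dirty
map, repeat until the residual peak falls below a stop threshold.  The
short-template variant correlates once with the leading quarter of the
pulse and keeps the single strongest detection — with the asymmetric
monocycle template this is the *nearest* echo whenever later echoes do not
overlap its leading quarter and are no stronger than it, which is the
regime silent-speech articulation lives in (the lips are the closest and
dominant reflector).

Correlation is normalized by template energy only, so detection amplitudes
scale linearly with the received signal and the stop threshold is expressed
in signal-amplitude units (default 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clutter import ClutterReducedMatrix
from .pulse import PulseTemplate

__all__ = [
    "CleanDetection",
    "CleanMap",
    "normalized_xcorr",
    "conventional_clean",
    "short_template_clean",
    "build_clean_map",
]

DEFAULT_T_STOP = 2.0
DEFAULT_MAX_ITER = 50


@dataclass(frozen=True)
class CleanDetection:
    """A single clean-map impulse: range bin and correlation amplitude."""

    bin: int
    amplitude: float

    @property
    def no_signal(self) -> bool:
        return self.amplitude == 0.0


@dataclass(frozen=True)
class CleanMap:
    """Per-scan detections plus the metadata needed to time them.

    ``detections[m]`` lists the impulses found in scan ``m`` in discovery
    order; short-template maps have exactly one entry per scan.
    """

    detections: tuple[tuple[CleanDetection, ...], ...]
    detector_tag: str
    scan_interval_s: float
    bin_size_m: float

    @property
    def n_scans(self) -> int:
        return len(self.detections)

    def primary(self) -> list[CleanDetection | None]:
        """Per-scan primary detection: the maximum-amplitude impulse.

        For short-template maps this is the sole detection.  Scans with no
        detection yield None.
        """
        out: list[CleanDetection | None] = []
        for scan in self.detections:
            out.append(max(scan, key=lambda d: d.amplitude) if scan else None)
        return out

    def primary_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(scan_times, bins, amplitudes) of scans that have a primary detection."""
        times, bins, amps = [], [], []
        for m, det in enumerate(self.primary()):
            if det is not None:
                times.append(m * self.scan_interval_s)
                bins.append(det.bin)
                amps.append(det.amplitude)
        return np.asarray(times), np.asarray(bins, dtype=int), np.asarray(amps)


def normalized_xcorr(signal: np.ndarray, template: PulseTemplate) -> np.ndarray:
    """Cross-correlate a scan with a template, normalized by template energy.

    ``s[n] = sum_k signal[n + k] * v[k] / ||v||^2`` for lags ``n = 0..N-1``,
    with the signal zero-extended past its end, so a noiseless echo
    ``a * v`` at bin ``n0`` yields ``s[n0] = a`` exactly.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be a 1-D scan")
    v = template.samples
    if v.size > signal.size:
        raise ValueError(
            f"template ({v.size} bins) longer than signal ({signal.size} bins)"
        )
    energy = template.energy
    if energy == 0.0:
        raise ValueError("template has zero energy")
    padded = np.concatenate([signal, np.zeros(v.size - 1)])
    return np.correlate(padded, v, mode="valid") / energy


def conventional_clean(
    y: np.ndarray,
    template: PulseTemplate,
    t_stop: float = DEFAULT_T_STOP,
    max_iter: int = DEFAULT_MAX_ITER,
) -> list[CleanDetection]:
    """Iterative CLEAN deconvolution of one scan.

    Repeatedly finds the correlation peak ``(a_i, n_i)``, records the
    impulse, and subtracts ``a_i * v[n - n_i]`` from the dirty map; stops
    when the peak falls below ``t_stop`` or after ``max_iter`` iterations
    (a safety bound for pathological inputs).  Detections are returned in
    discovery order; ties at the correlation maximum resolve to the
    smallest bin.
    """
    if t_stop <= 0:
        raise ValueError(f"t_stop must be positive, got {t_stop}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    dirty = np.array(y, dtype=float)
    v = template.samples
    detections: list[CleanDetection] = []
    for _ in range(max_iter):
        s = normalized_xcorr(dirty, template)
        n_i = int(np.argmax(s))  # first occurrence = smallest bin on ties
        a_i = float(s[n_i])
        if a_i < t_stop:
            break
        stop = min(n_i + v.size, dirty.size)
        dirty[n_i:stop] -= a_i * v[: stop - n_i]
        detections.append(CleanDetection(bin=n_i, amplitude=a_i))
    return detections


def short_template_clean(
    y: np.ndarray, short: PulseTemplate
) -> CleanDetection:
    """Single-pass nearest-echo detection with the short template.

    One correlation, one maximum: ``(n_max, a_max)``.  No iteration and no
    subtraction, because echoes beyond the first may be contaminated by
    overlap.  An all-zero scan yields a zero-amplitude detection flagged by
    :attr:`CleanDetection.no_signal`.
    """
    s = normalized_xcorr(y, short)
    if not np.any(np.asarray(y) != 0.0):
        return CleanDetection(bin=0, amplitude=0.0)
    n_max = int(np.argmax(s))
    return CleanDetection(bin=n_max, amplitude=float(s[n_max]))


def build_clean_map(
    reduced: ClutterReducedMatrix,
    template: PulseTemplate,
    detector: str = "short_template",
    t_stop: float = DEFAULT_T_STOP,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CleanMap:
    """Apply a detector scan-by-scan to a clutter-reduced session.

    ``detector`` is ``"conventional"`` (pass the full template) or
    ``"short_template"`` (pass the short template).  Detector errors are
    re-raised with the scan index attached.
    """
    if detector not in ("conventional", "short_template"):
        raise ValueError(
            f"detector must be 'conventional' or 'short_template', got {detector!r}"
        )
    rows: list[tuple[CleanDetection, ...]] = []
    for m in range(reduced.m_scans):
        scan = reduced.values[m]
        try:
            if detector == "conventional":
                rows.append(tuple(conventional_clean(scan, template, t_stop, max_iter)))
            else:
                rows.append((short_template_clean(scan, template),))
        except ValueError as exc:
            raise ValueError(f"scan {m}: {exc}") from exc
    return CleanMap(
        detections=tuple(rows),
        detector_tag=detector,
        scan_interval_s=reduced.scan_interval_s,
        bin_size_m=reduced.bin_size_m,
    )
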