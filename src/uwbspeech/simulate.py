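"""Received-signal synthesis: fast-time/slow-time frame matrices.

Each radar scan is modeled as a superposition of delayed, scaled copies of
the transmitted pulse — one per scatterer — plus antenna-coupling leakage at
zero range, additive white Gaussian receiver noise and a slow common-mode
baseline wander.  Scans taken every ``scan_interval_s`` stack into the
``M x N`` frame matrix ``R[m, n]`` (slow time x fast time) that every
downstream stage consumes.

Scan ``m`` is sampled at slow time ``m * scan_interval_s`` with 0-based
indexing; range bin ``n`` spans ``[n * bin_size_m, (n + 1) * bin_size_m)``
and delays are rounded to the nearest bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pulse import PulseTemplate
from .scene import SceneSpec

__all__ = ["RadarFrameMatrix", "GroundTruth", "simulate_scan", "simulate_session"]


@dataclass(frozen=True)
class RadarFrameMatrix:
    """Sampled received signal: row ``m`` is the scan at slow time ``m * T_s``."""

    values: np.ndarray
    scan_interval_s: float
    bin_size_m: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("frame matrix must be 2-D with at least one scan and one bin")
        if not np.all(np.isfinite(values)):
            raise ValueError("frame matrix entries must be finite")
        object.__setattr__(self, "values", values)

    @property
    def m_scans(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.values.shape[1])

    def scan_times(self) -> np.ndarray:
        return np.arange(self.m_scans) * self.scan_interval_s


@dataclass(frozen=True)
class GroundTruth:
    """Per-scan truth for a simulated session.

    ``bins[m]`` is the range bin of the nearest scatterer at scan ``m`` and
    ``amplitudes[m]`` its reflectivity; ``speech_interval_s`` is the
    configured articulation interval, if any.
    """

    bins: np.ndarray
    amplitudes: np.ndarray
    speech_interval_s: tuple[float, float] | None


def _wander_phase(scene: SceneSpec) -> float:
    """Session-level baseline-wander phase, deterministic in the scene seed."""
    return float(np.random.default_rng([scene.seed, 999_983]).uniform())


def _wander_value(scene: SceneSpec, t: float, phase: float) -> float:
    if scene.wander_amplitude == 0.0:
        return 0.0
    frac = (t / scene.wander_period_s + phase) % 1.0
    return scene.wander_amplitude * (4.0 * abs(frac - 0.5) - 1.0)


def _scatterers_at(scene: SceneSpec, t: float) -> list[tuple[float, float, str]]:
    """(range_m, reflectivity, kind) for every scatterer at slow time t."""
    out = [(r, a, "static") for r, a in scene.static_reflectors]
    out.extend(
        (float(tg.trajectory(t)), float(tg.reflectivity(t)), f"target[{i}]")
        for i, tg in enumerate(scene.targets)
    )
    return out


def simulate_scan(
    scene: SceneSpec, template: PulseTemplate, scan_index: int
) -> np.ndarray:
    """Synthesize the received signal of a single scan (length ``n_bins``).

    Deterministic given the scene (including its seed) and ``scan_index``:
    the same scan simulated twice is bit-identical.
    """
    if not 0 <= scan_index < scene.m_scans:
        raise ValueError(
            f"scan_index {scan_index} outside session of {scene.m_scans} scans"
        )
    t = scan_index * scene.scan_interval_s
    n_bins = scene.n_bins
    max_range = n_bins * scene.bin_size_m
    y = np.zeros(n_bins)
    v = template.samples
    for rng_m, amp, kind in _scatterers_at(scene, t):
        if not 0.0 <= rng_m < max_range:
            raise ValueError(
                f"{kind} at {rng_m:.4f} m is outside the unambiguous range "
                f"[0, {max_range:.3f}) m at t = {t:.3f} s"
            )
        if amp < 0:
            raise ValueError(f"{kind} has negative reflectivity {amp} at t = {t:.3f} s")
        start = int(round(rng_m / scene.bin_size_m))
        stop = min(start + v.size, n_bins)
        y[start:stop] += amp * v[: stop - start]
    if scene.coupling_amplitude:
        stop = min(v.size, n_bins)
        y[:stop] += scene.coupling_amplitude * v[:stop]
    y += _wander_value(scene, t, _wander_phase(scene))
    if scene.noise_sd > 0:
        rng = np.random.default_rng([scene.seed, scan_index])
        y += rng.normal(0.0, scene.noise_sd, n_bins)
    return y


def simulate_session(
    scene: SceneSpec, template: PulseTemplate
) -> tuple[RadarFrameMatrix, GroundTruth]:
    """Simulate every scan of a session and its ground truth.

    Returns ``floor(duration_s / scan_interval_s)`` scans.  Ground truth
    records, per scan, the bin and reflectivity of the nearest scatterer
    (moving targets take precedence over statics when present), plus the
    configured speech interval.
    """
    m_scans = scene.m_scans
    phase = _wander_phase(scene)
    n_bins = scene.n_bins
    max_range = n_bins * scene.bin_size_m
    v = template.samples

    values = np.zeros((m_scans, n_bins))
    truth_bins = np.zeros(m_scans, dtype=int)
    truth_amp = np.zeros(m_scans)

    for m in range(m_scans):
        t = m * scene.scan_interval_s
        y = values[m]
        scatterers = _scatterers_at(scene, t)
        for rng_m, amp, kind in scatterers:
            if not 0.0 <= rng_m < max_range:
                raise ValueError(
                    f"{kind} at {rng_m:.4f} m is outside the unambiguous range "
                    f"[0, {max_range:.3f}) m at t = {t:.3f} s"
                )
            if amp < 0:
                raise ValueError(
                    f"{kind} has negative reflectivity {amp} at t = {t:.3f} s"
                )
            start = int(round(rng_m / scene.bin_size_m))
            stop = min(start + v.size, n_bins)
            y[start:stop] += amp * v[: stop - start]
        if scene.coupling_amplitude:
            stop = min(v.size, n_bins)
            y[:stop] += scene.coupling_amplitude * v[:stop]
        y += _wander_value(scene, t, phase)
        if scene.noise_sd > 0:
            rng = np.random.default_rng([scene.seed, m])
            y += rng.normal(0.0, scene.noise_sd, n_bins)

        moving = [(r, a) for r, a, k in scatterers if k.startswith("target")]
        pool = moving if moving else [(r, a) for r, a, _ in scatterers]
        if pool:
            nearest = min(pool, key=lambda ra: ra[0])
            truth_bins[m] = int(round(nearest[0] / scene.bin_size_m))
            truth_amp[m] = nearest[1]

    frame = RadarFrameMatrix(
        values, scan_interval_s=scene.scan_interval_s, bin_size_m=scene.bin_size_m
    )
    truth = GroundTruth(
        bins=truth_bins, amplitudes=truth_amp, speech_interval_s=scene.speech_interval_s
    )
    return frame, truth
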