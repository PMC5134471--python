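"""Synthetic radar scenes: moving articulator targets, statics, noise.

A :class:`SceneSpec` describes everything in front of the simulated radar:
point targets with time-varying range and reflectivity (the articulators),
fixed reflectors (room clutter and the parts of the face that do not move),
antenna coupling, receiver noise and a slow baseline wander.  Word profiles
encode the two articulation phenomenologies the radar distinguishes: a
range dip with an amplitude drop (lips pushing toward the radar, as for
"two") and a flat range with a slight amplitude rise (jaw dropping
perpendicular to the boresight, as for "five").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .pulse import DEFAULT_BIN_SIZE_M

__all__ = [
    "PointTarget",
    "SceneSpec",
    "word_trajectory",
    "word_scene",
    "static_scene",
    "default_vocabulary",
]

Trajectory = Callable[[float], float]

# nominal articulation geometry: lips at rest ~13.2 cm from the antenna,
# within the 10-16 cm operating distance
REST_RANGE_M = 0.132
REST_REFLECTIVITY = 5.0
# immobile face/jaw echo slightly behind the lips: overlaps the lip echo
# (separation < pulse length) but is weaker, as for a real face
FACE_RANGE_M = 0.190
FACE_REFLECTIVITY = 2.5
ROOM_RANGE_M = 0.450
ROOM_REFLECTIVITY = 6.0


@dataclass(frozen=True)
class PointTarget:
    """A moving point scatterer: range and reflectivity as functions of time (s)."""

    trajectory: Trajectory
    reflectivity: Trajectory


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a simulated radar session.

    Ranges are metres, times seconds, reflectivities arbitrary amplitude
    units.  ``noise_sd`` is the per-sample sd of additive white Gaussian
    receiver noise; ``wander_amplitude``/``wander_period_s`` parameterize a
    bounded triangular slow-time baseline drift common to all range bins
    (thermal/DC wander of the receiver chain).
    """

    targets: tuple[PointTarget, ...] = ()
    static_reflectors: tuple[tuple[float, float], ...] = ()
    coupling_amplitude: float = 3.0
    noise_sd: float = 0.003
    wander_amplitude: float = 0.08
    wander_period_s: float = 0.6
    seed: int = 0
    duration_s: float = 2.0
    scan_interval_s: float = 0.01
    n_bins: int = 256
    bin_size_m: float = DEFAULT_BIN_SIZE_M
    speech_interval_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.scan_interval_s <= 0:
            raise ValueError("scan_interval_s must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        max_range = self.n_bins * self.bin_size_m
        for rng_m, _ in self.static_reflectors:
            if not 0.0 <= rng_m < max_range:
                raise ValueError(
                    f"static reflector at {rng_m} m outside unambiguous range "
                    f"[0, {max_range}) m"
                )

    @property
    def m_scans(self) -> int:
        return int(np.floor(self.duration_s / self.scan_interval_s))

    def background(self, duration_s: float = 1.2, seed: int | None = None) -> "SceneSpec":
        """The same scene with every moving target removed.

        Emulates the empty-room capture used to estimate the clutter
        background (the statics, coupling and noise remain).
        """
        return replace(
            self,
            targets=(),
            duration_s=duration_s,
            seed=self.seed + 10_007 if seed is None else seed,
            speech_interval_s=None,
        )


def _ramp(t: float, start: float, rise: float) -> float:
    """Piecewise-linear 0->1 ramp beginning at ``start`` over ``rise`` seconds."""
    if rise <= 0:
        return 1.0 if t >= start else 0.0
    return float(np.clip((t - start) / rise, 0.0, 1.0))


def _bump(t: float, start: float, end: float, rise: float, fall: float) -> float:
    """0->1->0 activation supported on [start, end], linear edges."""
    if t <= start or t >= end:
        return 0.0
    up = (t - start) / rise if rise > 0 else 1.0
    down = (end - t) / fall if fall > 0 else 1.0
    return float(min(1.0, up, down))


def word_trajectory(
    profile_name: str,
    *,
    rest_range_m: float = REST_RANGE_M,
    rest_reflectivity: float = REST_REFLECTIVITY,
    speech_interval_s: tuple[float, float] = (0.5, 1.2),
    excursion_m: float = 0.02,
    amplitude_change: float = -0.3,
    rise_s: float = 0.15,
    knots: Sequence[tuple[float, float, float]] | None = None,
) -> PointTarget:
    """Build (range, reflectivity) functions of time for a word profile.

    Profiles
    --------
    ``two_like``
        Range decreases by ``excursion_m`` during the speech interval and
        returns; reflectivity dips by ``|amplitude_change|`` (lips forward).
    ``five_like``
        Range constant; reflectivity rises by ``amplitude_change``
        (default interpreted as +0.3 when the profile is five_like and the
        caller leaves the default -0.3 unchanged).
    ``custom``
        Piecewise-linear ``knots``: (time_s, range_offset_m,
        reflectivity_factor_offset) interpolated linearly, zero outside the
        knot span.

    Outside the speech interval both built-in profiles return exactly the
    rest range and rest reflectivity.
    """
    t0, t1 = speech_interval_s
    if t1 <= t0:
        raise ValueError("speech interval must have positive length")

    if profile_name == "two_like":
        amp_change = amplitude_change

        def trajectory(t: float) -> float:
            return rest_range_m - excursion_m * _bump(t, t0, t1, rise_s, rise_s)

        def reflectivity(t: float) -> float:
            return rest_reflectivity * (1.0 + amp_change * _bump(t, t0, t1, rise_s, rise_s))

    elif profile_name == "five_like":
        amp_change = abs(amplitude_change)

        def trajectory(t: float) -> float:  # noqa: ARG001 - range is flat by definition
            return rest_range_m

        def reflectivity(t: float) -> float:
            return rest_reflectivity * (1.0 + amp_change * _bump(t, t0, t1, rise_s, rise_s))

    elif profile_name == "custom":
        if not knots:
            raise ValueError("custom profile requires knots")
        times = np.array([k[0] for k in knots])
        dranges = np.array([k[1] for k in knots])
        damps = np.array([k[2] for k in knots])
        if np.any(np.diff(times) <= 0):
            raise ValueError("knot times must be strictly increasing")

        def trajectory(t: float) -> float:
            return rest_range_m + float(np.interp(t, times, dranges, left=0.0, right=0.0))

        def reflectivity(t: float) -> float:
            return rest_reflectivity * (
                1.0 + float(np.interp(t, times, damps, left=0.0, right=0.0))
            )

    else:
        raise ValueError(
            f"unknown profile {profile_name!r}; expected 'two_like', 'five_like' or 'custom'"
        )

    return PointTarget(trajectory=trajectory, reflectivity=reflectivity)


def _base_statics() -> tuple[tuple[float, float], ...]:
    return ((FACE_RANGE_M, FACE_REFLECTIVITY), (ROOM_RANGE_M, ROOM_REFLECTIVITY))


def static_scene(seed: int = 0, duration_s: float = 2.0) -> SceneSpec:
    """A no-articulation scene: statics, coupling, noise and wander only."""
    return SceneSpec(
        targets=(),
        static_reflectors=_base_statics(),
        seed=seed,
        duration_s=duration_s,
    )


def word_scene(
    profile_name: str,
    seed: int = 0,
    *,
    duration_s: float = 2.0,
    speech_interval_s: tuple[float, float] = (0.5, 1.2),
    **profile_kwargs,
) -> SceneSpec:
    """A one-word articulation scene over the standard face/room statics."""
    target = word_trajectory(
        profile_name, speech_interval_s=speech_interval_s, **profile_kwargs
    )
    return SceneSpec(
        targets=(target,),
        static_reflectors=_base_statics(),
        seed=seed,
        duration_s=duration_s,
        speech_interval_s=speech_interval_s,
    )


# Five-word synthetic vocabulary with distinct (range, amplitude) signatures.
# Each entry: label -> custom knot builder given jittered timing/scale.
def _vocab_knots(label: str, t0: float, dur: float, scale: float):
    """Knots (time, range offset m, reflectivity factor offset) per word."""
    t1 = t0 + dur
    mid = t0 + dur / 2.0
    if label == "push":  # strong forward dip, amplitude drop ("two"-like)
        return [
            (t0, 0.0, 0.0),
            (t0 + 0.25 * dur, -0.020 * scale, -0.30 * scale),
            (t1 - 0.25 * dur, -0.020 * scale, -0.30 * scale),
            (t1, 0.0, 0.0),
        ]
    if label == "drop":  # flat range, amplitude rise ("five"-like)
        return [
            (t0, 0.0, 0.0),
            (t0 + 0.2 * dur, 0.0, 0.30 * scale),
            (t1 - 0.2 * dur, 0.0, 0.30 * scale),
            (t1, 0.0, 0.0),
        ]
    if label == "pull":  # backward excursion with mild amplitude rise
        return [
            (t0, 0.0, 0.0),
            (t0 + 0.3 * dur, 0.016 * scale, 0.15 * scale),
            (t1 - 0.3 * dur, 0.016 * scale, 0.15 * scale),
            (t1, 0.0, 0.0),
        ]
    if label == "tap":  # two short forward taps
        return [
            (t0, 0.0, 0.0),
            (t0 + 0.2 * dur, -0.012 * scale, -0.18 * scale),
            (mid, 0.0, 0.0),
            (t1 - 0.2 * dur, -0.012 * scale, -0.18 * scale),
            (t1, 0.0, 0.0),
        ]
    if label == "slide":  # slow shallow approach with deep amplitude fade
        return [
            (t0, 0.0, 0.0),
            (mid, -0.010 * scale, -0.45 * scale),
            (t1, 0.0, 0.0),
        ]
    raise ValueError(f"unknown vocabulary label {label!r}")


VOCABULARY_LABELS = ("push", "drop", "pull", "tap", "slide")


def default_vocabulary(
    seed: int,
    repetitions: int = 20,
    labels: Sequence[str] = VOCABULARY_LABELS,
) -> list[tuple[str, SceneSpec]]:
    """Seeded (label, scene) pairs for a word-recognition experiment.

    Each repetition jitters the articulation onset (+-0.1 s), duration
    (x0.85-1.15) and excursion/amplitude scale (x0.9-1.1) so repetitions of
    a word differ in length and detail, as real utterances do.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, SceneSpec]] = []
    for rep in range(repetitions):
        for label in labels:
            t0 = 0.55 + rng.uniform(-0.08, 0.08)
            dur = 0.7 * rng.uniform(0.85, 1.15)
            scale = rng.uniform(0.9, 1.1)
            scene_seed = int(rng.integers(0, 2**31 - 1))
            target = word_trajectory(
                "custom",
                speech_interval_s=(t0, t0 + dur),
                knots=_vocab_knots(label, t0, dur, scale),
            )
            out.append(
                (
                    label,
                    SceneSpec(
                        targets=(target,),
                        static_reflectors=_base_statics(),
                        seed=scene_seed,
                        duration_s=2.0,
                        speech_interval_s=(t0, t0 + dur),
                    ),
                )
            )
    return out
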