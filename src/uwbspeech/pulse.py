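"""Transmitted-pulse templates for IR-UWB matched-filter (CLEAN) detection.

The radar transmits a short zero-mean pulse; echoes are delayed, scaled
copies of it.  Target detection correlates the received scan with a sampled
copy of the transmitted pulse (the CLEAN template ``v[n]``), or — for the
short-template variant — with a copy whose trailing 75% is zeroed
(``v_s[n]``), so that only the leading edge of the nearest echo is matched.

The default template is an asymmetric monocycle: a sharp positive half-sine
lobe over the leading quarter of the pulse, balanced by a shallow negative
recovery lobe over the remaining three quarters.  This shape is chosen so
that the leading-quarter window is everywhere nonnegative and the tail
everywhere nonpositive; the short-template correlation with any later,
overlapping echo is then never *increased* by the first echo's tail, which
is exactly the property the nearest-target detector relies on.  Multi-cycle
Hann-windowed sinusoids are available through ``cycles >= 2`` for
experimentation; they do not carry that guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PulseTemplate", "make_pulse_template", "make_short_template"]

#: fast-time range-bin size in metres (4 mm range resolution)
DEFAULT_BIN_SIZE_M = 0.004


@dataclass(frozen=True)
class PulseTemplate:
    """Sampled transmitted pulse.

    Parameters
    ----------
    samples
        Pulse amplitudes (arbitrary units), unit peak magnitude.
    bin_size_m
        Range extent of one fast-time sample, metres.
    """

    samples: np.ndarray
    bin_size_m: float = DEFAULT_BIN_SIZE_M

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 4:
            raise ValueError("pulse template needs a 1-D vector of >= 4 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("pulse template samples must be finite")
        if np.max(np.abs(samples)) == 0.0:
            raise ValueError("pulse template must not be identically zero")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def length_bins(self) -> int:
        return int(self.samples.size)

    @property
    def energy(self) -> float:
        """Sum of squared samples; the matched-filter normalizer."""
        return float(self.samples @ self.samples)

    @property
    def length_m(self) -> float:
        return self.length_bins * self.bin_size_m


def make_pulse_template(
    length_bins: int = 24,
    cycles: int = 1,
    envelope_width: float = 0.25,
    bin_size_m: float = DEFAULT_BIN_SIZE_M,
) -> PulseTemplate:
    """Construct a zero-mean oscillatory pulse with unit peak amplitude.

    With ``cycles == 1`` (default) the pulse is an asymmetric monocycle whose
    positive lobe spans the leading ``envelope_width`` fraction of the pulse
    and whose negative recovery lobe spans the remainder, scaled so the
    samples sum exactly to zero.  With ``cycles >= 2`` a Hann-windowed
    sinusoid is returned (mean-subtracted).

    Parameters
    ----------
    length_bins
        Number of fast-time samples, >= 8.
    cycles
        Number of oscillation cycles; 1 selects the monocycle.
    envelope_width
        Monocycle only: fraction of the pulse occupied by the leading
        positive lobe (0 < envelope_width < 1).  The default 0.25 aligns the
        lobe with the short-template window.
    """
    if length_bins < 8:
        raise ValueError(f"length_bins must be >= 8, got {length_bins}")
    if cycles < 1:
        raise ValueError(f"cycles must be >= 1, got {cycles}")
    if not 0.0 < envelope_width < 1.0:
        raise ValueError(f"envelope_width must lie in (0, 1), got {envelope_width}")

    n = np.arange(length_bins)
    if cycles == 1:
        q = int(round(length_bins * envelope_width))
        q = min(max(q, 2), length_bins - 2)
        v = np.empty(length_bins)
        # half-sine lobes sampled at bin centres: strictly positive front,
        # strictly negative tail, areas balanced for an exactly zero mean
        v[:q] = np.sin(np.pi * (np.arange(q) + 0.5) / q)
        tail = np.sin(np.pi * (np.arange(length_bins - q) + 0.5) / (length_bins - q))
        v[q:] = -tail * (v[:q].sum() / tail.sum())
    else:
        window = np.hanning(length_bins)
        v = window * np.sin(2.0 * np.pi * cycles * (n + 0.5) / length_bins)
        v -= v.mean()
    v /= np.max(np.abs(v))
    return PulseTemplate(v, bin_size_m=bin_size_m)


def make_short_template(template: PulseTemplate, keep_fraction: float = 0.25) -> PulseTemplate:
    """Zero the trailing part of a template, keeping the leading fraction.

    The short template keeps the first ``floor(keep_fraction * L)`` samples
    and zeroes the rest; its length is unchanged, so detections from the two
    templates share the same lag convention.

    Parameters
    ----------
    template
        Full CLEAN template.
    keep_fraction
        Fraction of leading samples kept, in (0, 1); 0.25 keeps the front
        quarter.
    """
    if not 0.0 < keep_fraction < 1.0:
        raise ValueError(f"keep_fraction must lie in (0, 1), got {keep_fraction}")
    keep = int(np.floor(keep_fraction * template.length_bins))
    if keep < 1:
        raise ValueError(
            f"keep_fraction {keep_fraction} keeps no samples of a "
            f"{template.length_bins}-bin template"
        )
    samples = np.array(template.samples, dtype=float)
    samples[keep:] = 0.0
    if np.max(np.abs(samples)) == 0.0:
        raise ValueError("short template is identically zero; pulse front is empty")
    return PulseTemplate(samples, bin_size_m=template.bin_size_m)
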