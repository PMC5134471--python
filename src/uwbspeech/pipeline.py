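"""End-to-end processing chain: raw frames to a recognized word.

Mirrors the signal-flow of the system: clutter reduction, CLEAN target
detection, general-motion segmentation, articulator confirmation, feature
extraction and nearest-template classification.  Every stage's parameters
and decisions are collected into a report for auditability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .activity import (
    SpeechSegment,
    confirm_articulator_motion,
    detect_general_motion,
    motion_trace,
    rest_distance,
)
from .clean import CleanMap, build_clean_map
from .clutter import BackgroundModel, estimate_background, reduce_clutter
from .config import PipelineConfig
from .pulse import PulseTemplate, make_pulse_template, make_short_template
from .recognize import FeatureMatrix, classify
from .simulate import RadarFrameMatrix

__all__ = ["PipelineReport", "SegmentResult", "run_pipeline"]

log = logging.getLogger("uwbspeech")


@dataclass(frozen=True)
class SegmentResult:
    segment: SpeechSegment
    rest_bin: int
    confirmed: bool
    features: FeatureMatrix | None
    label: str | None


@dataclass(frozen=True)
class PipelineReport:
    config: PipelineConfig
    n_scans: int
    segments: tuple[SegmentResult, ...]

    @property
    def recognized_labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.segments if r.label is not None)

    def summary(self) -> str:
        if not self.segments:
            return "no speech segments"
        lines = []
        for i, res in enumerate(self.segments):
            seg = res.segment
            status = res.label if res.confirmed else "discarded (gate)"
            lines.append(
                f"segment {i}: raw {seg.raw_start_s:.2f}-{seg.raw_end_s:.2f} s, "
                f"stored {seg.start_s:.2f}-{seg.end_s:.2f} s, "
                f"rest bin {res.rest_bin} -> {status}"
            )
        return "\n".join(lines)


def default_template(config: PipelineConfig) -> PulseTemplate:
    return make_pulse_template(config.template_bins, bin_size_m=config.bin_size_m)


def run_pipeline(
    config: PipelineConfig,
    session: RadarFrameMatrix,
    background_session: RadarFrameMatrix,
    library: Sequence[FeatureMatrix] | None = None,
    template: PulseTemplate | None = None,
) -> PipelineReport:
    """Process one session against a background capture and template library.

    Stages: estimate background -> reduce clutter -> build clean map ->
    detect general motion -> confirm articulator motion -> extract features
    -> classify (when a library is given).  Unconfirmed segments carry no
    features or label.  Deterministic for fixed inputs and config.
    """
    from .recognize import extract_features  # local import to avoid cycle at module load

    log.info("pipeline config: %s", config)
    background = _stage("estimate_background", estimate_background,
                        background_session, config.m_b)
    reduced = _stage("reduce_clutter", reduce_clutter, session, background)

    template = template or default_template(config)
    detect_template = (
        template
        if config.detector == "conventional"
        else make_short_template(template, config.keep_fraction)
    )
    clean_map = _stage(
        "build_clean_map",
        build_clean_map,
        reduced,
        detect_template,
        config.detector,
        config.t_stop,
        config.max_iter,
    )

    trace = _stage("motion_trace", motion_trace, reduced, config.alpha)
    segments = _stage(
        "detect_general_motion",
        detect_general_motion,
        trace,
        config.motion_threshold,
        config.end_gap_s,
        config.pre_margin_s,
        config.post_margin_s,
    )

    results: list[SegmentResult] = []
    for seg in segments:
        rest_bin = rest_distance(clean_map, seg, config.rest_window_s)
        confirmed = confirm_articulator_motion(
            clean_map, seg, rest_bin, config.gate_lo_m, config.gate_hi_m
        )
        log.info(
            "segment raw %.2f-%.2f s stored %.2f-%.2f s rest bin %d confirmed %s",
            seg.raw_start_s, seg.raw_end_s, seg.start_s, seg.end_s, rest_bin, confirmed,
        )
        seg = SpeechSegment(
            raw_start_s=seg.raw_start_s,
            raw_end_s=seg.raw_end_s,
            start_s=seg.start_s,
            end_s=seg.end_s,
            confirmed=confirmed,
        )
        features = None
        label = None
        if confirmed:
            features = extract_features(clean_map, seg)
            if library:
                label = classify(features, library)
        results.append(
            SegmentResult(
                segment=seg,
                rest_bin=rest_bin,
                confirmed=confirmed,
                features=features,
                label=label,
            )
        )
    return PipelineReport(config=config, n_scans=session.m_scans,
                          segments=tuple(results))


def _stage(name, func, *args):
    try:
        return func(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
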