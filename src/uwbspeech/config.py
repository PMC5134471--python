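"""Pipeline configuration: every stage parameter with its standard default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the processing chain.

    Defaults are the operating constants of the reference system: 100-scan
    background average, stop threshold 2.0, front-quarter short template,
    EMA constant 0.1, motion threshold 1e-5, 0.4 s end gap, 0.2/0.1 s
    storage margins, −4/+3 cm articulator gate, 0.01 s scan interval, 4 mm
    bins, 256 bins per scan.
    """

    m_b: int = 100
    t_stop: float = 2.0
    max_iter: int = 50
    keep_fraction: float = 0.25
    alpha: float = 0.1
    motion_threshold: float = 1e-5
    end_gap_s: float = 0.4
    pre_margin_s: float = 0.2
    post_margin_s: float = 0.1
    gate_lo_m: float = -0.04
    gate_hi_m: float = 0.03
    rest_window_s: float = 0.5
    scan_interval_s: float = 0.01
    bin_size_m: float = 0.004
    n_bins: int = 256
    template_bins: int = 24
    detector: str = "short_template"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.m_b >= 1, "m_b must be >= 1"),
            (self.t_stop > 0, "t_stop must be positive"),
            (self.max_iter >= 1, "max_iter must be >= 1"),
            (0 < self.keep_fraction < 1, "keep_fraction must lie in (0, 1)"),
            (0 < self.alpha <= 1, "alpha must lie in (0, 1]"),
            (self.motion_threshold > 0, "motion_threshold must be positive"),
            (self.end_gap_s > 0, "end_gap_s must be positive"),
            (self.pre_margin_s >= 0, "pre_margin_s must be >= 0"),
            (self.post_margin_s >= 0, "post_margin_s must be >= 0"),
            (self.gate_lo_m < self.gate_hi_m, "gate_lo_m must be < gate_hi_m"),
            (self.rest_window_s > 0, "rest_window_s must be positive"),
            (self.scan_interval_s > 0, "scan_interval_s must be positive"),
            (self.bin_size_m > 0, "bin_size_m must be positive"),
            (self.n_bins >= 1, "n_bins must be >= 1"),
            (self.template_bins >= 8, "template_bins must be >= 8"),
            (
                self.detector in ("conventional", "short_template"),
                "detector must be 'conventional' or 'short_template'",
            ),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
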