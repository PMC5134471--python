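"""File formats: delimited-text matrices with JSON sidecar metadata.

A session is stored as a whitespace-delimited numeric matrix (one scan per
row) plus a ``<name>.meta.json`` sidecar carrying ``scan_interval_s``,
``bin_size_m`` and ``n_bins``; the sidecar is authoritative and a mismatch
with the matrix shape is a format error.  Clean maps, segments and
confusion/metric tables are tab-separated tables; template libraries are a
directory of feature files with a manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import SpeechSegment
from .clean import CleanDetection, CleanMap
from .clutter import BackgroundModel
from .recognize import ConfusionMatrix, FeatureMatrix, Metrics, round_half_up
from .simulate import RadarFrameMatrix

__all__ = [
    "write_session",
    "read_session",
    "write_background",
    "read_background",
    "write_clean_map",
    "read_clean_map",
    "write_segments",
    "read_segments",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_library",
    "read_library",
    "write_confusion",
    "read_confusion",
    "write_metrics",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_session(path, session: RadarFrameMatrix) -> None:
    path = Path(path)
    np.savetxt(path, session.values, fmt="%.17g")
    meta = {
        "scan_interval_s": session.scan_interval_s,
        "bin_size_m": session.bin_size_m,
        "n_bins": session.n_bins,
        "m_scans": session.m_scans,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_session(path) -> RadarFrameMatrix:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("scan_interval_s", "bin_size_m", "n_bins"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required field {key!r}")
    try:
        values = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"cannot parse session matrix {path}: {exc}") from exc
    if values.shape[1] != meta["n_bins"]:
        raise ValueError(
            f"sidecar declares n_bins={meta['n_bins']} but matrix has "
            f"{values.shape[1]} columns"
        )
    if "m_scans" in meta and values.shape[0] != meta["m_scans"]:
        raise ValueError(
            f"sidecar declares m_scans={meta['m_scans']} but matrix has "
            f"{values.shape[0]} rows"
        )
    return RadarFrameMatrix(
        values=values,
        scan_interval_s=float(meta["scan_interval_s"]),
        bin_size_m=float(meta["bin_size_m"]),
    )


def write_background(path, background: BackgroundModel) -> None:
    path = Path(path)
    np.savetxt(path, background.mean_row[None, :], fmt="%.17g")
    _sidecar(path).write_text(
        json.dumps({"m_scans_used": background.m_scans_used}, indent=1)
    )


def read_background(path) -> BackgroundModel:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    mean_row = np.loadtxt(path, ndmin=2)[0]
    return BackgroundModel(mean_row=mean_row, m_scans_used=int(meta["m_scans_used"]))


def write_clean_map(path, clean_map: CleanMap) -> None:
    records = []
    for m, scan in enumerate(clean_map.detections):
        for det in scan:
            records.append(
                {
                    "scan_index": m,
                    "bin": det.bin,
                    "amplitude": det.amplitude,
                    "detector_tag": clean_map.detector_tag,
                }
            )
    frame = pd.DataFrame.from_records(
        records, columns=["scan_index", "bin", "amplitude", "detector_tag"]
    )
    frame.to_csv(path, sep="\t", index=False)
    _sidecar(Path(path)).write_text(
        json.dumps(
            {
                "n_scans": clean_map.n_scans,
                "scan_interval_s": clean_map.scan_interval_s,
                "bin_size_m": clean_map.bin_size_m,
                "detector_tag": clean_map.detector_tag,
            },
            indent=1,
        )
    )


def read_clean_map(path) -> CleanMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    frame = pd.read_csv(path, sep="\t")
    rows: list[list[CleanDetection]] = [[] for _ in range(int(meta["n_scans"]))]
    for rec in frame.itertuples(index=False):
        rows[int(rec.scan_index)].append(
            CleanDetection(bin=int(rec.bin), amplitude=float(rec.amplitude))
        )
    return CleanMap(
        detections=tuple(tuple(r) for r in rows),
        detector_tag=str(meta["detector_tag"]),
        scan_interval_s=float(meta["scan_interval_s"]),
        bin_size_m=float(meta["bin_size_m"]),
    )


_SEGMENT_COLUMNS = ["segment_id", "raw_start_s", "raw_end_s", "start_s", "end_s", "confirmed"]


def write_segments(path, segments: Sequence[SpeechSegment]) -> None:
    frame = pd.DataFrame.from_records(
        [
            {
                "segment_id": i,
                "raw_start_s": round(s.raw_start_s, 2),
                "raw_end_s": round(s.raw_end_s, 2),
                "start_s": round(s.start_s, 2),
                "end_s": round(s.end_s, 2),
                "confirmed": s.confirmed,
            }
            for i, s in enumerate(segments)
        ],
        columns=_SEGMENT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[SpeechSegment]:
    frame = pd.read_csv(path, sep="\t")
    return [
        SpeechSegment(
            raw_start_s=float(r.raw_start_s),
            raw_end_s=float(r.raw_end_s),
            start_s=float(r.start_s),
            end_s=float(r.end_s),
            confirmed=bool(r.confirmed),
        )
        for r in frame.itertuples(index=False)
    ]


def write_feature_matrix(path, features: FeatureMatrix) -> None:
    frame = pd.DataFrame(features.rows, columns=["distance_bin", "amplitude"])
    frame.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path, label: str | None = None, speaker: str | None = None) -> FeatureMatrix:
    frame = pd.read_csv(path, sep="\t")
    return FeatureMatrix(rows=frame.to_numpy(dtype=float), label=label, speaker=speaker)


def write_library(directory, samples: Sequence[FeatureMatrix]) -> None:
    """Write labeled feature matrices plus a manifest into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, sample in enumerate(samples):
        name = f"sample_{i:04d}.tsv"
        write_feature_matrix(directory / name, sample)
        manifest.append(
            {"file": name, "label": sample.label, "speaker": sample.speaker or ""}
        )
    pd.DataFrame.from_records(manifest, columns=["file", "label", "speaker"]).to_csv(
        directory / "manifest.tsv", sep="\t", index=False
    )


def read_library(directory) -> list[FeatureMatrix]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t", keep_default_na=False)
    out = []
    for rec in manifest.itertuples(index=False):
        out.append(
            read_feature_matrix(
                directory / rec.file,
                label=str(rec.label),
                speaker=str(rec.speaker) or None,
            )
        )
    return out


def write_confusion(path, confusion: ConfusionMatrix, percent: bool = True) -> None:
    confusion.to_dataframe(percent=percent).to_csv(path, sep="\t")


def read_confusion(path) -> ConfusionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    counts = frame.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("confusion table must contain integer counts")
    return ConfusionMatrix(
        counts=counts.astype(int), labels=tuple(str(c) for c in frame.columns)
    )


def write_metrics(path, metrics: Metrics, decimals: int = 3) -> None:
    frame = metrics.to_dataframe().map(lambda v: round_half_up(v, decimals))
    frame["f_measure"] = ""
    frame.loc["macro", "f_measure"] = round_half_up(metrics.f_measure, decimals)
    frame.to_csv(path, sep="\t")
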