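"""MD-DTW template matching, nearest-template classification, evaluation.

A confirmed speech segment yields a two-column feature matrix: per scan,
the detected range bin (lip position) and the correlation amplitude (lip
and jaw shape).  Words are recognized by multi-dimensional dynamic time
warping — the local cost between feature rows is the sum of absolute
per-column differences — against a library of labeled templates, taking
the label of the closest match.  Evaluation is leave-one-out (jackknife):
every sample is classified against all remaining samples and the decisions
accumulate into a confusion matrix from which precision, recall and the
F-measure are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from ._dtw import dtw_cost
from .activity import SpeechSegment
from .clean import CleanMap

__all__ = [
    "FeatureMatrix",
    "ConfusionMatrix",
    "Metrics",
    "extract_features",
    "mddtw_distance",
    "classify",
    "jackknife_evaluate",
    "precision_recall_f",
    "round_half_up",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-epoch (distance bin, correlation amplitude) rows for one segment."""

    rows: np.ndarray
    label: str | None = None
    speaker: str | None = None

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != 2 or rows.shape[0] < 1:
            raise ValueError("feature matrix must have shape (>=1, 2)")
        if not np.all(np.isfinite(rows)):
            raise ValueError("feature matrix entries must be finite")
        object.__setattr__(self, "rows", rows)

    @property
    def n_epochs(self) -> int:
        return int(self.rows.shape[0])


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[true, predicted] with row sums equal to per-class sample counts."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} to match labels")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    def to_dataframe(self, percent: bool = False) -> pd.DataFrame:
        data = self.counts.astype(float)
        if percent:
            sums = data.sum(axis=1, keepdims=True)
            sums[sums == 0] = 1.0
            data = 100.0 * data / sums
        return pd.DataFrame(data if percent else self.counts,
                            index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class Metrics:
    """Per-class and macro-averaged precision/recall plus the F-measure.

    The F-measure is the harmonic mean of the macro-averaged precision and
    recall (this convention reproduces printed three-decimal summaries of
    the form P=0.946, R=0.940, F=0.943).
    """

    labels: tuple[str, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    macro_precision: float
    macro_recall: float
    f_measure: float
    undefined_precision: tuple[str, ...] = ()
    undefined_recall: tuple[str, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": list(self.precision) + [self.macro_precision],
                "recall": list(self.recall) + [self.macro_recall],
            },
            index=list(self.labels) + ["macro"],
        )


def round_half_up(value: float, decimals: int = 3) -> float:
    """Half-up decimal rounding, matching printed-table conventions."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def extract_features(clean_map: CleanMap, segment: SpeechSegment) -> FeatureMatrix:
    """One feature row per scan inside the stored window.

    Scans with times in ``[start_s, end_s]`` (both ends inclusive)
    contribute their primary detection: the sole detection for
    short-template maps, the maximum-amplitude detection for conventional
    maps.  Scans without any detection are skipped.
    """
    times, bins, amps = clean_map.primary_arrays()
    mask = (times >= segment.start_s) & (times <= segment.end_s)
    if not np.any(mask):
        raise ValueError(
            f"no detections inside segment [{segment.start_s}, {segment.end_s}] s"
        )
    rows = np.column_stack([bins[mask].astype(float), amps[mask]])
    return FeatureMatrix(rows=rows)


def mddtw_distance(f_temp: FeatureMatrix, f_test: FeatureMatrix) -> float:
    """Minimal cumulative alignment cost between two feature matrices.

    Local cost between epoch ``i`` of the template and epoch ``j`` of the
    test sample is ``sum_k |F_temp[i,k] - F_test[j,k]|``; the warping path
    is monotone with steps {(1,0), (0,1), (1,1)}, anchored at both ends,
    with no window constraint and no path-length normalization.
    """
    return dtw_cost(f_temp.rows, f_test.rows)


def classify(
    f_test: FeatureMatrix, library: Sequence[FeatureMatrix]
) -> str:
    """Label of the library template closest in MD-DTW distance.

    Ties resolve deterministically: smallest distance, then lexicographic
    label order, then library position.
    """
    if not library:
        raise ValueError("template library is empty")
    best: tuple[float, str, int] | None = None
    for idx, entry in enumerate(library):
        if entry.label is None:
            raise ValueError(f"library entry {idx} has no label")
        key = (mddtw_distance(entry, f_test), entry.label, idx)
        if best is None or key < best:
            best = key
    return best[1]


def jackknife_evaluate(
    samples: Sequence[FeatureMatrix],
    group_by_speaker: bool = False,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation over a labeled sample collection.

    Each sample is classified against all remaining samples (within its
    speaker's subset when ``group_by_speaker``); decisions accumulate into
    a confusion matrix whose row sums equal the per-class sample counts.
    Classes with fewer than two samples cannot be held out meaningfully and
    raise an error naming the class.
    """
    if not samples:
        raise ValueError("no samples to evaluate")
    labels = sorted({s.label for s in samples if s.label is not None})
    if any(s.label is None for s in samples):
        raise ValueError("every sample needs a label")
    index = {lab: i for i, lab in enumerate(labels)}

    groups: dict[str | None, list[FeatureMatrix]] = {}
    for s in samples:
        groups.setdefault(s.speaker if group_by_speaker else None, []).append(s)

    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for group in groups.values():
        per_class: dict[str, int] = {}
        for s in group:
            per_class[s.label] = per_class.get(s.label, 0) + 1
        for lab, n in per_class.items():
            if n < 2:
                raise ValueError(
                    f"class {lab!r} has only {n} sample(s); leave-one-out needs >= 2"
                )
        for i, held_out in enumerate(group):
            library = group[:i] + group[i + 1 :]
            predicted = classify(held_out, library)
            counts[index[held_out.label], index[predicted]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def precision_recall_f(confusion: ConfusionMatrix) -> Metrics:
    """Per-class and macro precision/recall and the macro F-measure.

    Precision of class c is ``diag / column sum`` and recall ``diag / row
    sum``; a zero denominator yields 0 for that class and the class is
    flagged in ``undefined_precision`` / ``undefined_recall``.  The
    F-measure is ``2 P R / (P + R)`` on the macro averages.
    """
    counts = confusion.counts
    if counts.sum() == 0:
        raise ValueError("confusion matrix is all zeros")
    diag = np.diag(counts).astype(float)
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float)

    undefined_p = tuple(l for l, c in zip(confusion.labels, col) if c == 0)
    undefined_r = tuple(l for l, r in zip(confusion.labels, row) if r == 0)
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)

    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    f = 0.0 if macro_p + macro_r == 0 else 2 * macro_p * macro_r / (macro_p + macro_r)
    return Metrics(
        labels=confusion.labels,
        precision=tuple(float(p) for p in precision),
        recall=tuple(float(r) for r in recall),
        macro_precision=macro_p,
        macro_recall=macro_r,
        f_measure=f,
        undefined_precision=undefined_p,
        undefined_recall=undefined_r,
    )
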