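"""Per-pixel segmentation metrics and cohort summaries.

Each pixel is treated as an independent binary classification decision:
TP/FP/TN/FN are pixel counts over the whole image. From these,

* accuracy      = (TP + TN) / (TP + TN + FP + FN)
* overlap rate  = |A ∧ B| / |A ∨ B|      (Jaccard index of the foregrounds)
* precision     = TP / (TP + FP)
* recall        = TP / (TP + FN)
* F-measure     = 2 P R / (P + R)

Degenerate denominators (paper-silent corner cases) follow fixed
conventions: two empty masks are a perfect match (overlap = precision =
recall = F = 1); an empty prediction against a nonempty reference (or vice
versa) scores 0 on the affected ratios; F is 0 when P + R = 0. Cohort
standard deviations use the population (divide-by-n) convention.
"""

from __future__ import annotations

import csv
import pathlib
from dataclasses import dataclass

import numpy as np

from .pairs_io import as_binary_mask

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "CohortSummary",
    "confusion",
    "score",
    "summarize",
    "compare_methods",
    "write_records_csv",
    "write_summaries_csv",
]

METRIC_NAMES = ("accuracy", "overlap", "precision", "recall", "f_measure")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricRecord:
    pair_id: str
    counts: ConfusionCounts
    accuracy: float
    overlap: float
    precision: float
    recall: float
    f_measure: float


@dataclass(frozen=True)
class CohortSummary:
    metric_name: str
    minimum: float
    maximum: float
    mean: float
    standard_deviation: float


def confusion(predicted: np.ndarray, reference: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts between a predicted and a reference mask."""
    pred = as_binary_mask(predicted).astype(bool)
    ref = as_binary_mask(reference).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: predicted {pred.shape} vs reference {ref.shape}")
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, empty_value: float) -> float:
    return num / den if den else empty_value


def score(predicted: np.ndarray, reference: np.ndarray, pair_id: str = "") -> MetricRecord:
    """Score one predicted mask against a reference mask."""
    c = confusion(predicted, reference)
    accuracy = (c.tp + c.tn) / c.total
    overlap = _ratio(c.tp, c.tp + c.fp + c.fn, 1.0)  # empty union: identical empties
    # an empty prediction is perfectly precise only if nothing was missed
    precision = _ratio(c.tp, c.tp + c.fp, 1.0 if c.fn == 0 else 0.0)
    recall = _ratio(c.tp, c.tp + c.fn, 1.0 if c.fp == 0 else 0.0)
    f = 2.0 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricRecord(pair_id=pair_id, counts=c, accuracy=accuracy,
                        overlap=overlap, precision=precision, recall=recall,
                        f_measure=f)


def summarize(records: list[MetricRecord], metric_name: str) -> CohortSummary:
    """Min/max/mean/population-sd of one metric across a cohort."""
    if not records:
        raise ValueError("records must be nonempty")
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}")
    values = np.array([getattr(r, metric_name) for r in records], dtype=np.float64)
    return CohortSummary(
        metric_name=metric_name,
        minimum=float(values.min()),
        maximum=float(values.max()),
        mean=float(values.mean()),
        standard_deviation=float(values.std()),  # population convention
    )


def compare_methods(per_method_records: dict[str, list[MetricRecord]]) -> list[dict]:
    """One row per method: mean ± sd of accuracy, overlap and F-measure.

    All methods must have been scored on the same pair ids.
    """
    id_sets = {m: frozenset(r.pair_id for r in recs) for m, recs in per_method_records.items()}
    distinct = set(id_sets.values())
    if len(distinct) > 1:
        raise ValueError(f"methods scored on different pair_id sets: {id_sets}")
    rows = []
    for method, recs in per_method_records.items():
        row = {"method": method}
        for metric in ("accuracy", "overlap", "f_measure"):
            s = summarize(recs, metric)
            row[f"{metric}_mean"] = s.mean
            row[f"{metric}_sd"] = s.standard_deviation
        rows.append(row)
    return rows


def write_records_csv(records: list[MetricRecord], path: pathlib.Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pair_id", "tp", "fp", "tn", "fn", *METRIC_NAMES])
        for r in records:
            w.writerow([r.pair_id, r.counts.tp, r.counts.fp, r.counts.tn, r.counts.fn]
                       + [f"{getattr(r, m):.6f}" for m in METRIC_NAMES])


def write_summaries_csv(summaries: list[CohortSummary], path: pathlib.Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "minimum", "maximum", "mean", "standard_deviation"])
        for s in summaries:
            w.writerow([s.metric_name, f"{s.minimum:.6f}", f"{s.maximum:.6f}",
                        f"{s.mean:.6f}", f"{s.standard_deviation:.6f}"])
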