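"""Pixelwise segmentation scores: accuracy, sensitivity, specificity, Dice.

Lung is the positive class.  All four scores derive from the per-pixel
confusion counts; the Dice coefficient DI(e, f) = 2|e∩f| / (|e| + |f|) is also
computed directly from the masks and equals 2TP / (2TP + FP + FN).

Degenerate denominators (e.g. sensitivity of an image with no lung pixels)
yield NaN, flagged so aggregation can exclude them; two empty masks have
Dice 1 by convention.  Neither case arises on real radiographs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "accuracy",
           "sensitivity", "specificity", "dice", "report", "aggregate",
           "write_reports"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    ac: float
    se: float
    sp: float
    di: float


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return p.astype(bool), t.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    p, t = _check_pair(pred, truth)
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        return float("nan")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return float("nan")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        return float("nan")
    return c.tn / (c.tn + c.fp)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """DI = 2|pred ∩ truth| / (|pred| + |truth|); both-empty -> 1."""
    p, t = _check_pair(pred, truth)
    denom = int(np.count_nonzero(p)) + int(np.count_nonzero(t))
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(p & t) / denom


def report(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    c = confusion(pred, truth)
    return MetricsReport(accuracy(c), sensitivity(c), specificity(c),
                         dice(pred, truth))


def aggregate(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean over images; NaN (undefined) entries are excluded."""
    if not reports:
        raise ValueError("no reports to aggregate")
    arr = np.array([[r.ac, r.se, r.sp, r.di] for r in reports])
    means = np.nanmean(arr, axis=0)
    return MetricsReport(*map(float, means))


def write_reports(ids: list[str], reports: list[MetricsReport],
                  csv_path: Path | str | None = None,
                  json_path: Path | str | None = None) -> pd.DataFrame:
    """Per-image table (columns id, AC, SE, SP, DI) plus the aggregate row."""
    df = pd.DataFrame(
        [{"id": i, "AC": r.ac, "SE": r.se, "SP": r.sp, "DI": r.di}
         for i, r in zip(ids, reports)])
    agg = aggregate(reports)
    if csv_path is not None:
        df.to_csv(csv_path, index=False, float_format="%.6f")
    if json_path is not None:
        payload = {"per_image": df.to_dict(orient="records"),
                   "aggregate": asdict(agg)}
        Path(json_path).write_text(json.dumps(payload, indent=2))
    return df
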