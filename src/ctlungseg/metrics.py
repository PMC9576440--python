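"""Per-case and averaged segmentation scores.

Each case is scored against the gold standard with four quantities
derived from voxelwise confusion counts (TP, TN, FP, FN):

    IOU       = |e∩f| / |e∪f|            = TP / (TP + FP + FN)
    Dice(e,f) = 2|e∩f| / (|e| + |f|)     = 2TP / (2TP + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)

with ``e`` the gold standard and ``f`` the segmentation result, and the
algebraic identity Dice = 2·IOU / (1 + IOU). Case scores are
macro-averaged (unweighted mean over cases) for reporting.

Conventions for degenerate cases: when both masks are empty all four
scores are 1; an empty-vs-nonempty comparison scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import MaskVolume

__all__ = ["ConfusionCounts", "CaseMetrics", "confusion", "case_metrics", "aggregate", "metrics_table"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise confusion counts of one case."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class CaseMetrics:
    """The four scores of one case."""

    case_id: str
    iou: float
    dice: float
    precision: float
    recall: float


def confusion(e: MaskVolume | np.ndarray, f: MaskVolume | np.ndarray) -> ConfusionCounts:
    """Voxelwise confusion counts of prediction ``f`` vs gold standard ``e``."""
    e_arr = e.voxels if isinstance(e, MaskVolume) else np.asarray(e)
    f_arr = f.voxels if isinstance(f, MaskVolume) else np.asarray(f)
    if e_arr.shape != f_arr.shape:
        raise ValueError(f"shape mismatch: {e_arr.shape} vs {f_arr.shape}")
    e_bool = e_arr.astype(bool)
    f_bool = f_arr.astype(bool)
    tp = int(np.count_nonzero(e_bool & f_bool))
    fp = int(np.count_nonzero(~e_bool & f_bool))
    fn = int(np.count_nonzero(e_bool & ~f_bool))
    tn = e_arr.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else 0.0


def case_metrics(c: ConfusionCounts, case_id: str = "case") -> CaseMetrics:
    """Derive IOU, Dice, precision and recall from confusion counts."""
    if c.tp + c.fp + c.fn == 0:  # both masks empty
        return CaseMetrics(case_id, 1.0, 1.0, 1.0, 1.0)
    return CaseMetrics(
        case_id=case_id,
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
    )


def score_case(e: MaskVolume, f: MaskVolume, case_id: str | None = None) -> CaseMetrics:
    """Convenience: confusion + case_metrics in one call."""
    cid = case_id or getattr(e, "case_id", "case")
    return case_metrics(confusion(e, f), case_id=cid)


def aggregate(cases: list[CaseMetrics]) -> CaseMetrics:
    """Unweighted (macro) mean of each score across cases."""
    if not cases:
        raise ValueError("cannot aggregate an empty list of cases")
    return CaseMetrics(
        case_id="Average",
        iou=float(np.mean([c.iou for c in cases])),
        dice=float(np.mean([c.dice for c in cases])),
        precision=float(np.mean([c.precision for c in cases])),
        recall=float(np.mean([c.recall for c in cases])),
    )


def metrics_table(cases: list[CaseMetrics]) -> pd.DataFrame:
    """Per-case table with an Average row, one row per case."""
    rows = [
        {"case": c.case_id, "IOU": c.iou, "Dice": c.dice,
         "Precision": c.precision, "Recall": c.recall}
        for c in cases
    ]
    avg = aggregate(cases)
    rows.append({"case": avg.case_id, "IOU": avg.iou, "Dice": avg.dice,
                 "Precision": avg.precision, "Recall": avg.recall})
    return pd.DataFrame(rows).set_index("case")
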