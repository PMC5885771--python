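"""Confusion-matrix statistics for binary bitter/non-bitter classification.

Six metrics are derived from the four counts (TP = true bitterant,
TN = true non-bitterant, FP = false bitterant, FN = false non-bitterant):

    F1          = 2 TP / (2 TP + FP + FN)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    MCC         = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus ΔF1 = |F1(cross-validation) − F1(test set)|, a robustness monitor.
Any metric with a zero denominator is an NA sentinel that prints as "–",
mirroring benchmark tables evaluated on single-class datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

__all__ = [
    "NA",
    "is_na",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "delta_f1",
    "round3",
    "format_value",
]

#: Sentinel for undefined ratios (zero denominator). NaN so it propagates.
NA = float("nan")

METRIC_NAMES = ("accuracy", "precision", "specificity", "sensitivity", "f1", "mcc")


def is_na(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


def round3(x: float) -> float:
    """Round to 3 decimals, half-even (display convention of printed tables).

    Half-even is forced by the reference tables themselves: 18/32 = 0.5625
    prints as 0.562 (ruling out half-up) while 30/52 = 0.57692 prints as
    0.577 (ruling out truncation).
    """
    if is_na(x):
        return NA
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN))


def format_value(x: float) -> str:
    return "–" if is_na(x) else f"{round3(x):.3f}"


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    specificity: float
    sensitivity: float
    f1: float
    mcc: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self) -> dict[str, float]:
        return {name: round3(getattr(self, name)) for name in METRIC_NAMES}

    def row(self) -> str:
        cells = [str(self.tp), str(self.tn), str(self.fp), str(self.fn)]
        cells += [format_value(getattr(self, name)) for name in METRIC_NAMES]
        return "\t".join(cells)


def confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with the bitter class (1 / "Y" / "bitter") positive."""
    yt = _binary(y_true)
    yp = _binary(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(((yp == 1) & (yt == 1)).sum())
    tn = int(((yp == 0) & (yt == 0)).sum())
    fp = int(((yp == 1) & (yt == 0)).sum())
    fn = int(((yp == 0) & (yt == 1)).sum())
    return tp, tn, fp, fn


def _binary(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "US" or arr.dtype == object:
        arr = np.asarray([1 if v in ("bitter", "Y", "1", 1, True) else 0 for v in arr])
    return arr.astype(int)


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else NA


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("all four confusion counts are zero")
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        precision=_ratio(tp, tp + fp),
        specificity=_ratio(tn, tn + fp),
        sensitivity=_ratio(tp, tp + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        mcc=(tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den != 0 else NA,
    )


def delta_f1(f1_cv: float, f1_test: float) -> float:
    """|F1(cross-validation) − F1(test set)|; values above 0.04 flag possible
    over/underfitting. NA inputs propagate."""
    if is_na(f1_cv) or is_na(f1_test):
        return NA
    return abs(f1_cv - f1_test)


ROBUSTNESS_BAND = 0.04


def delta_f1_flag(f1_cv: float, f1_test: float) -> bool:
    """True when ΔF1 exceeds the 0.04 robustness band (NA never flags)."""
    d = delta_f1(f1_cv, f1_test)
    return (not is_na(d)) and d > ROBUSTNESS_BAND
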