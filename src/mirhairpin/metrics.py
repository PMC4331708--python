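"""Confusion counts and the six-metric evaluation suite.

Metrics (percentages except MCC):

* SN  = TP / (TP + FN)          sensitivity / recall
* SP  = TN / (TN + FP)          specificity
* PRE = TP / (TP + FP)          precision
* ACC = (TP + TN) / total
* balanced ACC = (SN + SP) / 2  robust to class imbalance
* MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)) in [-1, 1]

Internal values keep full precision; :meth:`MetricsReport.rounded` applies
round-half-up to two decimals for reporting.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies; supports ``+`` for pooling across CV folds."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        """Tally binary labels (1 = positive)."""
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred, strict=True):
            if t and p:
                tp += 1
            elif t and not p:
                fn += 1
            elif not t and p:
                fp += 1
            else:
                tn += 1
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class MetricsReport:
    """Six-metric report; percentage fields are on the 0-100 scale."""

    sn: float
    sp: float
    pre: float
    acc: float
    balanced_acc: float
    mcc: float
    flags: tuple[str, ...] = field(default=())

    def rounded(self) -> dict[str, float]:
        """Two-decimal, round-half-up presentation values."""
        return {
            "SN": _round2(self.sn),
            "SP": _round2(self.sp),
            "PRE": _round2(self.pre),
            "ACC": _round2(self.acc),
            "balanced_ACC": _round2(self.balanced_acc),
            "MCC": _round2(self.mcc),
        }


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Derive the metric suite from confusion counts.

    Requires at least one evaluated record of each class (TP+FN >= 1 and
    TN+FP >= 1).  A zero factor in the MCC denominator (possible when a
    predictor assigns a single class) yields MCC = 0, flagged.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("metrics need at least one positive and one negative record")
    flags: list[str] = []
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    if tp + fp == 0:
        pre = 0.0
        flags.append("pre_undefined")
    else:
        pre = 100.0 * tp / (tp + fp)
    acc = 100.0 * (tp + tn) / counts.total
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
        flags.append("mcc_zero_denominator")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        sn=sn,
        sp=sp,
        pre=pre,
        acc=acc,
        balanced_acc=(sn + sp) / 2.0,
        mcc=mcc,
        flags=tuple(flags),
    )
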