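"""Confusion matrices and classification performance metrics.

The positive class is CR-POPF.  Metrics with a zero denominator (e.g. PPV
when nothing is predicted positive) are reported as ``None`` (undefined),
never coerced to 0.  F1 is the harmonic mean of PPV (precision) and
sensitivity (recall).  Percentages for report tables are rounded half-up to
whole percents; raw values are always kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

__all__ = [
    "MetricsError",
    "ConfusionMatrix",
    "PerformanceMetrics",
    "confusion",
    "metrics_from_confusion",
    "pool_confusions",
    "f1_score",
    "round_percent",
]


class MetricsError(ValueError):
    """Invalid metric computation request."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of predicted vs actual CR-POPF."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise MetricsError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity, PPV, NPV and F1; ``None`` means undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f1: Optional[float]


def confusion(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> ConfusionMatrix:
    """Cross-tabulate predicted vs actual outcomes."""
    if len(predictions) != len(labels):
        raise MetricsError("predictions and labels must have equal length")
    if not predictions:
        raise MetricsError("cannot build a confusion matrix from no samples")
    tp = fp = fn = tn = 0
    for p, y in zip(predictions, labels):
        if p and y:
            tp += 1
        elif p and not y:
            fp += 1
        elif not p and y:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def f1_score(ppv: Optional[float], sensitivity: Optional[float]) -> Optional[float]:
    """Harmonic mean of precision (PPV) and recall (sensitivity)."""
    if ppv is None or sensitivity is None or (ppv + sensitivity) == 0:
        return None
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def metrics_from_confusion(cm: ConfusionMatrix) -> PerformanceMetrics:
    """The five reported metrics from a 2x2 confusion matrix."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    return PerformanceMetrics(sens, spec, ppv, npv, f1_score(ppv, sens))


def pool_confusions(matrices: Sequence[ConfusionMatrix]) -> ConfusionMatrix:
    """Cellwise sum of confusion matrices (e.g. across diagnosis strata)."""
    if not matrices:
        raise MetricsError("cannot pool an empty list of confusion matrices")
    pooled = matrices[0]
    for m in matrices[1:]:
        pooled = pooled + m
    return pooled


def round_percent(metric: float) -> int:
    """Round a [0, 1] metric half-up to a whole percent (0.8667 -> 87)."""
    if metric is None or not 0.0 <= metric <= 1.0:
        raise MetricsError(f"metric must be in [0, 1], got {metric!r}")
    return int(
        (Decimal(repr(metric)) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
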