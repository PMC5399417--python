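"""Prediction-performance measures for imbalanced targets.

Accuracy is uninformative when the positive class is rare (predicting the
majority everywhere already scores 1 - prevalence), so the measures here are
precision, sensitivity, specificity, their harmonic-mean summary F1, and the
geometric mean of sensitivity and specificity (G-mean), which is the
training criterion of the pattern-discovery classifier.

Zero-denominator cases are defined (not errors) so that cross-validation
aggregation never drops folds: precision is 0 with no predicted positives,
sensitivity 0 with no positives, specificity 0 with no negatives, and
F1 = 0 whenever TP = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .pattern import ConfusionCounts

__all__ = ["MetricSet", "metrics_from_counts", "f1_from_rates", "METRIC_NAMES"]

METRIC_NAMES = ("precision", "sensitivity", "specificity", "f1", "g_mean")


@dataclass(frozen=True)
class MetricSet:
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    g_mean: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """All five measures from a confusion count."""
    pre = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    sen = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    f1 = 0.0 if c.TP == 0 else f1_from_rates(pre, sen)
    return MetricSet(
        precision=pre,
        sensitivity=sen,
        specificity=spec,
        f1=f1,
        g_mean=math.sqrt(sen * spec),
    )


def f1_from_rates(pre: float, sen: float) -> float:
    """Harmonic mean 2*pre*sen/(pre+sen); 0 when both rates are 0."""
    if not (0 <= pre <= 1 and 0 <= sen <= 1):
        raise ValueError("rates must be in [0, 1]")
    if pre + sen == 0:
        return 0.0
    return 2 * pre * sen / (pre + sen)
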