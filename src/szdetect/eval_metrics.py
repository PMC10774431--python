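"""Confusion-matrix metrics for binary and one-vs-rest evaluation.

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, precision
TP/(TP+FP), F-measure 2TP/(2TP+FP+FN), recall (= sensitivity) and the
geometric mean sqrt(sensitivity * specificity).  Zero-denominator metrics
are reported as an explicit ``UNDEFINED`` marker (serialized as JSON
null), never silently 0 or NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict


class _Undefined:
    """Marker for metrics whose denominator is zero."""

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = _Undefined()


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float | _Undefined
    specificity: float | _Undefined
    accuracy: float | _Undefined
    precision: float | _Undefined
    recall: float | _Undefined
    f_measure: float | _Undefined
    g_mean: float | _Undefined

    def as_dict(self) -> dict:
        return {k: (None if isinstance(v, _Undefined) else v)
                for k, v in asdict(self).items()}


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """2x2 confusion counts with the stated positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) == 0:
        raise ValueError("need at least one instance")
    labels = set(y_true) | set(y_pred)
    if positive_class not in labels and len(labels) > 0:
        # a positive class absent from both vectors is almost surely a typo
        raise ValueError(f"positive_class {positive_class!r} not among labels {sorted(map(str, labels))}")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: float, den: float):
    return UNDEFINED if den == 0 else num / den


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """All metrics of one confusion table; zero denominators -> UNDEFINED."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    sens = _ratio(c.TP, c.TP + c.FN)
    spec = _ratio(c.TN, c.TN + c.FP)
    acc = (c.TP + c.TN) / c.total
    prec = _ratio(c.TP, c.TP + c.FP)
    f1 = _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    if isinstance(sens, _Undefined) or isinstance(spec, _Undefined):
        gm = UNDEFINED
    else:
        gm = math.sqrt(sens * spec)
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc,
                         precision=prec, recall=sens, f_measure=f1, g_mean=gm)


def evaluate(y_true, y_pred, positive_class) -> MetricsReport:
    """Convenience: counts + metrics in one call (binary)."""
    return classification_metrics(confusion_counts(y_true, y_pred, positive_class))


def one_vs_rest_report(y_true, y_pred, class_names) -> dict:
    """Per-class one-vs-rest metrics plus unweighted macro averages."""
    per_class = {}
    for cls in class_names:
        per_class[str(cls)] = classification_metrics(
            confusion_counts(y_true, y_pred, cls)
        ).as_dict()
    macro = {}
    for key in next(iter(per_class.values())):
        vals = [m[key] for m in per_class.values() if m[key] is not None]
        macro[key] = sum(vals) / len(vals) if vals else None
    return {"per_class": per_class, "macro": macro}
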