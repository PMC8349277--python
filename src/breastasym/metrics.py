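"""Binary-classification metrics and across-iteration aggregation.

Units follow the mixed convention common in CAD reporting: accuracy and
error rate in percent, sensitivity/specificity/precision/F-score/MCC as
proportions (MCC in [-1, 1]).  Any 0/0 metric is reported as 0 and flagged
as degenerate rather than raising, so one pathological train/test split does
not abort a whole experiment.

Aggregation over repeated train/test iterations reports mean, sample
standard deviation (n-1 divisor), minimum and maximum per metric.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ContractError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "AggregateReport",
    "confusion_matrix",
    "compute_metrics",
    "aggregate",
    "METRIC_NAMES",
    "report_to_json",
]

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "accuracy",
    "error_rate",
    "precision",
    "mcc",
    "f_score",
)


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ContractError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ContractError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float  # percent
    error_rate: float  # percent
    precision: float
    mcc: float
    f_score: float
    degenerate: tuple[str, ...] = ()  # metrics that were 0/0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclasses.dataclass(frozen=True)
class AggregateReport:
    mean: dict[str, float]
    sd: dict[str, float]
    min: dict[str, float]
    max: dict[str, float]
    n: int

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            name: {
                "mean": self.mean[name],
                "sd": self.sd[name],
                "min": self.min[name],
                "max": self.max[name],
            }
            for name in METRIC_NAMES
        }


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, positive
) -> ConfusionMatrix:
    """Standard TP/TN/FP/FN tally over a binary label set."""
    if len(y_true) != len(y_pred):
        raise ContractError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) == 0:
        raise ContractError("empty label sequences")
    labels = set(y_true) | set(y_pred)
    if positive not in labels and len(labels) > 0:
        # allow: predictions may simply never hit the positive class
        pass
    if len(labels - {positive}) > 1:
        raise ContractError(f"more than two labels present: {sorted(map(str, labels))}")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The seven standard metrics of a binary confusion matrix."""
    degenerate: list[str] = []
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", degenerate)
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity", degenerate)
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision", degenerate)
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    error_rate = 100.0 - accuracy
    f_score = _ratio(2 * prec * sens, prec + sens, "f_score", degenerate)
    mcc_den = math.sqrt(
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = _ratio(float(cm.tp * cm.tn - cm.fp * cm.fn), mcc_den, "mcc", degenerate)
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
        error_rate=error_rate,
        precision=prec,
        mcc=mcc,
        f_score=f_score,
        degenerate=tuple(degenerate),
    )


def aggregate(reports: Sequence[MetricsReport]) -> AggregateReport:
    """Mean, sample SD (n-1; 0 for a single report), min and max per metric."""
    if not reports:
        raise ContractError("cannot aggregate an empty report list")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.asarray([getattr(r, name) for r in reports], dtype=float)
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        lo[name] = float(vals.min())
        hi[name] = float(vals.max())
    return AggregateReport(mean=mean, sd=sd, min=lo, max=hi, n=len(reports))


def report_to_json(
    per_iteration: Sequence[MetricsReport],
    aggregate_report: AggregateReport,
    path: str | Path | None = None,
    extra: dict | None = None,
) -> str:
    """Serialize an experiment's metrics as JSON; optionally write to disk."""
    payload = {
        "per_iteration": [r.as_dict() for r in per_iteration],
        "aggregate": aggregate_report.as_dict(),
        "n_iterations": aggregate_report.n,
    }
    if extra:
        payload.update(extra)
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
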