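"""Evaluation toolkit: MCC, MCC-optimal thresholding, bootstrap metrics.

The decision threshold on the classifier's risk output is selected by
maximizing the Matthews correlation coefficient

    MCC = (TN·TP − FN·FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which ranges over [−1, 1] (1 = perfect, 0 = chance, −1 = inverse
prediction) and rewards balanced performance on both classes, making it
well suited to imbalanced acceptability data. Threshold-based metrics
(sensitivity, specificity, accuracy, precision, F1) and the ROC AUC are
reported with 95% percentile-bootstrap confidence intervals.

Positive class throughout = unacceptable; a maneuver is predicted
unacceptable when its risk ≥ threshold.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import InvalidParameterError

__all__ = [
    "ConfusionMatrix",
    "ThresholdResult",
    "EvalReport",
    "mcc",
    "select_threshold",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for the binary decision, positive class = unacceptable."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")
        if self.total == 0:
            raise InvalidParameterError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, scores, labels, threshold: float) -> "ConfusionMatrix":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        pred = scores >= threshold
        return cls(
            tp=int(np.sum(pred & (labels == 1))),
            fp=int(np.sum(pred & (labels == 0))),
            fn=int(np.sum(~pred & (labels == 1))),
            tn=int(np.sum(~pred & (labels == 0))),
        )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    When any marginal is zero the denominator vanishes and the
    coefficient is defined as 0 (the chance convention).
    """
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tn * cm.tp - cm.fn * cm.fp) / math.sqrt(denom)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    mcc_at_threshold: float


def _check_both_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise InvalidParameterError("both classes must be present")


def select_threshold(scores, labels) -> ThresholdResult:
    """MCC-maximizing decision threshold over the candidate grid.

    Candidates are 0, 1 and the midpoints between consecutive distinct
    sorted scores; the rule predicts unacceptable when risk ≥ threshold.
    Ties in MCC are broken toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_both_classes(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0]))
    best = ThresholdResult(threshold=0.0, mcc_at_threshold=-np.inf)
    for thr in candidates:
        value = mcc(ConfusionMatrix.from_predictions(scores, labels, thr))
        if value > best.mcc_at_threshold:  # strict: ties keep the smaller thr
            best = ThresholdResult(threshold=float(thr), mcc_at_threshold=value)
    return best


@dataclass(frozen=True)
class EvalReport:
    """Point estimates with 95% bootstrap CIs, all on the [0, 1] scale."""

    metrics: dict  # name -> (point, ci_low, ci_high)
    threshold: float
    confusion: ConfusionMatrix
    n_boot: int

    def __getitem__(self, name: str):
        return self.metrics[name]

    def to_json(self) -> str:
        payload = {
            "threshold": self.threshold,
            "n_boot": self.n_boot,
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "fn": self.confusion.fn, "tn": self.confusion.tn,
            },
            "metrics": {
                k: {"value": v[0], "ci95": [v[1], v[2]]}
                for k, v in self.metrics.items()
            },
        }
        return json.dumps(payload, indent=2, allow_nan=True)

    def format_text(self) -> str:
        lines = [f"threshold = {self.threshold:.3f}  (n = {self.confusion.total})"]
        for k, (pt, lo, hi) in self.metrics.items():
            if np.isnan(pt):
                lines.append(f"  {k:<12} undefined")
            else:
                lines.append(f"  {k:<12} {pt:6.2f}  (95% CI {lo:.2f}-{hi:.2f})")
        return "\n".join(lines)


def _point_metrics(scores, labels, threshold) -> dict[str, float]:
    cm = ConfusionMatrix.from_predictions(scores, labels, threshold)

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
            return float("nan")
        return num / den

    sens = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    prec = ratio(cm.tp, cm.tp + cm.fp, "precision")
    f1 = (
        float("nan")
        if np.isnan(prec) or np.isnan(sens) or prec + sens == 0
        else 2 * prec * sens / (prec + sens)
    )
    return {
        "auc": roc_auc_score(labels, scores),  # trapezoidal ROC integration
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "f1": f1,
        "precision": prec,
    }


def evaluate(
    scores, labels, threshold: float, n_boot: int = 2000, seed: int = 0
) -> EvalReport:
    """Threshold-based evaluation with percentile-bootstrap 95% CIs.

    Resamples (score, label) pairs with replacement ``n_boot`` times;
    resamples that lose one of the classes are skipped (their AUC is
    undefined). Metrics with a zero denominator at the point estimate are
    reported as NaN with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_both_classes(labels)
    if not 0.0 <= threshold <= 1.0:
        raise InvalidParameterError("threshold must be in [0, 1]")

    point = _point_metrics(scores, labels, threshold)
    rng = np.random.default_rng(seed)
    n = scores.size
    boots: dict[str, list[float]] = {k: [] for k in point}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-denominator resamples
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if len(np.unique(labels[idx])) < 2:
                continue
            for k, v in _point_metrics(scores[idx], labels[idx], threshold).items():
                if not np.isnan(v):
                    boots[k].append(v)

    metrics = {}
    for k, pt in point.items():
        if boots[k]:
            lo, hi = np.percentile(boots[k], [2.5, 97.5])
            # the point estimate is always inside its own CI
            lo, hi = min(lo, pt), max(hi, pt)
        else:
            lo = hi = pt
        metrics[k] = (float(pt), float(lo), float(hi))
    return EvalReport(
        metrics=metrics,
        threshold=float(threshold),
        confusion=ConfusionMatrix.from_predictions(scores, labels, threshold),
        n_boot=n_boot,
    )
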