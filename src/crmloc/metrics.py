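"""Binary-classification metric suite and Wilson confidence intervals.

Accuracy, AUC, sensitivity, specificity, F measure and the Matthews
correlation coefficient (MCC), with the abnormal class as positive, plus
the Wilson score interval used to report AUC confidence bounds with
per-interval coverage sqrt(0.95) (so that two simultaneous two-sided
intervals jointly cover at 95%).

Degenerate cells follow fixed conventions: sensitivity/specificity of an
empty class are reported as NaN, an MCC with a zero denominator is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from .exceptions import InputError

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "confusion",
    "metric_suite",
    "wilson_interval",
    "SIMULTANEOUS_COVERAGE",
]

# per-interval coverage giving joint 95% over two simultaneous intervals
SIMULTANEOUS_COVERAGE = math.sqrt(0.95)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; positive class = abnormal."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.total < 1:
            raise InputError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricRecord:
    accuracy: float
    auc: Optional[float]
    auc_ci: Optional[tuple[float, float]]
    sensitivity: float
    specificity: float
    f_measure: float
    mcc: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(
    labels_true: np.ndarray, p_abnormal: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts at a probability threshold (1 = abnormal)."""
    y = np.asarray(labels_true, dtype=int).ravel()
    p = np.asarray(p_abnormal, dtype=float).ravel()
    if y.size == 0:
        raise InputError("empty input")
    if y.size != p.size:
        raise InputError("labels and probabilities differ in length")
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def mcc_from_counts(cc: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    num = cc.tp * cc.tn - cc.fp * cc.fn
    den = math.sqrt(
        float(cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    )
    return num / den if den > 0 else 0.0


def metric_suite(
    cc: ConfusionCounts,
    labels_true: Optional[np.ndarray] = None,
    p_abnormal: Optional[np.ndarray] = None,
    ci_coverage: float = SIMULTANEOUS_COVERAGE,
) -> MetricRecord:
    """Full metric record from confusion counts (+ scores for AUC).

    AUC is the trapezoidal area under the ROC curve swept over the score
    thresholds, computed only when ``labels_true``/``p_abnormal`` are given
    and both classes are present.  Its Wilson interval treats the AUC as a
    proportion with n = sample count — the reporting convention adopted
    here, with the caveat that AUC is not a binomial proportion.
    """
    auc = None
    auc_ci = None
    if labels_true is not None and p_abnormal is not None:
        y = np.asarray(labels_true, dtype=int).ravel()
        if y.size and 0 < y.sum() < y.size:
            auc = float(roc_auc_score(y, np.asarray(p_abnormal, dtype=float).ravel()))
            auc_ci = wilson_interval(auc, y.size, coverage=ci_coverage)
    return MetricRecord(
        accuracy=(cc.tp + cc.tn) / cc.total,
        auc=auc,
        auc_ci=auc_ci,
        sensitivity=_safe_div(cc.tp, cc.tp + cc.fn),
        specificity=_safe_div(cc.tn, cc.tn + cc.fp),
        f_measure=_safe_div(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn),
        mcc=mcc_from_counts(cc),
        n=cc.total,
    )


def wilson_interval(
    p_hat: float, n: int, coverage: float = 0.95
) -> tuple[float, float]:
    """Wilson score confidence interval for a proportion.

    ``z`` is the standard-normal quantile at ``1 - (1 - coverage) / 2``.
    The interval always contains ``p_hat`` and stays inside [0, 1].  Pass
    ``coverage=sqrt(0.95)`` for two simultaneous two-sided intervals with
    joint 95% coverage.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise InputError(f"p_hat must be in [0, 1], got {p_hat}")
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    if not 0.0 < coverage < 1.0:
        raise InputError(f"coverage must be in (0, 1), got {coverage}")
    z = float(norm.ppf(1.0 - (1.0 - coverage) / 2.0))
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (p_hat + z2 / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p_hat * (1.0 - p_hat) / n + z2 / (4.0 * n * n))
    return (max(0.0, center - half), min(1.0, center + half))
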