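"""Evaluation metrics for affinity regression and interaction classification.

Regression (DTA): concordance index, mean squared error, the modified
squared correlation rm2 standard in affinity benchmarking, and AUPR after
binarizing affinities at an explicit threshold.  Classification (CPI):
AUROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricReport",
    "concordance_index",
    "mse",
    "rm_squared",
    "aupr",
    "auroc",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given labels."""


@dataclass
class MetricReport:
    n_pairs: int
    ci: Optional[float] = None
    mse: Optional[float] = None
    rm2: Optional[float] = None
    aupr: Optional[float] = None
    auroc: Optional[float] = None
    binarization_threshold: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _as_arrays(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length 1D sequences")
    return y, yhat


def concordance_index(y, yhat) -> float:
    """Fraction of comparable label pairs ordered concordantly by ``yhat``.

    Over all pairs (a, b) with ``y_a != y_b``: 1 if the predictions order
    them as the labels do, 0.5 on a predicted tie, 0 otherwise.
    """
    y, yhat = _as_arrays(y, yhat)
    if len(y) < 2:
        raise ValueError("need at least two observations")
    dy = y[:, None] - y[None, :]
    dp = yhat[:, None] - yhat[None, :]
    comparable = dy > 0  # each unordered pair counted once, from the larger label
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedMetricError("all labels equal: no comparable pairs")
    score = (dp[comparable] > 0).sum() + 0.5 * (dp[comparable] == 0).sum()
    return float(score / n)


def mse(y, yhat) -> float:
    y, yhat = _as_arrays(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def rm_squared(y, yhat) -> float:
    """Modified squared correlation ``r^2 * (1 - sqrt(|r^2 - r0^2|))``.

    ``r^2`` is the squared Pearson correlation of labels and predictions;
    ``r0^2`` is the through-origin coefficient with slope
    ``k = sum(y * yhat) / sum(yhat^2)``.  The penalty term shrinks the score
    whenever the fit through the origin disagrees with the free fit, as is
    conventional in affinity benchmarking.
    """
    y, yhat = _as_arrays(y, yhat)
    if len(y) < 3:
        raise ValueError("need at least three observations")
    if np.var(y) == 0 or np.var(yhat) == 0:
        raise UndefinedMetricError("zero variance in labels or predictions")
    r = np.corrcoef(y, yhat)[0, 1]
    r2 = r * r
    k = float(np.sum(y * yhat) / np.sum(yhat ** 2))
    r0_2 = 1.0 - np.sum((y - k * yhat) ** 2) / np.sum((y - y.mean()) ** 2)
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r0_2))))


def aupr(y, yhat, threshold: float) -> float:
    """Area under the precision-recall curve after binarizing ``y >= threshold``."""
    y, yhat = _as_arrays(y, yhat)
    labels = (y >= threshold).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            f"binarizing at {threshold} leaves a single class; choose another threshold"
        )
    return float(average_precision_score(labels, yhat))


def auroc(y, yhat) -> float:
    """Area under the ROC curve (equals the Mann-Whitney statistic)."""
    y, yhat = _as_arrays(y, yhat)
    classes = np.unique(y)
    if len(classes) != 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(y, yhat))
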