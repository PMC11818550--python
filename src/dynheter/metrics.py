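"""Evaluation metrics for affinity regression and interaction classification.

Regression: mean squared error; the concordance index
``CI = (1/Z) * sum_{y_x > y_y} h(yhat_x - yhat_y)`` with the step function
``h = 1 / 0.5 / 0`` for positive / zero / negative differences and ``Z``
the number of comparable (strictly ordered) true pairs; and the modified
squared correlation ``rm2 = r2 * (1 - sqrt(r2 - r02))`` where ``r2`` is the
Pearson correlation squared (fit with intercept) and ``r02`` the
through-origin coefficient of determination of predictions on truth.

Classification: precision, recall, F1 at a probability threshold, plus
AUROC and AUPR (area under the precision-recall curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricReport",
    "mse_loss",
    "concordance_index",
    "rm2",
    "classification_metrics",
    "regression_report",
]


@dataclass
class MetricReport:
    n: int
    mse: float | None = None
    ci: float | None = None
    rm2: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    auroc: float | None = None
    aupr: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def mse_loss(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((y_true - y_pred) ** 2))


def concordance_index(y_true, y_pred) -> float:
    """Fraction of strictly ordered true pairs whose predicted ordering agrees.

    Predicted ties count 1/2.  Raises if no pair of true values differs.
    """
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("expected equal-length 1-d vectors")
    if len(y_true) < 2:
        raise ValueError("need at least 2 records")
    dy = y_true[:, None] > y_true[None, :]          # pairs with y_x > y_y
    Z = int(dy.sum())
    if Z == 0:
        raise ValueError("all true values are equal; concordance index undefined")
    diff = y_pred[:, None] - y_pred[None, :]
    h = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(h[dy].sum() / Z)


def rm2(y_true, y_pred, formula: str = "roy") -> float:
    """Modified squared correlation penalizing intercept/through-origin gaps.

    ``formula="roy"`` (default) uses ``r2 * (1 - sqrt(r2 - r02))``;
    ``formula="paper"`` drops the square root.  ``r02`` is the coefficient
    of determination of the through-origin regression of predictions on
    truth, clamped into [0, r2].
    """
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    if len(y_true) < 3:
        raise ValueError("need at least 3 records")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("zero variance in inputs; rm2 undefined")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    r2 = r * r
    # through-origin regression of y_pred on y_true
    k = float(np.dot(y_true, y_pred) / np.dot(y_true, y_true))
    ss_res = float(np.sum((y_pred - k * y_true) ** 2))
    ss_tot = float(np.sum((y_pred - y_pred.mean()) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    r02 = min(max(r02, 0.0), r2)
    radicand = r2 - r02
    if radicand < 0:
        warnings.warn("r2 < r02 numerically; clamping radicand at 0")
        radicand = 0.0
    if formula == "roy":
        return float(r2 * (1.0 - np.sqrt(radicand)))
    if formula == "paper":
        return float(r2 * (1.0 - radicand))
    raise ValueError(f"unknown formula {formula!r}")


def classification_metrics(y_true, y_score, threshold: float = 0.5) -> MetricReport:
    y_true = np.asarray(y_true, float)
    y_score = np.asarray(y_score, float)
    if not np.isin(y_true, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    y_hat = (y_score >= threshold).astype(float)
    tp = float(np.sum((y_hat == 1) & (y_true == 1)))
    fp = float(np.sum((y_hat == 1) & (y_true == 0)))
    fn = float(np.sum((y_hat == 0) & (y_true == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall > 0 else 0.0
    return MetricReport(
        n=len(y_true),
        precision=precision,
        recall=recall,
        f1=f1,
        auroc=float(roc_auc_score(y_true, y_score)),
        aupr=float(average_precision_score(y_true, y_score)),
    )


def regression_report(y_true, y_pred) -> MetricReport:
    return MetricReport(
        n=len(np.asarray(y_true)),
        mse=mse_loss(y_true, y_pred),
        ci=concordance_index(y_true, y_pred),
        rm2=rm2(y_true, y_pred),
    )
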