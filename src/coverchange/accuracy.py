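"""Confusion-matrix accuracy assessment: overall accuracy, kappa, per-class.

Conventions: rows of the confusion matrix are the reference (truth)
class, columns the predicted class, in fixed class-code order.  Overall
accuracy OA = trace/total.  Cohen's kappa corrects OA for chance
agreement from the marginals: kappa = (p_o - p_e) / (1 - p_e) with
p_o = OA and p_e = sum_k row_k * col_k / total^2; kappa <= OA always.
Per-class accuracy is producer's (diagonal over reference-row total) by
default, with user's (diagonal over predicted-column total) available —
published per-class figures often do not say which they are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import ROISet
from .raster_core import CLASS_CODES, CLASS_DISPLAY_NAMES, NODATA, ClassMap

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "confusion_matrix",
    "overall_accuracy",
    "kappa",
    "per_class_accuracy",
    "assess",
]

logger = logging.getLogger(__name__)

K = len(CLASS_CODES)


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = reference class, columns = predicted class."""

    counts: np.ndarray
    class_codes: tuple[int, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_codes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square over the class codes")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_DISPLAY_NAMES.get(c, str(c)) for c in self.class_codes]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class AccuracyReport:
    overall_accuracy: float
    kappa: float
    per_class: dict[int, float]  # producer's accuracy by class code
    per_class_user: dict[int, float]
    n_validation: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in sorted(self.n_validation):
            rows.append(
                {
                    "class": CLASS_DISPLAY_NAMES.get(code, str(code)),
                    "producer_accuracy": self.per_class.get(code, np.nan),
                    "user_accuracy": self.per_class_user.get(code, np.nan),
                    "n_validation": self.n_validation[code],
                }
            )
        return pd.DataFrame(rows)


def confusion_matrix(predicted: ClassMap, validation: ROISet) -> ConfusionMatrix:
    """Cross-tabulate validation reference labels against predicted classes.

    Validation ROIs on nodata pixels are dropped with a logged warning.
    """
    r = validation.records["row"].to_numpy()
    c = validation.records["col"].to_numpy()
    ref = validation.records["class_code"].to_numpy()
    pred = predicted.values[r, c].astype(np.int64)
    ok = pred != NODATA
    if (~ok).any():
        logger.warning(
            "dropping %d validation ROI(s) on nodata pixels", int((~ok).sum())
        )
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (ref[ok] - 1, pred[ok] - 1), 1)
    return ConfusionMatrix(counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """OA = sum of the diagonal over the grand total."""
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa, chance-corrected agreement from the marginals."""
    total = cm.total
    p_o = np.trace(cm.counts) / total
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float(rows @ cols) / total**2
    if p_e >= 1.0:
        raise ValueError("kappa undefined: expected agreement is 1 (degenerate matrix)")
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_accuracy(cm: ConfusionMatrix, mode: str = "producer") -> dict[int, float]:
    """Per-class accuracy; classes with a zero marginal map to NaN."""
    if mode not in ("producer", "user"):
        raise ValueError("mode must be 'producer' or 'user'")
    diag = np.diag(cm.counts).astype(float)
    marg = cm.counts.sum(axis=1 if mode == "producer" else 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(marg > 0, diag / marg, np.nan)
    return {code: float(v) for code, v in zip(cm.class_codes, vals)}


def assess(predicted: ClassMap, validation: ROISet) -> tuple[ConfusionMatrix, AccuracyReport]:
    """Full accuracy assessment from a predicted map and validation ROIs."""
    cm = confusion_matrix(predicted, validation)
    n_val = {
        code: int(n) for code, n in zip(cm.class_codes, cm.counts.sum(axis=1))
    }
    report = AccuracyReport(
        overall_accuracy=overall_accuracy(cm),
        kappa=kappa(cm),
        per_class=per_class_accuracy(cm, "producer"),
        per_class_user=per_class_accuracy(cm, "user"),
        n_validation=n_val,
    )
    return cm, report
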