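"""Performance measures: ROC/AUC, accuracy, confusion matrices, and agreement
of external MHC-binding predictions with measured IVIG binding labels.

AUC is the area under the ROC curve by trapezoidal integration, equal to the
probability that a random binder outscores a random non-binder with ties
credited 0.5.  Accuracy is correctly classified instances over all instances.
Confusion matrices follow the orientation rows = prediction, columns = actual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import ConfigurationError, EvaluationError, InputError

BINDING = "binding"
NON_BINDING = "non-binding"


@dataclass
class ROCCurve:
    """ROC points sorted from the strictest to the loosest threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self):
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


@dataclass
class EvalReport:
    """2x2 confusion counts (rows = prediction, columns = actual) plus accuracy."""

    confusion: np.ndarray  # [[pred binding x actual binder, pred binding x actual non-binder],
    #                         [pred non-binding x actual binder, pred non-binding x actual non-binder]]
    accuracy: float
    auc: Optional[float] = None

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=pd.Index([BINDING, NON_BINDING], name="prediction"),
            columns=pd.Index(["actual binders", "actual non-binders"]),
        )


def _binary(labels: Sequence[str]) -> np.ndarray:
    return np.array([1 if l == BINDING else 0 for l in labels])


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> ROCCurve:
    """ROC curve and AUC of *scores* against binary binding *labels*."""
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise InputError("scores and labels differ in length")
    if not np.all(np.isfinite(s)):
        raise InputError("scores must be finite")
    if y.min() == y.max():
        raise EvaluationError("ROC requires both classes to be present")
    fpr, tpr, thr = _roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_trapezoid_auc(fpr, tpr)))


def confusion_accuracy(
    predicted: Sequence[str], actual: Sequence[str]
) -> EvalReport:
    """Confusion counts and accuracy for predicted vs actual binding labels."""
    if len(predicted) != len(actual):
        raise InputError("predicted and actual label lists differ in length")
    pred = _binary(predicted)
    act = _binary(actual)
    bb = int(np.sum((pred == 1) & (act == 1)))
    bn = int(np.sum((pred == 1) & (act == 0)))
    nb = int(np.sum((pred == 0) & (act == 1)))
    nn = int(np.sum((pred == 0) & (act == 0)))
    confusion = np.array([[bb, bn], [nb, nn]])
    accuracy = (bb + nn) / confusion.sum()
    return EvalReport(confusion=confusion, accuracy=float(accuracy))


def report_from_confusion(
    pred_binding_actual_binding: int,
    pred_binding_actual_nonbinding: int,
    pred_nonbinding_actual_binding: int,
    pred_nonbinding_actual_nonbinding: int,
) -> EvalReport:
    """Build an :class:`EvalReport` directly from four confusion counts."""
    confusion = np.array(
        [
            [pred_binding_actual_binding, pred_binding_actual_nonbinding],
            [pred_nonbinding_actual_binding, pred_nonbinding_actual_nonbinding],
        ]
    )
    if confusion.min() < 0 or confusion.sum() == 0:
        raise InputError("confusion counts must be nonnegative with a positive total")
    accuracy = (confusion[0, 0] + confusion[1, 1]) / confusion.sum()
    return EvalReport(confusion=confusion, accuracy=float(accuracy))


def mhc_agreement(
    mhc_scores: pd.DataFrame,
    labels: Dict[str, str],
    aggregation: str = "max",
    cutoff: float = 0.5,
) -> Tuple[ROCCurve, EvalReport]:
    """Agreement of external MHC-binding scores with IVIG binding labels.

    *mhc_scores* has columns ``peptide_id``, ``allele``, ``score``; each
    labeled peptide needs at least one row.  The per-peptide score is the
    maximum (or mean) over the listed alleles; the ROC treats the IVIG label
    as ground truth.  The second return value is the operating point at the
    prediction-server cutoff (score > *cutoff* means MHC-binding).
    """
    for col in ("peptide_id", "allele", "score"):
        if col not in mhc_scores.columns:
            raise InputError(f"MHC score table missing column {col!r}")
    if aggregation not in ("max", "mean"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    grouped = mhc_scores.groupby("peptide_id")["score"]
    per_peptide = (grouped.max() if aggregation == "max" else grouped.mean())
    missing = sorted(set(labels) - set(per_peptide.index))
    if missing:
        raise InputError(
            f"{len(missing)} labeled peptide(s) without MHC scores: {missing[:10]}"
        )
    ids = sorted(labels)
    scores = np.array([per_peptide[i] for i in ids])
    lab = [labels[i] for i in ids]
    curve = roc_auc(scores, lab)
    predicted = [BINDING if s > cutoff else NON_BINDING for s in scores]
    return curve, confusion_accuracy(predicted, lab)
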