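"""Classifiability stratification and Type I / Type II EAR assignment.

A labeled peptide set is split into five class-stratified folds; each fold
is judged by an interpretable logistic classifier trained on the other four.
Correctly predicted peptides are *1st degree classifiable*, the rest
*unclassifiable*.  Iterating the procedure inside the unclassifiable subset
yields the 2nd degree partition, and a ratio PWM built within the remaining
2nd degree unclassifiable peptides rescues position-specific signal that
composition-based classifiers cannot see (3rd degree).

Binding peptides that are 1st degree classifiable are *Type I EAR*; binding
peptides that are 1st degree unclassifiable are *Type II EAR*.  Scatter
coordinates score every peptide against a whole-set ratio PWM (x) and an
unclassifiable-only ratio PWM (y) to display the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import EarError, InputError, StratificationError
from .evaluate import ROCCurve, confusion_accuracy, roc_auc
from .features import FeatureMatrix, interpretable_feature_matrix
from .peptide_io import BINDING, NON_BINDING, LabeledPeptide
from .pwm import (
    PWMClassifier,
    RatioPWM,
    build_frequency_pwm,
    build_ratio_pwm,
    calibrate_threshold,
    pwm_scores,
)
from .rules import fit_interpretable_classifier


@dataclass
class ClassifiabilityPartition:
    """Per-peptide classifiable/unclassifiable flags for one degree."""

    degree: int
    classifiable_ids: List[str]
    unclassifiable_ids: List[str]
    folds: int
    seed: int

    @property
    def all_ids(self) -> List[str]:
        return self.classifiable_ids + self.unclassifiable_ids


@dataclass
class EARTypeAssignment:
    """Type I/II labels for binding peptides (non-binders receive no type)."""

    type_I_ids: List[str]
    type_II_ids: List[str]


@dataclass
class ScatterCoordinates:
    """Dual-PWM coordinates: x from the whole-set PWM, y from the
    unclassifiable-only PWM."""

    peptide_ids: List[str]
    x: np.ndarray
    y: np.ndarray


@dataclass
class PWMRescueResult:
    """PWM classification within a restricted peptide set (3rd degree)."""

    peptide_ids: List[str]
    scores: np.ndarray
    predicted: List[str]
    threshold: float
    roc: ROCCurve
    accuracy: float
    classifiable_ids: List[str]      # correctly classified by the PWM
    unclassifiable_ids: List[str]


def _check_classes(labels: Sequence[str], folds: int) -> np.ndarray:
    y = np.array([1 if l == BINDING else 0 for l in labels])
    if min(np.sum(y == 1), np.sum(y == 0)) < folds:
        raise StratificationError(
            f"need at least {folds} peptides in each class for {folds} folds"
        )
    return y


def partition_by_classifiability(
    features: FeatureMatrix,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    degree: int = 1,
    cutoff: float = 0.5,
) -> ClassifiabilityPartition:
    """Judge every peptide with a classifier that never saw it.

    Each of *folds* class-stratified subsets is predicted by an interpretable
    logistic classifier trained on the remaining folds; correctly predicted
    peptides are classifiable, the rest unclassifiable.
    """
    y = _check_classes(labels, folds)
    n = len(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    correct = np.zeros(n, dtype=bool)
    for fit_idx, held_idx in skf.split(np.zeros(n), y):
        clf = fit_interpretable_classifier(
            features.subset_rows(fit_idx), [labels[i] for i in fit_idx], seed=seed
        )
        pred = clf.predict(features.subset_rows(held_idx), cutoff=cutoff)
        correct[held_idx] = [p == labels[i] for p, i in zip(pred, held_idx)]
    ids = features.peptide_ids
    return ClassifiabilityPartition(
        degree=degree,
        classifiable_ids=[ids[i] for i in range(n) if correct[i]],
        unclassifiable_ids=[ids[i] for i in range(n) if not correct[i]],
        folds=folds,
        seed=seed,
    )


def iterate_partition(
    features: FeatureMatrix,
    labels: Sequence[str],
    first: ClassifiabilityPartition,
    folds: int = 5,
    seed: int = 0,
) -> ClassifiabilityPartition:
    """Apply the same procedure within the 1st degree unclassifiable subset."""
    unclass = set(first.unclassifiable_ids)
    idx = [i for i, pid in enumerate(features.peptide_ids) if pid in unclass]
    if not idx:
        return ClassifiabilityPartition(
            degree=first.degree + 1, classifiable_ids=[], unclassifiable_ids=[],
            folds=folds, seed=seed,
        )
    sub = features.subset_rows(idx)
    sub_labels = [labels[i] for i in idx]
    part = partition_by_classifiability(
        sub, sub_labels, folds=folds, seed=seed, degree=first.degree + 1
    )
    return part


def groupwise_cv_performance(
    features: FeatureMatrix,
    labels: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    folds: int = 10,
    seed: int = 0,
) -> Tuple[float, float]:
    """Cross-validated (accuracy, AUC) of the interpretable classifier within
    a peptide subset (the whole set when *ids* is None)."""
    if ids is not None:
        keep = set(ids)
        idx = [i for i, pid in enumerate(features.peptide_ids) if pid in keep]
        features = features.subset_rows(idx)
        labels = [labels[i] for i in idx]
    y = _check_classes(labels, folds)
    n = len(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    proba = np.empty(n)
    for fit_idx, held_idx in skf.split(np.zeros(n), y):
        clf = fit_interpretable_classifier(
            features.subset_rows(fit_idx), [labels[i] for i in fit_idx], seed=seed
        )
        proba[held_idx] = clf.predict_proba_binding(features.subset_rows(held_idx))
    predicted = [BINDING if p > 0.5 else NON_BINDING for p in proba]
    report = confusion_accuracy(predicted, list(labels))
    curve = roc_auc(proba, list(labels))
    return report.accuracy, curve.auc


def pwm_rescue(
    peptides: Sequence[LabeledPeptide],
    pseudocount: float = 1.0,
    threshold_mode: str = "fit",
    threshold: Optional[float] = None,
) -> PWMRescueResult:
    """Classify a restricted peptide set by a ratio PWM built within it.

    ``threshold_mode="fit"`` picks the accuracy-maximizing score threshold on
    the set itself; ``"fixed"`` uses *threshold*.  Correctly classified
    peptides form the 3rd degree classifiable subset.
    """
    binding = [p.sequence for p in peptides if p.label == BINDING]
    nonbinding = [p.sequence for p in peptides if p.label == NON_BINDING]
    if not binding or not nonbinding:
        raise EarError("PWM rescue requires both classes in the subset")
    length = len(peptides[0].sequence)
    ratio = build_ratio_pwm(
        build_frequency_pwm(binding, length=length, pseudocount=pseudocount),
        build_frequency_pwm(nonbinding, length=length, pseudocount=pseudocount),
    )
    seqs = [p.sequence for p in peptides]
    labels = [p.label for p in peptides]
    scores = pwm_scores(seqs, PWMClassifier(ratio_pwm=ratio, threshold=1.0))
    if threshold_mode == "fit":
        thr = calibrate_threshold(scores, labels)
    elif threshold_mode == "fixed":
        if threshold is None:
            raise InputError("threshold_mode='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise InputError(f"unknown threshold_mode {threshold_mode!r}")
    predicted = [BINDING if s > thr else NON_BINDING for s in scores]
    report = confusion_accuracy(predicted, labels)
    curve = roc_auc(scores, labels)
    ids = [p.peptide_id for p in peptides]
    correct = [pr == la for pr, la in zip(predicted, labels)]
    return PWMRescueResult(
        peptide_ids=ids,
        scores=scores,
        predicted=predicted,
        threshold=thr,
        roc=curve,
        accuracy=report.accuracy,
        classifiable_ids=[i for i, ok in zip(ids, correct) if ok],
        unclassifiable_ids=[i for i, ok in zip(ids, correct) if not ok],
    )


def assign_ear_types(
    partition: ClassifiabilityPartition, labels: Dict[str, str]
) -> EARTypeAssignment:
    """Type I = binding and classifiable; Type II = binding and unclassifiable."""
    covered = set(partition.all_ids)
    missing = sorted(set(labels) - covered)
    if missing:
        raise InputError(f"peptide(s) not covered by the partition: {missing[:10]}")
    classifiable = set(partition.classifiable_ids)
    type_I, type_II = [], []
    for pid, label in labels.items():
        if label != BINDING:
            continue
        (type_I if pid in classifiable else type_II).append(pid)
    return EARTypeAssignment(type_I_ids=sorted(type_I), type_II_ids=sorted(type_II))


def scatter_coordinates(
    peptides: Sequence[Tuple[str, str]],
    pwm_all: RatioPWM,
    pwm_unclassifiable: RatioPWM,
) -> ScatterCoordinates:
    """Per-peptide (x, y) PWM scores against the whole-set and the
    unclassifiable-only ratio PWMs."""
    seqs = [seq for _, seq in peptides]
    x = pwm_scores(seqs, PWMClassifier(ratio_pwm=pwm_all, threshold=1.0))
    y = pwm_scores(seqs, PWMClassifier(ratio_pwm=pwm_unclassifiable, threshold=1.0))
    return ScatterCoordinates(peptide_ids=[pid for pid, _ in peptides], x=x, y=y)


def stratify_peptides(
    peptides: Sequence[LabeledPeptide],
    k_max: int = 1,
    folds: int = 5,
    seed: int = 0,
) -> Tuple[ClassifiabilityPartition, EARTypeAssignment, FeatureMatrix]:
    """Convenience pipeline: interpretable features -> 1st degree partition ->
    EAR types.  Returns the partition, the type assignment and the feature
    matrix for reuse.

    The default attribute set for stratification is the single-residue
    frequencies plus all property-scale means (``k_max=1``): at the sample
    sizes this toolkit targets, longer subsequence vocabularies overfit the
    fold classifiers and blur the classifiable/unclassifiable boundary.
    """
    feats = interpretable_feature_matrix(
        [(p.peptide_id, p.sequence) for p in peptides], k_max=k_max
    )
    labels = [p.label for p in peptides]
    part = partition_by_classifiability(feats, labels, folds=folds, seed=seed)
    types = assign_ear_types(part, {p.peptide_id: p.label for p in peptides})
    return part, types, feats
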