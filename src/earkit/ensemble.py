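"""Stacked ensemble epitope prediction over eight peptide representations.

Each peptide is represented by the eight attribute families; one base
classifier per family is trained on oversample-balanced data and returns the
probability that the peptide contains an epitope.  The eight probabilities
form a meta attribute vector, assigned to every training peptide through
5-fold cross-validation (a peptide is only scored by base models that never
saw it), on which a meta-classifier computes the final probability.  The
meta-classifier can be trained on the original class ratio or on balanced
rows.

Base and meta algorithms default to regularized logistic regression (with
standardization); any scikit-learn style probability classifier can be
substituted per family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, StratificationError
from .features import (
    AttributeFamilySpec,
    FeatureMatrix,
    build_feature_matrix,
    default_family_specs,
)
from .peptide_io import BINDING, LabeledPeptide

EstimatorFactory = Callable[[], object]


def default_algorithm() -> object:
    """Standardized L2 logistic regression, the default base/meta learner."""
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, C=1.0),
    )


@dataclass
class BaseModel:
    """One fitted base classifier consuming one attribute family."""

    family_id: int
    spec: AttributeFamilySpec
    algorithm: str
    estimator: object
    oversample_seed: int

    def predict_proba_binding(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]


@dataclass
class MetaFeatures:
    """Out-of-fold base probabilities: the meta attribute vectors."""

    peptide_ids: List[str]
    matrix: np.ndarray  # n x 8 probabilities
    fold_assignment: np.ndarray  # n integers in 0..folds-1
    folds: int
    seed: int


@dataclass
class EnsembleModel:
    """Eight fitted base models plus the meta-classifier over their outputs."""

    base_models: List[BaseModel]
    meta_model: object
    meta_training_mode: str
    seed: int


def _labels_to_binary(train: Sequence[LabeledPeptide]) -> np.ndarray:
    return np.array([1 if p.label == BINDING else 0 for p in train])


def oversample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row indices keeping every row and duplicating uniformly chosen minority
    rows (with replacement) until both classes have the majority count."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise StratificationError("oversampling requires both classes")
    small, big = (idx1, idx0) if len(idx1) < len(idx0) else (idx0, idx1)
    if len(small) == len(big):
        return np.arange(len(y))
    extra = rng.choice(small, size=len(big) - len(small), replace=True)
    return np.concatenate([np.arange(len(y)), extra])


def _family_matrices(
    peptides: Sequence[LabeledPeptide], specs: Sequence[AttributeFamilySpec]
) -> List[FeatureMatrix]:
    pairs = [(p.peptide_id, p.sequence) for p in peptides]
    return [build_feature_matrix(pairs, spec) for spec in specs]


def build_meta_features(
    train: Sequence[LabeledPeptide],
    specs: Optional[Sequence[AttributeFamilySpec]] = None,
    algorithms: Optional[Dict[int, EstimatorFactory]] = None,
    folds: int = 5,
    seed: int = 0,
) -> MetaFeatures:
    """Out-of-fold base-classifier probabilities for every training peptide.

    The training set is split into *folds* class-stratified subsets; for each
    held-out subset the eight base classifiers are trained on the remaining
    folds (oversample-balanced) and probabilities estimated for the held-out
    peptides.
    """
    specs = list(specs) if specs is not None else default_family_specs()
    algorithms = algorithms or {}
    y = _labels_to_binary(train)
    n = len(train)
    if min(np.sum(y == 0), np.sum(y == 1)) < folds:
        raise StratificationError(
            f"need at least {folds} peptides per class for {folds}-fold stacking"
        )
    mats = _family_matrices(train, specs)
    matrix = np.full((n, len(specs)), np.nan)
    fold_assignment = np.empty(n, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    rng = np.random.default_rng(seed)
    for fold_no, (fit_idx, held_idx) in enumerate(skf.split(np.zeros(n), y)):
        fold_assignment[held_idx] = fold_no
        y_fit = y[fit_idx]
        if y_fit.min() == y_fit.max():
            raise StratificationError(f"fold {fold_no}: training part lacks a class")
        os_rows = oversample_indices(y_fit, rng)
        for j, spec in enumerate(specs):
            factory = algorithms.get(spec.family_id, default_algorithm)
            est = factory()
            X = mats[j].values
            est.fit(X[fit_idx][os_rows], y_fit[os_rows])
            proba = est.predict_proba(X[held_idx])
            classes = list(est.classes_)
            matrix[held_idx, j] = proba[:, classes.index(1)]
    return MetaFeatures(
        peptide_ids=[p.peptide_id for p in train],
        matrix=matrix,
        fold_assignment=fold_assignment,
        folds=folds,
        seed=seed,
    )


def train_ensemble(
    train: Sequence[LabeledPeptide],
    meta: MetaFeatures,
    specs: Optional[Sequence[AttributeFamilySpec]] = None,
    algorithms: Optional[Dict[int, EstimatorFactory]] = None,
    meta_algorithm: Optional[EstimatorFactory] = None,
    meta_training_mode: str = "original",
    seed: int = 0,
) -> EnsembleModel:
    """Refit the eight base models on the full oversampled training set and
    fit the meta-classifier on the out-of-fold meta features.

    ``meta_training_mode="original"`` keeps the training class ratio for the
    meta-classifier; ``"balanced"`` oversamples its rows to parity.
    """
    if meta_training_mode not in ("original", "balanced"):
        raise ConfigurationError(f"unknown meta_training_mode {meta_training_mode!r}")
    if meta.peptide_ids != [p.peptide_id for p in train]:
        raise ConfigurationError("meta features were built on different peptides")
    specs = list(specs) if specs is not None else default_family_specs()
    algorithms = algorithms or {}
    y = _labels_to_binary(train)
    rng = np.random.default_rng(seed)
    mats = _family_matrices(train, specs)
    os_rows = oversample_indices(y, rng)

    base_models: List[BaseModel] = []
    for j, spec in enumerate(specs):
        factory = algorithms.get(spec.family_id, default_algorithm)
        est = factory()
        est.fit(mats[j].values[os_rows], y[os_rows])
        base_models.append(
            BaseModel(
                family_id=spec.family_id,
                spec=spec,
                algorithm=type(est).__name__,
                estimator=est,
                oversample_seed=seed,
            )
        )

    meta_est = (meta_algorithm or default_algorithm)()
    if meta_training_mode == "balanced":
        rows = oversample_indices(y, rng)
    else:
        rows = np.arange(len(y))
    meta_est.fit(meta.matrix[rows], y[rows])
    return EnsembleModel(
        base_models=base_models,
        meta_model=meta_est,
        meta_training_mode=meta_training_mode,
        seed=seed,
    )


def ensemble_meta_vectors(
    model: EnsembleModel, peptides: Sequence[Tuple[str, str]]
) -> np.ndarray:
    """The n x 8 base-probability matrix for new ``(id, sequence)`` peptides."""
    vectors = np.empty((len(peptides), len(model.base_models)))
    for j, bm in enumerate(model.base_models):
        X = build_feature_matrix(peptides, bm.spec).values
        vectors[:, j] = bm.predict_proba_binding(X)
    return vectors


def predict_ensemble(
    model: EnsembleModel,
    peptides: Sequence[Tuple[str, str]],
    cutoff: float = 0.5,
) -> Tuple[np.ndarray, List[str]]:
    """Final epitope probabilities and labels (binding iff probability > cutoff)."""
    meta_vectors = ensemble_meta_vectors(model, peptides)
    proba = model.meta_model.predict_proba(meta_vectors)
    classes = list(model.meta_model.classes_)
    p = proba[:, classes.index(1)]
    labels = [BINDING if v > cutoff else "non-binding" for v in p]
    return p, labels
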