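"""Uniform classifier contract with stratified cross-validation.

Learner internals are delegated to scikit-learn; the harness contributes
the fixed fold protocol (folds depend only on the labels and the seed, so
every feature scheme is compared on identical partitions), out-of-fold
prediction aggregation, and training-time bookkeeping.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import TrainingDataset

logger = logging.getLogger(__name__)

__all__ = ["CLASSIFIER_KINDS", "ClassifierSpec", "FoldPredictions", "make_estimator", "train_and_predict_cv"]

CLASSIFIER_KINDS = ("NB", "SVM", "KNN", "DT", "RF")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with hyperparameters and a recorded seed.

    Defaults: NB = multinomial event model on counts; SVM = linear kernel,
    one-vs-rest, margin scores; KNN = 3 neighbours, Euclidean distance;
    DT = entropy-split decision tree; RF = 100 trees with sqrt(p) features
    per split.
    """

    kind: str
    hyperparameters: tuple = ()
    random_seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}")
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(self, "hyperparameters", tuple(sorted(self.hyperparameters.items())))

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


def make_estimator(spec: ClassifierSpec):
    params = spec.params
    seed = spec.random_seed
    if spec.kind == "NB":
        return MultinomialNB(**params)
    if spec.kind == "SVM":
        params.setdefault("C", 1.0)
        params.setdefault("max_iter", 10000)
        return LinearSVC(random_state=seed, **params)
    if spec.kind == "KNN":
        params.setdefault("n_neighbors", 3)
        params.setdefault("metric", "euclidean")
        return KNeighborsClassifier(**params)
    if spec.kind == "DT":
        params.setdefault("criterion", "entropy")
        return DecisionTreeClassifier(random_state=seed, **params)
    if spec.kind == "RF":
        params.setdefault("n_estimators", 100)
        params.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=seed, **params)
    raise AssertionError(spec.kind)


@dataclass
class FoldPredictions:
    """Aggregated out-of-fold predictions for one dataset + classifier."""

    report_ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    scores: np.ndarray  # reports x classes, aligned with `classes`
    classes: tuple[str, ...]
    fold_index: np.ndarray
    train_time_seconds: float
    probabilistic: bool
    spec: ClassifierSpec = field(default=None)  # type: ignore[assignment]


def fold_assignment(labels: Sequence[str], folds: int, seed: int) -> np.ndarray:
    """Stratified fold index per report — a function of (labels, folds, seed) only."""
    y = np.asarray(list(labels))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = i
    return assignment


def _effective_folds(labels: Sequence[str], folds: int) -> int:
    counts = np.unique(np.asarray(list(labels)), return_counts=True)[1]
    smallest = int(counts.min())
    if smallest < 2:
        raise ValueError(
            "a class has a single instance; stratified cross-validation is impossible "
            "(regenerate or enlarge the corpus)"
        )
    if smallest < folds:
        logger.warning("smallest class has %d instances; reducing folds from %d", smallest, folds)
        return smallest
    return folds


def train_and_predict_cv(
    dataset: TrainingDataset,
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int = 0,
) -> FoldPredictions:
    """Stratified k-fold cross-validation returning out-of-fold predictions.

    Per-class scores are predicted probabilities where the learner provides
    them, otherwise one-vs-rest decision margins (rank-based AUC only needs
    scores, not probabilities).
    """
    y = np.asarray(dataset.labels)
    folds = _effective_folds(y, folds)
    assignment = fold_assignment(y, folds, seed)
    classes = tuple(sorted(set(dataset.labels)))
    class_pos = {c: i for i, c in enumerate(classes)}
    scores = np.zeros((len(y), len(classes)))
    y_pred = np.empty(len(y), dtype=object)
    train_time = 0.0
    probabilistic = True
    for f in range(folds):
        test = assignment == f
        train = ~test
        est = make_estimator(spec)
        t0 = time.perf_counter()
        est.fit(dataset.X[train], y[train])
        train_time += time.perf_counter() - t0
        y_pred[test] = est.predict(dataset.X[test])
        if hasattr(est, "predict_proba"):
            block = est.predict_proba(dataset.X[test])
        else:
            probabilistic = False
            raw = est.decision_function(dataset.X[test])
            if raw.ndim == 1:  # binary: margin for classes_[1]
                raw = np.column_stack([-raw, raw])
            block = raw
        for c_local, cls in enumerate(est.classes_):
            scores[test, class_pos[cls]] = block[:, c_local]
    return FoldPredictions(
        report_ids=list(dataset.report_ids) or [str(i) for i in range(len(y))],
        y_true=list(dataset.labels),
        y_pred=list(y_pred),
        scores=scores,
        classes=classes,
        fold_index=assignment,
        train_time_seconds=train_time,
        probabilistic=probabilistic,
        spec=spec,
    )
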