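"""Evaluation metrics, the experiment grid, and the sample-size sweep.

Metrics follow the macro-averaged multiclass conventions: per-class
precision and recall averaged with equal class weights, the F-measure of
the macro averages, and two accuracies — the plain fraction of correct
predictions (trace accuracy) and the per-class averaged accuracy that
also credits true negatives (reported as ``accuracy_avg_paper``; for more
than two classes it is inflated relative to trace accuracy and the two
are kept side by side).  Per-class AUC is the Hand–Till rank formulation,
one-vs-rest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import ClassifierSpec, FoldPredictions, train_and_predict_cv
from .dataset import TrainingDataset
from .expert import ExpertFeatureSet, build_class_score_dataset
from .preprocess import MasterFeatureVector, ProcessedReport, build_master_feature_vector
from .selection import (
    RankedFeatureList,
    build_bow_dataset,
    emffs_rank_aggregation,
    score_chi_square,
    score_fms,
    score_igfs,
    score_information_gain,
    score_pearson,
    select_top_k,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "EvaluationResult",
    "macro_precision",
    "macro_recall",
    "macro_f_measure",
    "accuracy_avg",
    "trace_accuracy",
    "hand_till_auc",
    "evaluate_predictions",
    "DEFAULT_SCHEMES",
    "DEFAULT_SUBSET_SIZES",
    "DEFAULT_CLASSIFIERS",
    "grid_cells",
    "run_experiment_grid",
    "sample_size_sweep",
]

DEFAULT_SCHEMES: tuple[str, ...] = ("expert", "info_gain", "chi_square", "pearson", "fms", "igfs")
DEFAULT_SUBSET_SIZES: tuple = (10, 20, 30, 40, "all")
DEFAULT_CLASSIFIERS: tuple[str, ...] = ("NB", "SVM", "KNN", "DT", "RF")

_SCORERS = {
    "info_gain": score_information_gain,
    "chi_square": score_chi_square,
    "pearson": score_pearson,
    "fms": score_fms,
    "igfs": score_igfs,
    "emffs": emffs_rank_aggregation,
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted."""

    matrix: np.ndarray
    classes: tuple[str, ...]

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] | None = None
    ) -> "ConfusionMatrix":
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        pos = {c: i for i, c in enumerate(classes)}
        m = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            m[pos[t], pos[p]] += 1
        return cls(matrix=m, classes=tuple(classes))

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix).astype(float)

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fp - self.fn


def _safe_ratio(num: np.ndarray, den: np.ndarray, context: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    if not ok.all():
        logger.warning("%s: %d class(es) with empty denominator contribute 0", context, int((~ok).sum()))
    out[ok] = num[ok] / den[ok]
    return out


def macro_precision(cm: ConfusionMatrix) -> float:
    """Unweighted mean over classes of TP / (TP + FP)."""
    return float(_safe_ratio(cm.tp, cm.tp + cm.fp, "macro_precision").mean())


def macro_recall(cm: ConfusionMatrix) -> float:
    """Unweighted mean over classes of TP / (TP + FN)."""
    return float(_safe_ratio(cm.tp, cm.tp + cm.fn, "macro_recall").mean())


def macro_f_measure(precision: float, recall: float, beta: float = 1.0) -> float:
    """Weighted harmonic combination (beta^2 + 1) * P * R / (beta^2 * P + R).

    beta > 1 weights recall more heavily; beta = 1 is the plain harmonic
    mean of the macro precision and recall.  Returns 0 when P + R = 0.
    """
    if precision + recall == 0:
        return 0.0
    return (beta**2 + 1) * recall * precision / (beta**2 * precision + recall)


def accuracy_avg(cm: ConfusionMatrix) -> float:
    """Per-class accuracy including true negatives, averaged over classes.

    For two classes this coincides with trace accuracy; beyond that the
    true-negative term inflates it, so report it alongside
    :func:`trace_accuracy` rather than instead of it.
    """
    per_class = (cm.tp + cm.tn) / cm.total
    return float(per_class.mean())


def trace_accuracy(cm: ConfusionMatrix) -> float:
    """Plain fraction of correctly classified reports."""
    return float(cm.tp.sum() / cm.total)


def hand_till_auc(scores: Sequence[float], labels: Sequence[str], positive_class: str) -> float:
    """One-vs-rest rank AUC: (S0 - n0(n0+1)/2) / (n0 * n1).

    Scores are ranked ascending with mid-ranks for ties; S0 is the rank sum
    of the positive examples.  Equivalent to the tie-corrected Mann–Whitney
    statistic.  Returns NaN when either group is empty.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray([lab == positive_class for lab in labels])
    n0, n1 = int(pos.sum()), int((~pos).sum())
    if n0 == 0 or n1 == 0:
        return float("nan")
    ranks = rankdata(scores, method="average")
    s0 = ranks[pos].sum()
    return float((s0 - n0 * (n0 + 1) / 2) / (n0 * n1))


@dataclass(frozen=True)
class EvaluationResult:
    """Macro metrics, both accuracies, per-class AUC and training time."""

    precision_m: float
    recall_m: float
    f_measure_m: float
    accuracy_avg_paper: float
    accuracy: float
    per_class_auc: Mapping[str, float]
    training_time_seconds: float
    beta: float = 1.0

    @property
    def mean_auc(self) -> float:
        vals = [v for v in self.per_class_auc.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_class_auc"] = dict(self.per_class_auc)
        d["mean_auc"] = self.mean_auc
        return d


def evaluate_predictions(pred: FoldPredictions, beta: float = 1.0) -> EvaluationResult:
    cm = ConfusionMatrix.from_predictions(pred.y_true, pred.y_pred, pred.classes)
    p = macro_precision(cm)
    r = macro_recall(cm)
    auc = {
        cls: hand_till_auc(pred.scores[:, j], pred.y_true, cls)
        for j, cls in enumerate(pred.classes)
    }
    return EvaluationResult(
        precision_m=p,
        recall_m=r,
        f_measure_m=macro_f_measure(p, r, beta),
        accuracy_avg_paper=accuracy_avg(cm),
        accuracy=trace_accuracy(cm),
        per_class_auc=auc,
        training_time_seconds=pred.train_time_seconds,
        beta=beta,
    )


def grid_cells(
    schemes: Sequence[str] = DEFAULT_SCHEMES,
    sizes: Sequence = DEFAULT_SUBSET_SIZES,
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
) -> list[tuple[str, object, str]]:
    """Enumerate the (scheme, subset size, classifier) cross-product."""
    return [(s, k, c) for s in schemes for k in sizes for c in classifiers]


def _dataset_for_cell(
    scheme: str,
    k,
    corpus: Sequence[ProcessedReport],
    lexicons: Sequence[ExpertFeatureSet] | None,
    M: MasterFeatureVector,
    rankings: dict[str, RankedFeatureList],
) -> TrainingDataset:
    if scheme == "expert":
        if lexicons is None:
            raise ValueError("expert scheme requires lexicons")
        return build_class_score_dataset(corpus, lexicons, k)
    if scheme == "bow":
        return build_bow_dataset(corpus, M, None, scheme="bow", k="all")
    if scheme not in _SCORERS:
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme not in rankings:
        rankings[scheme] = _SCORERS[scheme](M, corpus)
    subset = select_top_k(rankings[scheme], k)
    return build_bow_dataset(corpus, M, subset, scheme=scheme, k=k)


@dataclass
class GridResult:
    """Results of the experiment grid, indexed by (scheme, size, classifier)."""

    cells: dict[tuple[str, object, str], EvaluationResult] = field(default_factory=dict)
    failures: dict[tuple[str, object, str], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (cell, metric)."""
        rows = []
        for (scheme, k, clf), res in sorted(self.cells.items(), key=lambda kv: str(kv[0])):
            base = {"scheme": scheme, "size": str(k), "classifier": clf}
            for metric in ("precision_m", "recall_m", "f_measure_m", "accuracy_avg_paper", "accuracy"):
                rows.append({**base, "metric": metric, "value": getattr(res, metric)})
            rows.append({**base, "metric": "mean_auc", "value": res.mean_auc})
            rows.append({**base, "metric": "training_time_seconds", "value": res.training_time_seconds})
        return pd.DataFrame(rows)


def _cell_key_str(scheme: str, k, clf: str) -> str:
    return f"{scheme}|{k}|{clf}"


def run_experiment_grid(
    corpus: Sequence[ProcessedReport],
    lexicons: Sequence[ExpertFeatureSet] | None = None,
    schemes: Sequence[str] = DEFAULT_SCHEMES,
    sizes: Sequence = DEFAULT_SUBSET_SIZES,
    classifier_specs: Sequence[ClassifierSpec] | Sequence[str] = DEFAULT_CLASSIFIERS,
    folds: int = 10,
    seed: int = 0,
    rare_threshold: int = 2,
    out_path=None,
) -> GridResult:
    """Run the full (scheme x subset size x classifier) experiment grid.

    All cells share the same stratified folds (the partition depends only
    on the labels and the seed).  With ``out_path`` each finished cell is
    appended to a JSON-lines file and already-present cells are skipped on
    rerun, so interrupted grids resume.  Per-cell failures are recorded and
    the grid continues.
    """
    specs = [
        s if isinstance(s, ClassifierSpec) else ClassifierSpec(kind=s, random_seed=seed)
        for s in classifier_specs
    ]
    M = build_master_feature_vector(corpus, rare_threshold=rare_threshold)
    rankings: dict[str, RankedFeatureList] = {}
    result = GridResult()
    done: dict[str, dict] = {}
    if out_path is not None and Path(out_path).exists():
        for line in Path(out_path).read_text(encoding="utf-8").splitlines():
            if line.strip():
                rec = json.loads(line)
                done[rec["cell"]] = rec
    out_fh = open(out_path, "a", encoding="utf-8") if out_path is not None else None
    try:
        for scheme in schemes:
            for k in sizes:
                try:
                    dataset = _dataset_for_cell(scheme, k, corpus, lexicons, M, rankings)
                except Exception as exc:  # noqa: BLE001 — grid must continue
                    for spec in specs:
                        result.failures[(scheme, k, spec.kind)] = str(exc)
                    logger.error("scheme=%s k=%s: dataset build failed: %s", scheme, k, exc)
                    continue
                for spec in specs:
                    key = (scheme, k, spec.kind)
                    cell_id = _cell_key_str(*key)
                    if cell_id in done:
                        rec = done[cell_id]
                        result.cells[key] = EvaluationResult(**rec["result"])
                        continue
                    try:
                        pred = train_and_predict_cv(dataset, spec, folds=folds, seed=seed)
                        res = evaluate_predictions(pred)
                    except Exception as exc:  # noqa: BLE001
                        result.failures[key] = str(exc)
                        logger.error("cell %s failed: %s", cell_id, exc)
                        continue
                    result.cells[key] = res
                    if out_fh is not None:
                        rec = {"cell": cell_id, "result": dataclasses.asdict(res)}
                        out_fh.write(json.dumps(rec) + "\n")
                        out_fh.flush()
    finally:
        if out_fh is not None:
            out_fh.close()
    return result


def sample_size_sweep(
    generator_config,
    sizes_per_class: Sequence[int],
    spec: ClassifierSpec | str = "RF",
    scheme: str = "expert",
    k: int | str = "all",
    folds: int = 10,
) -> pd.DataFrame:
    """Learning curve: regenerate the corpus at each per-class size and evaluate.

    Returns a table of (n_per_class, accuracy, macro F) for the given
    scheme and classifier; the default mirrors the usual protocol of the
    expert scheme with all lexicon entries and a random forest.
    """
    from .synthetic import generate_corpus  # local import to avoid a cycle
    from .preprocess import preprocess_corpus

    if not isinstance(spec, ClassifierSpec):
        spec = ClassifierSpec(kind=spec, random_seed=generator_config.seed)
    rows = []
    for n in sizes_per_class:
        config = generator_config.with_per_class_size(n)
        reports, lexicons = generate_corpus(config)
        corpus = preprocess_corpus(reports, dictionary=config.dictionary_words())
        M = build_master_feature_vector(corpus)
        rankings: dict[str, RankedFeatureList] = {}
        dataset = _dataset_for_cell(scheme, k, corpus, lexicons, M, rankings)
        pred = train_and_predict_cv(dataset, spec, folds=folds, seed=config.seed)
        res = evaluate_predictions(pred)
        rows.append(
            {
                "n_per_class": n,
                "accuracy": res.accuracy,
                "f_measure_m": res.f_measure_m,
                "mean_auc": res.mean_auc,
            }
        )
    return pd.DataFrame(rows)
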