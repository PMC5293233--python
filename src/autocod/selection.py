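"""Automated filter feature selection over the master feature vector.

Five ranking schemes — information gain, chi-square, Pearson correlation,
the Fisher–Markov selector specialized to the linear kernel, and IGFS
(information gain globally, one-sided odds ratio locally) — plus gain
ratio and the EMFFS mean-rank fusion baseline.  Each scheme returns a
complete, strictly ranked ordering of the vocabulary; top-k subsets are
prefixes of that ordering.

Conventions: information gain, chi-square, gain ratio and odds ratio work
on document-level presence/absence tables; Pearson and the Fisher–Markov
criterion use the per-report occurrence-count vectors.  Entropies are in
bits.  Ties always break alphabetically on the rendered feature name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import TrainingDataset
from .preprocess import MasterFeatureVector, ProcessedReport, TaggedToken

logger = logging.getLogger(__name__)

__all__ = [
    "RankedFeatureList",
    "count_matrix",
    "score_information_gain",
    "score_chi_square",
    "score_pearson",
    "score_fms",
    "score_igfs",
    "score_gain_ratio",
    "emffs_rank_aggregation",
    "select_top_k",
    "build_bow_dataset",
]


@dataclass(frozen=True)
class RankedFeatureList:
    """A scored, strictly ranked permutation of the vocabulary."""

    scheme: str
    scores: Mapping[str, float]
    order: tuple[str, ...]

    def __post_init__(self):
        if set(self.order) != set(self.scores):
            raise ValueError("order must be a permutation of the scored features")

    def top(self, k: int | str) -> tuple[str, ...]:
        return select_top_k(self, k)

    def rank_of(self, feature: str) -> int:
        """1-based rank."""
        return self.order.index(feature) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.order),
                "scheme": self.scheme,
                "score": [self.scores[f] for f in self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def _ranked(scheme: str, names: Sequence[str], scores: np.ndarray) -> RankedFeatureList:
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return RankedFeatureList(
        scheme=scheme,
        scores={n: float(s) for n, s in zip(names, scores)},
        order=tuple(names[i] for i in order),
    )


def count_matrix(
    corpus: Sequence[ProcessedReport], M: MasterFeatureVector
) -> tuple[np.ndarray, list[str]]:
    """Reports x vocabulary occurrence-count matrix, columns in M's order."""
    index = {tok: j for j, tok in enumerate(M.vocabulary)}
    X = np.zeros((len(corpus), len(M.vocabulary)))
    for i, rep in enumerate(corpus):
        for tok, n in rep.tokens.items():
            j = index.get(tok)
            if j is not None:
                X[i, j] = n
    return X, M.rendered()


def _labels(corpus: Sequence[ProcessedReport], labels) -> np.ndarray:
    y = np.asarray([r.label for r in corpus] if labels is None else list(labels))
    if len(y) != len(corpus):
        raise ValueError("labels length mismatch")
    return y


def entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a vector of non-negative counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _class_presence_table(present: np.ndarray, y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """2 x C table: row 0 = reports containing the feature, row 1 = not."""
    table = np.zeros((2, len(classes)))
    for c, cls in enumerate(classes):
        mask = y == cls
        table[0, c] = np.count_nonzero(present & mask)
        table[1, c] = np.count_nonzero(~present & mask)
    return table


def score_information_gain(
    M: MasterFeatureVector, corpus: Sequence[ProcessedReport], labels=None
) -> RankedFeatureList:
    """Reduction in class entropy from splitting reports on feature presence.

    Generalizes the binary-class definition to C classes:
    I = -sum_c p_c log2 p_c; gain = I - sum over {present, absent} branches
    of (branch size / n) * branch entropy.
    """
    X, names = count_matrix(corpus, M)
    y = _labels(corpus, labels)
    classes = np.unique(y)
    if len(classes) < 2:
        logger.warning("single-class corpus: information gain is 0 everywhere")
        return _ranked("info_gain", names, np.zeros(len(names)))
    base = entropy(np.array([(y == c).sum() for c in classes]))
    n = len(y)
    scores = np.zeros(len(names))
    for j in range(X.shape[1]):
        table = _class_presence_table(X[:, j] > 0, y, classes)
        after = sum(
            (row.sum() / n) * entropy(row) for row in table if row.sum() > 0
        )
        scores[j] = base - after
    return _ranked("info_gain", names, scores)


def score_chi_square(
    M: MasterFeatureVector, corpus: Sequence[ProcessedReport], labels=None
) -> RankedFeatureList:
    """Chi-square statistic of the feature-presence x class contingency table.

    Expected counts come from the marginal products; a cell with zero
    expected count contributes 0.
    """
    X, names = count_matrix(corpus, M)
    y = _labels(corpus, labels)
    classes = np.unique(y)
    n = len(y)
    scores = np.zeros(len(names))
    for j in range(X.shape[1]):
        O = _class_presence_table(X[:, j] > 0, y, classes)
        E = np.outer(O.sum(axis=1), O.sum(axis=0)) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.where(E > 0, (O - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
        scores[j] = cells.sum()
    return _ranked("chi_square", names, scores)


def score_pearson(
    M: MasterFeatureVector, corpus: Sequence[ProcessedReport], labels=None
) -> RankedFeatureList:
    """Max over classes of |Pearson r| between feature counts and the
    one-vs-rest class indicator.  Zero-variance features score 0."""
    X, names = count_matrix(corpus, M)
    y = _labels(corpus, labels)
    classes = np.unique(y)
    scores = np.zeros(len(names))
    for j in range(X.shape[1]):
        x = X[:, j]
        if np.ptp(x) == 0:
            continue
        best = 0.0
        for cls in classes:
            ind = (y == cls).astype(float)
            if np.ptp(ind) == 0:
                continue
            r = np.corrcoef(x, ind)[0, 1]
            best = max(best, abs(float(r)))
        scores[j] = best
    return _ranked("pearson", names, scores)


def score_fms(
    M: MasterFeatureVector,
    corpus: Sequence[ProcessedReport],
    labels=None,
    gamma: float = 0.0,
) -> RankedFeatureList:
    """Fisher–Markov selector with linear kernel (degree 1).

    Under the linear kernel the criterion decomposes coordinate-wise, so
    each feature is scored independently by a Fisher-type ratio of
    between-class scatter to pooled within-class scatter of its count
    vector; ``gamma`` regularizes the denominator.  If every feature has
    zero within-class scatter the ordering falls back to between-class
    scatter alone.
    """
    X, names = count_matrix(corpus, M)
    y = _labels(corpus, labels)
    classes = np.unique(y)
    if len(classes) < 2:
        logger.warning("single-class corpus: FMS scores are 0 everywhere")
        return _ranked("fms", names, np.zeros(len(names)))
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for cls in classes:
        block = X[y == cls]
        mu = block.mean(axis=0)
        between += len(block) * (mu - grand) ** 2
        within += ((block - mu) ** 2).sum(axis=0)
    denom = within + gamma
    if np.all(denom == 0):
        logger.warning("all features degenerate (zero within-class scatter); ranking by between-class scatter")
        return _ranked("fms", names, between)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0, between / np.where(denom > 0, denom, 1.0), np.inf)
    scores = np.where((denom == 0) & (between == 0), 0.0, scores)
    return _ranked("fms", names, scores)


def _odds_ratios(present: np.ndarray, y: np.ndarray, cls) -> float:
    """Haldane-smoothed one-vs-rest odds ratio of feature presence for a class."""
    pos = y == cls
    a = np.count_nonzero(present & pos) + 0.5
    b = np.count_nonzero(~present & pos) + 0.5
    c = np.count_nonzero(present & ~pos) + 0.5
    d = np.count_nonzero(~present & ~pos) + 0.5
    return float((a * d) / (b * c))


def score_igfs(
    M: MasterFeatureVector,
    corpus: Sequence[ProcessedReport],
    labels=None,
    k: int | str = "all",
) -> RankedFeatureList:
    """IGFS: information gain globally, one-sided odds ratio locally.

    Features are ranked globally by information gain; the final ordering is
    then built class-by-class in round-robin, each class contributing its
    highest-gain feature whose smoothed one-vs-rest odds ratio exceeds 1
    (i.e. positively associated with that class), so every class is
    represented in any top-k prefix when possible.  Features positive for
    no class are appended in global-gain order.
    """
    ig = score_information_gain(M, corpus, labels)
    X, names = count_matrix(corpus, M)
    y = _labels(corpus, labels)
    classes = sorted(np.unique(y))
    name_to_col = {n: j for j, n in enumerate(names)}
    # per class: candidate features positively associated, in global IG order
    queues: dict[str, list[str]] = {}
    for cls in classes:
        q = []
        for feat in ig.order:
            present = X[:, name_to_col[feat]] > 0
            if _odds_ratios(present, y, cls) > 1.0:
                q.append(feat)
        if not q:
            logger.warning("IGFS: class %s has no positively associated feature", cls)
        queues[cls] = q
    order: list[str] = []
    chosen: set[str] = set()
    progressed = True
    while progressed and len(order) < len(names):
        progressed = False
        for cls in classes:
            q = queues[cls]
            while q and q[0] in chosen:
                q.pop(0)
            if q:
                feat = q.pop(0)
                order.append(feat)
                chosen.add(feat)
                progressed = True
    for feat in ig.order:  # leftovers keep their global ranking
        if feat not in chosen:
            order.append(feat)
            chosen.add(feat)
    n = len(order)
    scores = {feat: float(n - i) for i, feat in enumerate(order)}
    return RankedFeatureList(scheme="igfs", scores=scores, order=tuple(order))


def score_gain_ratio(
    M: MasterFeatureVector, corpus: Sequence[ProcessedReport], labels=None
) -> RankedFeatureList:
    """Information gain normalized by the split information of the
    presence/absence partition; zero split information scores 0."""
    ig = score_information_gain(M, corpus, labels)
    X, names = count_matrix(corpus, M)
    scores = np.zeros(len(names))
    for j, name in enumerate(names):
        present = int((X[:, j] > 0).sum())
        split_info = entropy(np.array([present, X.shape[0] - present]))
        scores[j] = ig.scores[name] / split_info if split_info > 0 else 0.0
    return _ranked("gain_ratio", names, scores)


def emffs_rank_aggregation(
    M: MasterFeatureVector, corpus: Sequence[ProcessedReport], labels=None
) -> RankedFeatureList:
    """Ensemble multi-filter feature selection (EMFFS) baseline.

    Fuses the chi-square, information-gain, Pearson and gain-ratio rank
    lists by mean rank (Borda aggregation); lower mean rank is better and
    ties break alphabetically.  The stored score is the negated mean rank
    so that higher still means better.
    """
    constituents = [
        score_chi_square(M, corpus, labels),
        score_information_gain(M, corpus, labels),
        score_pearson(M, corpus, labels),
        score_gain_ratio(M, corpus, labels),
    ]
    names = constituents[0].order
    mean_rank = {
        feat: float(np.mean([c.rank_of(feat) for c in constituents])) for feat in names
    }
    scores = np.array([-mean_rank[f] for f in names])
    return _ranked("emffs", list(names), scores)


def select_top_k(ranking: RankedFeatureList, k: int | str) -> tuple[str, ...]:
    """Prefix of the tie-broken ranking; ``'all'`` returns the whole vocabulary."""
    if k == "all":
        return ranking.order
    if not isinstance(k, int) or k < 1:
        raise ValueError(f"k must be a positive integer or 'all', got {k!r}")
    if k > len(ranking.order):
        logger.warning("k=%d exceeds vocabulary size %d; clamping", k, len(ranking.order))
        k = len(ranking.order)
    return ranking.order[:k]


def build_bow_dataset(
    corpus: Sequence[ProcessedReport],
    M: MasterFeatureVector,
    subset: Sequence[str] | None = None,
    *,
    scheme: str = "bow",
    k: int | str = "all",
) -> TrainingDataset:
    """Occurrence-count matrix over a feature subset (bag-of-words rows).

    ``subset`` entries are rendered ``surface/Tag`` names and must belong to
    the master vocabulary; None uses the full vocabulary.
    """
    rendered = M.rendered()
    if subset is None:
        subset = rendered
    else:
        unknown = sorted(set(subset) - set(rendered))
        if unknown:
            raise ValueError(f"features outside master vocabulary: {unknown[:5]}")
    tokens = [TaggedToken.parse(name) for name in subset]
    X = np.zeros((len(corpus), len(tokens)))
    for i, rep in enumerate(corpus):
        for j, tok in enumerate(tokens):
            X[i, j] = rep.tokens.get(tok, 0)
    labels = [r.label for r in corpus]
    return TrainingDataset(
        attributes=list(subset),
        X=X,
        labels=labels,
        classes=tuple(sorted(set(labels))),
        report_ids=[r.report_id for r in corpus],
        provenance={"scheme": scheme, "k": k},
    )
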