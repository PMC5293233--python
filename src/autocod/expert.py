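"""Expert-driven feature selection: per-class ranked lexicons with synonyms.

The central idea: instead of ranking thousands of corpus tokens, each
cause-of-death class gets a short expert-authored lexicon of discriminative
terms, each term carrying a synonym group (pathologists use e.g.
"abrasion", "graze" and "trauma" interchangeably).  A report is then
represented by a single non-negative integer per class — the total number
of its tokens matching any term or synonym among the class's top-k ranked
entries — so the training set has exactly as many attributes as classes,
regardless of vocabulary size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dataset import TrainingDataset
from .preprocess import ProcessedReport

__all__ = [
    "ExpertEntry",
    "ExpertFeatureSet",
    "load_expert_feature_sets",
    "save_expert_feature_sets",
    "expert_feature_weight",
    "build_class_score_dataset",
]


@dataclass(frozen=True)
class ExpertEntry:
    """One ranked lexicon entry: a canonical term plus interchangeable synonyms."""

    canonical: str
    synonyms: frozenset[str]
    rank: int

    def terms(self) -> frozenset[str]:
        return self.synonyms | {self.canonical}


@dataclass(frozen=True)
class ExpertFeatureSet:
    """Ranked discriminative-term lexicon for one ICD-10 class."""

    class_code: str
    entries: tuple[ExpertEntry, ...]

    def __post_init__(self):
        ranks = [e.rank for e in self.entries]
        if not self.entries:
            raise ValueError(f"{self.class_code}: empty entry list")
        if sorted(ranks) != list(range(1, len(ranks) + 1)):
            raise ValueError(f"{self.class_code}: ranks must be unique and contiguous 1..k, got {ranks}")
        seen: dict[str, int] = {}
        for e in self.entries:
            for term in e.terms():
                if term in seen and seen[term] != e.rank:
                    raise ValueError(
                        f"{self.class_code}: term {term!r} appears in entries ranked "
                        f"{seen[term]} and {e.rank}"
                    )
                seen[term] = e.rank

    def top(self, k: int | str) -> tuple[ExpertEntry, ...]:
        """The top-k entries by rank; ``k='all'`` returns every entry."""
        ordered = tuple(sorted(self.entries, key=lambda e: e.rank))
        if k == "all":
            return ordered
        if not isinstance(k, int) or k < 1:
            raise ValueError(f"k must be a positive integer or 'all', got {k!r}")
        return ordered[:k]


def save_expert_feature_sets(sets: Iterable[ExpertFeatureSet], path) -> None:
    docs = [
        {
            "class_code": s.class_code,
            "entries": [
                {"canonical": e.canonical, "synonyms": sorted(e.synonyms), "rank": e.rank}
                for e in sorted(s.entries, key=lambda e: e.rank)
            ],
        }
        for s in sets
    ]
    Path(path).write_text(json.dumps(docs, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def load_expert_feature_sets(path) -> list[ExpertFeatureSet]:
    """Load and validate a lexicon file (JSON list, one document per class).

    A missing ``synonyms`` key yields an empty synonym set; a missing
    ``rank`` defaults to list position.  Validation failures name the
    offending class.
    """
    docs = json.loads(Path(path).read_text(encoding="utf-8"))
    sets = []
    seen_codes: set[str] = set()
    for doc in docs:
        code = doc.get("class_code")
        if not code:
            raise ValueError(f"{path}: lexicon document without class_code")
        if code in seen_codes:
            raise ValueError(f"{path}: duplicate lexicon for class {code}")
        seen_codes.add(code)
        entries = []
        for pos, ent in enumerate(doc.get("entries", []), start=1):
            entries.append(
                ExpertEntry(
                    canonical=str(ent["canonical"]).lower(),
                    synonyms=frozenset(str(s).lower() for s in ent.get("synonyms", [])),
                    rank=int(ent.get("rank", pos)),
                )
            )
        try:
            sets.append(ExpertFeatureSet(class_code=code, entries=tuple(entries)))
        except ValueError as exc:
            raise ValueError(f"{path}: invalid lexicon for class {code}: {exc}") from exc
    return sets


def _count_term(sequence: Sequence[str], term: str) -> int:
    """Occurrences of a (possibly multi-word) term in an ordered surface stream."""
    words = term.split()
    if len(words) == 1:
        return sum(1 for w in sequence if w == words[0])
    n, span = 0, len(words)
    for i in range(len(sequence) - span + 1):
        if list(sequence[i : i + span]) == words:
            n += 1
    return n


def _report_sequence(report: ProcessedReport) -> Sequence[str]:
    if report.sequence:
        return report.sequence
    # fall back to the multiset when no ordered stream was retained
    seq: list[str] = []
    for tok, cnt in sorted(report.tokens.items()):
        seq.extend([tok.surface] * cnt)
    return seq


def expert_feature_weight(
    report: ProcessedReport,
    feature_set: ExpertFeatureSet,
    k: int | str = "all",
    *,
    binary: bool = False,
) -> int:
    """Total occurrence count of a class's top-k lexicon terms in a report.

    Matching is on the surface form (the lexical tag is ignored); synonyms
    count toward their entry's term.  With ``binary=True`` each entry
    contributes at most 1 (presence/absence instead of frequency).
    """
    sequence = _report_sequence(report)
    total = 0
    for entry in feature_set.top(k):
        hits = sum(_count_term(sequence, term) for term in sorted(entry.terms()))
        total += min(hits, 1) if binary else hits
    return total


def build_class_score_dataset(
    corpus: Sequence[ProcessedReport],
    sets: Sequence[ExpertFeatureSet],
    k: int | str = "all",
    *,
    binary: bool = False,
) -> TrainingDataset:
    """One row per report; one integer attribute per class (fixed class order).

    Every report label must be covered by a lexicon; reports matching no
    expert term anywhere get an all-zero row but are retained.
    """
    codes = [s.class_code for s in sets]
    uncovered = sorted({r.label for r in corpus} - set(codes))
    if uncovered:
        raise ValueError(f"no expert feature set for labels: {uncovered}")
    X = np.zeros((len(corpus), len(sets)), dtype=float)
    for i, rep in enumerate(corpus):
        for j, fs in enumerate(sets):
            X[i, j] = expert_feature_weight(rep, fs, k, binary=binary)
    return TrainingDataset(
        attributes=[f"expert_{c}" for c in codes],
        X=X,
        labels=[r.label for r in corpus],
        classes=tuple(sorted({r.label for r in corpus} | set(codes))),
        report_ids=[r.report_id for r in corpus],
        provenance={"scheme": "expert", "k": k, "binary": binary},
    )
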