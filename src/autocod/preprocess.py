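"""Report preprocessing and the corpus-wide master feature vector.

The pipeline applied to every report, in order: spell correction against a
supplied dictionary, lowercasing, sentence splitting and unigram
tokenization, stopword removal, and coarse lexical (part-of-speech)
tagging.  Purely numeric and punctuation tokens are dropped.  The surviving
``surface/Tag`` tokens of all reports, pruned of rare tokens, form the
master feature vector: the vocabulary every automated feature-selection
scheme ranks over.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from ._text import SpellCorrector, coarse_pos_tag, tokenize_words
from .reports import AutopsyReport
from .stopwords import DEFAULT_STOPWORDS

logger = logging.getLogger(__name__)

__all__ = [
    "TaggedToken",
    "ProcessedReport",
    "MasterFeatureVector",
    "correct_spelling",
    "preprocess_report",
    "preprocess_corpus",
    "build_master_feature_vector",
]


class TaggedToken(NamedTuple):
    """A lowercase surface form with its coarse lexical category."""

    surface: str
    tag: str

    def render(self) -> str:
        return f"{self.surface}/{self.tag}"

    @classmethod
    def parse(cls, rendered: str) -> "TaggedToken":
        surface, _, tag = rendered.rpartition("/")
        return cls(surface, tag)


@dataclass(frozen=True)
class ProcessedReport:
    """Token multiset of one report after the full preprocessing chain.

    ``sequence`` preserves document order of the (spell-corrected, lowercased,
    stopword-free) surfaces so multi-word lexicon terms can be matched as
    contiguous runs; ``tokens`` is the tagged multiset used everywhere else.
    """

    report_id: str
    tokens: Mapping[TaggedToken, int]
    label: str
    sequence: tuple[str, ...] = field(default=(), compare=False)


def correct_spelling(text: str, dictionary) -> str:
    """Correct out-of-dictionary words (edit distance <= 2, deterministic ties)."""
    corrector = dictionary if isinstance(dictionary, SpellCorrector) else SpellCorrector(dictionary)
    return corrector.correct_text(text)


def preprocess_report(
    report: AutopsyReport,
    stoplist: Iterable[str] | None = None,
    dictionary=None,
) -> ProcessedReport:
    """Run the preprocessing chain on one report.

    ``dictionary`` may be a word list, a word->frequency mapping, a
    :class:`SpellCorrector`, or None to skip spell correction.  ``stoplist``
    defaults to the vendored English list.
    """
    stopset = DEFAULT_STOPWORDS if stoplist is None else frozenset(w.lower() for w in stoplist)
    text = report.full_text()
    if dictionary is not None:
        text = correct_spelling(text, dictionary)
    words = tokenize_words(text.lower())
    kept = [w for w in words if w not in stopset]
    tokens = Counter(TaggedToken(w, coarse_pos_tag(w)) for w in kept)
    if not tokens:
        logger.warning("report %s: no tokens survive preprocessing", report.report_id)
    return ProcessedReport(
        report_id=report.report_id,
        tokens=dict(tokens),
        label=report.label,
        sequence=tuple(kept),
    )


def preprocess_corpus(
    reports: Sequence[AutopsyReport],
    stoplist: Iterable[str] | None = None,
    dictionary=None,
) -> list[ProcessedReport]:
    """Preprocess every report with one shared spell corrector (cached lookups)."""
    if dictionary is not None and not isinstance(dictionary, SpellCorrector):
        dictionary = SpellCorrector(dictionary)
    return [preprocess_report(r, stoplist=stoplist, dictionary=dictionary) for r in reports]


@dataclass(frozen=True)
class MasterFeatureVector:
    """Corpus-wide pruned vocabulary with exact frequency bookkeeping.

    Ordered by descending corpus frequency, then alphabetically by rendered
    form — a deterministic ordering independent of report order.
    """

    vocabulary: tuple[TaggedToken, ...]
    corpus_frequency: Mapping[TaggedToken, int]
    document_frequency: Mapping[TaggedToken, int]

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, token: TaggedToken) -> bool:
        return token in self.corpus_frequency

    def rendered(self) -> list[str]:
        return [t.render() for t in self.vocabulary]


def build_master_feature_vector(
    corpus: Sequence[ProcessedReport],
    rare_threshold: int = 2,
    *,
    count_documents: bool = False,
) -> MasterFeatureVector:
    """Aggregate token counts over the corpus and prune rare tokens.

    A token is kept iff its total corpus occurrence count (or its document
    count when ``count_documents`` is True) exceeds ``rare_threshold``; the
    default 2 discards tokens appearing only once or twice.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    total: Counter[TaggedToken] = Counter()
    docfreq: Counter[TaggedToken] = Counter()
    for rep in corpus:
        for tok, n in rep.tokens.items():
            total[tok] += n
            docfreq[tok] += 1
    basis = docfreq if count_documents else total
    kept = [t for t in total if basis[t] > rare_threshold]
    if not kept:
        logger.warning("master feature vector is empty after rare-token pruning")
    kept.sort(key=lambda t: (-total[t], t.render()))
    return MasterFeatureVector(
        vocabulary=tuple(kept),
        corpus_frequency={t: total[t] for t in kept},
        document_frequency={t: docfreq[t] for t in kept},
    )
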