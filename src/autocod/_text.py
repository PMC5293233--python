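"""Low-level text primitives: tokenization, coarse lexical tagging, spell correction.

These are deliberately small and deterministic.  The pipeline needs a
reproducible unigram stream, a coarse Noun/Verb/Adjective/Adverb/Other
category per token, and a spell corrector with a fully specified
tie-breaking policy — not a state-of-the-art NLP stack.
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Iterable, Mapping

__all__ = [
    "split_sentences",
    "tokenize_words",
    "coarse_pos_tag",
    "SpellCorrector",
    "edit_distance",
    "load_wordlist",
]

_SENTENCE_RE = re.compile(r"[.!?;]+\s+")
# words (hyphen/apostrophe-joined clinical terms stay single tokens) or bare numbers
_TOKEN_RE = re.compile(r"[A-Za-z]+(?:[-'][A-Za-z]+)*|\d+(?:\.\d+)?")
_NUMERIC_RE = re.compile(r"^\d+(?:\.\d+)?$")

TAGSET = ("Noun", "Verb", "Adjective", "Adverb", "Other")

# closed exception lists keep the suffix heuristics from misfiring on common words
_VERB_WORDS = frozenset(
    "is are was were be been being has have had show shows showed reveal reveals "
    "revealed note notes noted found sustain sustained suffer suffered die died "
    "cause caused occur occurred appear appeared seen observed present presented".split()
)
_ADJ_WORDS = frozenset(
    "left right upper lower anterior posterior lateral medial proximal distal "
    "acute chronic severe mild multiple deep superficial large small pale dark "
    "intact absent normal abnormal bilateral".split()
)
_NOUN_EXCEPTIONS = frozenset(
    "bed red head blood dead forehead bruising swelling bleeding morning evening "
    "finding findings opening".split()
)

_ADVERB_SUFFIXES = ("ly",)
_VERB_SUFFIXES = ("ed", "ing", "ise", "ize")
_ADJ_SUFFIXES = ("ous", "ive", "able", "ible", "al", "ic", "ful", "less", "ish", "ary")


def split_sentences(text: str) -> list[str]:
    """Split on sentence-final punctuation followed by whitespace."""
    return [s for s in _SENTENCE_RE.split(text) if s.strip()]


def tokenize_words(text: str, *, drop_numeric: bool = True) -> list[str]:
    """Lowercased unigram tokens in document order.

    Punctuation is discarded; purely numeric tokens are dropped unless
    ``drop_numeric`` is False.  Hyphenated terms remain single tokens.
    """
    tokens = []
    for sentence in split_sentences(text) or [text]:
        for tok in _TOKEN_RE.findall(sentence):
            if drop_numeric and _NUMERIC_RE.match(tok):
                continue
            tokens.append(tok.lower())
    return tokens


def coarse_pos_tag(word: str) -> str:
    """Assign a coarse lexical category to a lowercase word.

    A deterministic rule tagger: closed exception lists first, then suffix
    heuristics, defaulting to Noun (the dominant category in clinical
    nominal-style prose).
    """
    if not word or not word[0].isalpha():
        return "Other"
    if word in _NOUN_EXCEPTIONS:
        return "Noun"
    if word in _VERB_WORDS:
        return "Verb"
    if word in _ADJ_WORDS:
        return "Adjective"
    if word.endswith(_ADVERB_SUFFIXES) and len(word) > 3:
        return "Adverb"
    if word.endswith(_VERB_SUFFIXES) and len(word) > 3:
        return "Verb"
    if word.endswith(_ADJ_SUFFIXES) and len(word) > 4:
        return "Adjective"
    return "Noun"


def edit_distance(a: str, b: str, limit: int | None = None) -> int:
    """Levenshtein distance with optional early-exit band.

    Returns ``limit + 1`` as soon as the distance provably exceeds ``limit``.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if limit is not None and abs(la - lb) > limit:
        return limit + 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    prev = list(range(la + 1))
    for j in range(1, lb + 1):
        cur = [j] + [0] * la
        for i in range(1, la + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[i] = min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + cost)
        if limit is not None and min(cur) > limit:
            return limit + 1
        prev = cur
    return prev[la]


def load_wordlist(path) -> list[str]:
    """One entry per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip().lower()
            if word and not word.startswith("#"):
                out.append(word)
    return out


class SpellCorrector:
    """Deterministic dictionary-based spell correction.

    Every out-of-dictionary word is replaced by the nearest dictionary word
    within edit distance ``max_distance`` (default 2).  Ties break by smaller
    edit distance, then higher dictionary frequency, then alphabetical order.
    Words with no candidate in range pass through unchanged.
    """

    def __init__(
        self,
        dictionary: Iterable[str] | Mapping[str, int],
        max_distance: int = 2,
    ):
        if isinstance(dictionary, Mapping):
            self._freq = {w.lower(): int(f) for w, f in dictionary.items()}
        else:
            self._freq = {}
            for w in dictionary:
                w = w.lower()
                self._freq[w] = self._freq.get(w, 0) + 1
        if not self._freq:
            raise ValueError("spell dictionary must be non-empty")
        self.max_distance = max_distance
        self._words = sorted(self._freq)
        self._by_length: dict[int, list[str]] = {}
        for w in self._words:
            self._by_length.setdefault(len(w), []).append(w)
        self._correct_word = lru_cache(maxsize=65536)(self._correct_word_uncached)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._freq

    def _correct_word_uncached(self, word: str) -> str:
        lower = word.lower()
        if lower in self._freq or not lower[0].isalpha():
            return word  # in-dictionary words pass through untouched
        best: tuple[int, int, str] | None = None  # (distance, -freq, word)
        for length in range(len(lower) - self.max_distance, len(lower) + self.max_distance + 1):
            for cand in self._by_length.get(length, ()):
                d = edit_distance(lower, cand, limit=self.max_distance)
                if d > self.max_distance:
                    continue
                key = (d, -self._freq[cand], cand)
                if best is None or key < best:
                    best = key
        return best[2] if best is not None else word

    def correct_word(self, word: str) -> str:
        return self._correct_word(word)

    def correct_text(self, text: str) -> str:
        """Replace each out-of-dictionary word in free text, leaving layout intact."""

        def _sub(match: re.Match) -> str:
            return self._correct_word(match.group(0))

        return re.sub(r"[A-Za-z]+(?:[-'][A-Za-z]+)*", _sub, text)


def correct_spelling(text: str, dictionary: Iterable[str] | Mapping[str, int] | SpellCorrector) -> str:
    """Functional wrapper around :class:`SpellCorrector` for one-off use."""
    corrector = dictionary if isinstance(dictionary, SpellCorrector) else SpellCorrector(dictionary)
    return corrector.correct_text(text)
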