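"""Synthetic autopsy-report corpus and lexicon generator.

Emulates the statistical structure the classification method assumes —
nine accident-related ICD-10 classes with an imbalanced distribution,
class-discriminative injury vocabulary whose surface forms vary through
synonym groups (pathologists use terms like "abrasion", "graze" and
"trauma" interchangeably), a large background vocabulary shared across
all classes, and typographical misspellings — without attempting to mimic
real clinical language.  Every draw flows from one seeded generator, so a
config reproduces its corpus bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .expert import ExpertEntry, ExpertFeatureSet
from .reports import AutopsyReport, SECTION_ORDER

__all__ = [
    "SyntheticClassSpec",
    "SyntheticCorpusConfig",
    "DEFAULT_CLASSES",
    "largest_remainder",
    "generate_lexicons",
    "generate_report",
    "generate_corpus",
]

# Nine leading accident-related causes of death with the observed record
# fractions of a 2200-report hospital corpus (260/2200 x4, 250/2200 x2,
# 220/2200 x3).
DEFAULT_CLASSES: tuple[tuple[str, float], ...] = (
    ("T07", 260 / 2200),  # multiple injury
    ("S06", 260 / 2200),  # craniocerebral injury
    ("S38", 260 / 2200),  # abdominal injury
    ("S17", 260 / 2200),  # neck injury
    ("S28", 250 / 2200),  # chest injury
    ("S36", 250 / 2200),  # liver rupture
    ("T71", 220 / 2200),  # asphyxiation
    ("T75", 220 / 2200),  # electrocution
    ("G40", 220 / 2200),  # epileptic seizure
)

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"

# short clinical-style sentence frames per section; {} slots take generated terms
_SECTION_FRAMES: dict[str, tuple[str, ...]] = {
    "external_exam": (
        "external examination showed {} over the {} region.",
        "the body surface revealed {} with surrounding {}.",
        "rigor mortis present with {} and {} noted.",
    ),
    "injury": (
        "there was {} with associated {} on the trunk.",
        "examination of injuries revealed {} and {}.",
        "a large area of {} was found beside the {}.",
    ),
    "internal_exam": (
        "internal examination revealed {} involving the {}.",
        "dissection showed {} with marked {}.",
        "the organs demonstrated {} and patchy {}.",
    ),
    "histopathology": (
        "histology sections showed {} with focal {}.",
        "microscopy revealed {} and scattered {}.",
    ),
    "history": (
        "history records {} prior to the incident with {}.",
        "the deceased reportedly had {} followed by {}.",
    ),
}

#: which sections carry class-discriminative terms (the rest get background only)
_DISCRIMINATIVE_SECTIONS = ("injury", "internal_exam")


@dataclass(frozen=True)
class SyntheticClassSpec:
    code: str
    proportion: float
    pool_size: int = 30  # ranked discriminative entries per class lexicon


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Generator settings; every field has a defined default except the seed."""

    seed: int
    classes: tuple[SyntheticClassSpec, ...] = tuple(
        SyntheticClassSpec(code, prop) for code, prop in DEFAULT_CLASSES
    )
    reports_total: int = 2200
    background_vocab_size: int = 300
    background_terms_per_report: int = 40
    discriminative_terms_per_report: float = 8.0  # Poisson mean
    synonym_group_size: int = 3
    synonym_probability: float = 0.5
    misspelling_probability: float = 0.05
    lexicon_overlap: float = 0.1  # fraction of each pool drawn from a shared confusable pool
    sample_counts: bool = False  # multinomial class counts instead of largest remainder
    _dictionary: tuple[str, ...] = field(default=(), compare=False, repr=False)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(c.proportion for c in self.classes)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class proportions must sum to 1, got {total}")
        for name in ("synonym_probability", "misspelling_probability", "lexicon_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reports_total < len(self.classes):
            raise ValueError("reports_total must be at least the number of classes")
        codes = [c.code for c in self.classes]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate class codes")

    def class_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.classes)

    def with_per_class_size(self, n_per_class: int) -> "SyntheticCorpusConfig":
        """Equal-sized classes with ``n_per_class`` reports each (learning curves)."""
        c = len(self.classes)
        classes = tuple(dataclasses.replace(spec, proportion=1.0 / c) for spec in self.classes)
        return dataclasses.replace(self, classes=classes, reports_total=n_per_class * c)

    def dictionary_words(self) -> tuple[str, ...]:
        """Every correctly spelled word the generator can emit (spell dictionary)."""
        if not self._dictionary:
            raise RuntimeError("dictionary is populated by generate_corpus/generate_lexicons")
        return self._dictionary

    @classmethod
    def from_json(cls, path) -> "SyntheticCorpusConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        classes = raw.pop("classes", None)
        if classes is not None:
            raw["classes"] = tuple(SyntheticClassSpec(**c) for c in classes)
        return cls(**raw)


def largest_remainder(total: int, proportions: Sequence[float]) -> list[int]:
    """Deterministic apportionment: floors first, leftover seats by remainder."""
    quotas = [total * p for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    leftover = total - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def _make_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def _make_vocabulary(rng: np.random.Generator, n: int, taken: set[str], n_syllables=(3, 5)) -> list[str]:
    words: list[str] = []
    while len(words) < n:
        w = _make_word(rng, int(rng.integers(n_syllables[0], n_syllables[1] + 1)))
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def generate_lexicons(
    config: SyntheticCorpusConfig, rng: np.random.Generator
) -> tuple[list[ExpertFeatureSet], set[str]]:
    """Ground-truth ranked lexicons with synonym groups per class.

    A fraction ``lexicon_overlap`` of each class's entries is drawn from a
    pool of confusable term groups shared across classes (overlap 0 gives
    pairwise-disjoint pools).  Returns the lexicons and the set of every
    term surface generated (for the spell dictionary).
    """
    taken: set[str] = set()
    g = config.synonym_group_size
    n_shared_per_class = [round(config.lexicon_overlap * c.pool_size) for c in config.classes]
    shared_pool_size = max(n_shared_per_class, default=0)
    shared_groups = [
        _make_vocabulary(rng, g, taken) for _ in range(shared_pool_size)
    ]
    lexicons = []
    for spec, n_shared in zip(config.classes, n_shared_per_class):
        groups: list[list[str]] = []
        if n_shared:
            idx = rng.choice(len(shared_groups), size=n_shared, replace=False) if shared_groups else []
            groups.extend(shared_groups[i] for i in idx)
        while len(groups) < spec.pool_size:
            groups.append(_make_vocabulary(rng, g, taken))
        rng.shuffle(groups)
        entries = tuple(
            ExpertEntry(canonical=grp[0], synonyms=frozenset(grp[1:]), rank=r)
            for r, grp in enumerate(groups, start=1)
        )
        lexicons.append(ExpertFeatureSet(class_code=spec.code, entries=entries))
    all_terms = {t for lx in lexicons for e in lx.entries for t in e.terms()}
    return lexicons, all_terms


def _misspell(word: str, rng: np.random.Generator) -> str:
    """One random single-character edit (substitution, deletion, or insertion)."""
    alphabet = _CONSONANTS + _VOWELS
    op = rng.integers(3)
    i = int(rng.integers(len(word)))
    ch = alphabet[rng.integers(len(alphabet))]
    if op == 0:
        return word[:i] + ch + word[i + 1 :]
    if op == 1 and len(word) > 2:
        return word[:i] + word[i + 1 :]
    return word[:i] + ch + word[i:]


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_report(
    class_code: str,
    lexicons: Sequence[ExpertFeatureSet],
    config: SyntheticCorpusConfig,
    rng: np.random.Generator,
    background_vocab: Sequence[str],
    report_id: str = "R0",
) -> AutopsyReport:
    """One synthetic report for a class.

    Discriminative terms for the true class are drawn at the configured
    Poisson rate; each draw emits a uniformly chosen synonym instead of the
    canonical form with probability ``synonym_probability``.  Background
    terms are drawn Zipf-weighted from the shared vocabulary.  Each emitted
    word is independently misspelled (one character edit) with probability
    ``misspelling_probability``.
    """
    lexicon = next(lx for lx in lexicons if lx.class_code == class_code)
    n_disc = int(rng.poisson(config.discriminative_terms_per_report))
    disc_words = []
    for _ in range(n_disc):
        entry = lexicon.entries[int(rng.integers(len(lexicon.entries)))]
        synonyms = sorted(entry.synonyms)
        if synonyms and rng.random() < config.synonym_probability:
            disc_words.append(synonyms[int(rng.integers(len(synonyms)))])
        else:
            disc_words.append(entry.canonical)
    weights = _zipf_weights(len(background_vocab))
    bg_words = [
        background_vocab[i]
        for i in rng.choice(len(background_vocab), size=config.background_terms_per_report, p=weights)
    ]

    def emit(word: str) -> str:
        if rng.random() < config.misspelling_probability:
            return _misspell(word, rng)
        return word

    # distribute background words over all sections; discriminative terms go
    # to the injury/internal sections, interleaved with background
    sections: dict[str, str] = {}
    bg_iter = iter(bg_words)
    disc_iter = iter(disc_words)
    for name in SECTION_ORDER:
        frames = _SECTION_FRAMES[name]
        sentences = []
        n_frames = 3 if name in _DISCRIMINATIVE_SECTIONS else 2
        for fi in range(n_frames):
            frame = frames[int(rng.integers(len(frames)))]
            slots = frame.count("{}")
            words = []
            for s in range(slots):
                use_disc = name in _DISCRIMINATIVE_SECTIONS and rng.random() < 0.5
                word = next(disc_iter, None) if use_disc else None
                if word is None:
                    word = next(bg_iter, None)
                if word is None:
                    word = background_vocab[int(rng.integers(len(background_vocab)))]
                words.append(emit(word))
            sentences.append(frame.format(*words))
        sections[name] = " ".join(sentences)
    # any leftover discriminative terms are appended to the injury section
    leftover = [emit(w) for w in disc_iter]
    if leftover:
        sections["injury"] += " further findings included " + " and ".join(leftover) + "."
    demographics = {
        "age": int(rng.integers(5, 88)),
        "gender": "male" if rng.random() < 0.85 else "female",
        "nationality": "unknown",
    }
    return AutopsyReport(
        report_id=report_id, sections=sections, label=class_code, demographics=demographics
    )


def generate_corpus(
    config: SyntheticCorpusConfig,
) -> tuple[list[AutopsyReport], list[ExpertFeatureSet]]:
    """Generate the full corpus plus its ground-truth lexicons.

    Class counts follow deterministic largest-remainder apportionment of
    the configured proportions (or a multinomial draw with
    ``sample_counts``).  The returned config-bound spell dictionary — every
    word form the generator can emit — is available afterwards via
    ``config.dictionary_words()``.
    """
    rng = np.random.default_rng(config.seed)
    lexicons, lexicon_terms = generate_lexicons(config, rng)
    taken = set(lexicon_terms)
    background = _make_vocabulary(rng, config.background_vocab_size, taken)
    proportions = [c.proportion for c in config.classes]
    if config.sample_counts:
        counts = list(rng.multinomial(config.reports_total, proportions))
    else:
        counts = largest_remainder(config.reports_total, proportions)
    reports: list[AutopsyReport] = []
    rid = 0
    for spec, n in zip(config.classes, counts):
        for _ in range(n):
            rid += 1
            reports.append(
                generate_report(
                    spec.code, lexicons, config, rng, background, report_id=f"R{rid:05d}"
                )
            )
    template_words = sorted(
        {
            w
            for frames in _SECTION_FRAMES.values()
            for f in frames
            for w in f.replace("{}", " ").replace(".", " ").replace(",", " ").split()
        }
        | {"further", "findings", "included", "and"}
    )
    dictionary = tuple(sorted(lexicon_terms | set(background) | set(template_words)))
    object.__setattr__(config, "_dictionary", dictionary)
    return reports, lexicons
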