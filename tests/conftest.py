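"""Shared fixtures: tiny hand-built corpora and report constructors."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import settings

from autocod.preprocess import ProcessedReport, TaggedToken

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_report(report_id: str, words: list[str], label: str) -> ProcessedReport:
    """A processed report whose multiset is the given word list (all tagged Noun)."""
    tokens = Counter(TaggedToken(w, "Noun") for w in words)
    return ProcessedReport(
        report_id=report_id, tokens=dict(tokens), label=label, sequence=tuple(words)
    )


@pytest.fixture
def make_processed_report():
    return make_report


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_corpus(rng, n_reports: int, n_features: int, n_classes: int):
    """Random small corpus over a fixed word inventory, for oracle comparisons."""
    words = [f"w{i:02d}" for i in range(n_features)]
    labels = [f"C{i}" for i in range(n_classes)]
    reports = []
    for i in range(n_reports):
        counts = rng.poisson(0.8, size=n_features)
        bag = [w for w, c in zip(words, counts) for _ in range(int(c))]
        if not bag:  # keep every report non-empty
            bag = [words[int(rng.integers(n_features))]]
        reports.append(make_report(f"r{i}", bag, labels[int(rng.integers(n_classes))]))
    # make sure at least two classes are present
    if len({r.label for r in reports}) < 2:
        reports[0] = make_report(reports[0].report_id, list(reports[0].sequence), labels[0])
        reports[1] = make_report(reports[1].report_id, list(reports[1].sequence), labels[1])
    return reports, words
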