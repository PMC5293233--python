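"""Automated feature-ranking schemes against independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import pearsonr

from autocod.preprocess import build_master_feature_vector
from autocod.selection import (
    build_bow_dataset,
    emffs_rank_aggregation,
    score_chi_square,
    score_fms,
    score_gain_ratio,
    score_igfs,
    score_information_gain,
    score_pearson,
    select_top_k,
)

from conftest import make_report, random_corpus


def vectorize(corpus, words):
    """Independent count matrix: plain python loops over the word list."""
    X = np.array([[list(r.sequence).count(w) for w in words] for r in corpus], dtype=float)
    y = np.array([r.label for r in corpus])
    return X, y


# ---------------------------------------------------------------- oracles


def oracle_entropy(counts):
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c > 0) if total else 0.0


def oracle_info_gain(present, y):
    classes = sorted(set(y))
    base = oracle_entropy([sum(1 for lab in y if lab == c) for c in classes])
    n = len(y)
    after = 0.0
    for flag in (True, False):
        branch = [lab for p, lab in zip(present, y) if p == flag]
        if branch:
            after += (len(branch) / n) * oracle_entropy(
                [sum(1 for lab in branch if lab == c) for c in classes]
            )
    return base - after


def oracle_chi_square(present, y):
    classes = sorted(set(y))
    n = len(y)
    chi = 0.0
    for flag in (True, False):
        for c in classes:
            obs = sum(1 for p, lab in zip(present, y) if p == flag and lab == c)
            row = sum(1 for p in present if p == flag)
            col = sum(1 for lab in y if lab == c)
            exp = row * col / n
            if exp > 0:
                chi += (obs - exp) ** 2 / exp
    return chi


def oracle_pearson(x, y):
    if len(set(x)) == 1:
        return 0.0
    best = 0.0
    for c in sorted(set(y)):
        ind = [1.0 if lab == c else 0.0 for lab in y]
        if len(set(ind)) == 1:
            continue
        best = max(best, abs(pearsonr(x, ind)[0]))
    return best


def oracle_fisher(x, y, gamma=0.0):
    classes = sorted(set(y))
    grand = np.mean(x)
    between = within = 0.0
    for c in classes:
        block = np.array([v for v, lab in zip(x, y) if lab == c])
        between += len(block) * (block.mean() - grand) ** 2
        within += ((block - block.mean()) ** 2).sum()
    denom = within + gamma
    if denom == 0:
        return math.inf if between > 0 else 0.0
    return between / denom


def oracle_gain_ratio(present, y):
    ig = oracle_info_gain(present, y)
    n_present = sum(present)
    split = oracle_entropy([n_present, len(y) - n_present])
    return ig / split if split > 0 else 0.0


# ---------------------------------------------------------------- examples


def two_class_corpus():
    """4 reports, 2 classes; 'alpha' is a perfect marker, 'beta' is uninformative."""
    return [
        make_report("r1", ["alpha", "beta"], "H"),
        make_report("r2", ["alpha"], "H"),
        make_report("r3", ["gamma", "beta"], "M"),
        make_report("r4", ["gamma"], "M"),
    ]


class TestInformationGain:
    def test_perfect_split_on_balanced_classes_gains_one_bit(self):
        M = build_master_feature_vector(two_class_corpus(), rare_threshold=0)
        rank = score_information_gain(M, two_class_corpus())
        assert rank.scores["alpha/Noun"] == pytest.approx(1.0)

    def test_feature_present_in_half_of_each_class_gains_zero(self):
        corpus = [
            make_report("r1", ["tok", "pad"], "H"),
            make_report("r2", ["pad"], "H"),
            make_report("r3", ["tok", "pad"], "M"),
            make_report("r4", ["pad"], "M"),
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_information_gain(M, corpus)
        assert rank.scores["tok/Noun"] == pytest.approx(0.0, abs=1e-12)

    def test_single_class_corpus_scores_zero_with_warning(self, caplog):
        corpus = [make_report(f"r{i}", ["tok"], "H") for i in range(3)]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_information_gain(M, corpus)
        assert set(rank.scores.values()) == {0.0}

    def test_bounded_by_log2_c(self, rng):
        corpus, _ = random_corpus(rng, 20, 6, 3)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_information_gain(M, corpus)
        c = len({r.label for r in corpus})
        for s in rank.scores.values():
            assert -1e-12 <= s <= math.log2(c) + 1e-12


class TestChiSquare:
    def test_observed_equals_expected_gives_zero(self):
        corpus = [
            make_report("r1", ["tok"], "H"),
            make_report("r2", ["pad"], "H"),
            make_report("r3", ["tok"], "M"),
            make_report("r4", ["pad"], "M"),
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_chi_square(M, corpus)
        assert rank.scores["tok/Noun"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_2x2_association_equals_n(self):
        # presence table O = [[10, 0], [0, 10]]: chi-square = n = 20
        corpus = [make_report(f"h{i}", ["tok"], "H") for i in range(10)] + [
            make_report(f"m{i}", ["pad"], "M") for i in range(10)
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_chi_square(M, corpus)
        assert rank.scores["tok/Noun"] == pytest.approx(20.0)

    def test_invariant_to_label_permutation(self, rng):
        corpus, words = random_corpus(rng, 15, 5, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        swapped = [make_report(r.report_id, list(r.sequence), {"C0": "C1", "C1": "C0"}[r.label]) for r in corpus]
        r1 = score_chi_square(M, corpus)
        r2 = score_chi_square(M, swapped)
        for f in r1.scores:
            assert r1.scores[f] == pytest.approx(r2.scores[f])


class TestPearson:
    def test_indicator_feature_scores_one(self):
        corpus = [
            make_report("r1", ["mark", "pad"], "H"),
            make_report("r2", ["mark"], "H"),
            make_report("r3", ["pad"], "M"),
            make_report("r4", ["pad", "pad"], "M"),
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_pearson(M, corpus)
        assert rank.scores["mark/Noun"] == pytest.approx(1.0)

    def test_constant_feature_scores_zero_not_nan(self):
        corpus = [
            make_report("r1", ["same"], "H"),
            make_report("r2", ["same"], "M"),
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_pearson(M, corpus)
        assert rank.scores["same/Noun"] == 0.0


class TestFMS:
    def test_zero_within_scatter_feature_is_maximal(self):
        corpus = [
            make_report("r1", ["sep", "noise", "noise"], "H"),
            make_report("r2", ["sep"], "H"),
            make_report("r3", ["noise"], "M"),
            make_report("r4", ["noise", "noise"], "M"),
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_fms(M, corpus)
        assert rank.order[0] == "sep/Noun"

    def test_identically_distributed_feature_never_beats_a_separator(self):
        corpus = [
            make_report("r1", ["sep", "flat"], "H"),
            make_report("r2", ["sep", "flat"], "H"),
            make_report("r3", ["flat"], "M"),
            make_report("r4", ["flat"], "M"),
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_fms(M, corpus)
        assert rank.scores["flat/Noun"] <= rank.scores["sep/Noun"]


class TestIGFS:
    def test_one_marker_per_class_both_selected_at_k2(self):
        corpus = [
            make_report("r1", ["ha", "pad"], "H"),
            make_report("r2", ["ha"], "H"),
            make_report("r3", ["mo", "pad"], "M"),
            make_report("r4", ["mo"], "M"),
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_igfs(M, corpus)
        assert set(rank.order[:2]) == {"ha/Noun", "mo/Noun"}

    def test_k_equal_vocab_returns_everything(self, rng):
        corpus, _ = random_corpus(rng, 12, 6, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_igfs(M, corpus)
        assert set(select_top_k(rank, len(M))) == set(M.rendered())

    def test_three_class_round_robin_matches_hand_trace(self):
        # Each class c has a perfect marker m_c; IG(m_H)=IG(m_M)=IG(m_G) and
        # round-robin over alphabetical classes G, H, M picks their markers
        # in that class order regardless of alphabetical feature order.
        corpus = [
            make_report("r1", ["hmark"], "H"),
            make_report("r2", ["hmark"], "H"),
            make_report("r3", ["mmark"], "M"),
            make_report("r4", ["mmark"], "M"),
            make_report("r5", ["gmark"], "G"),
            make_report("r6", ["gmark"], "G"),
        ]
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_igfs(M, corpus)
        assert rank.order[:3] == ("gmark/Noun", "hmark/Noun", "mmark/Noun")


class TestGainRatioAndEMFFS:
    def test_gain_ratio_normalizes_by_split_information(self):
        corpus = two_class_corpus()
        M = build_master_feature_vector(corpus, rare_threshold=0)
        gr = score_gain_ratio(M, corpus)
        # alpha: IG = 1, split info = entropy(2/4) = 1 -> ratio 1
        assert gr.scores["alpha/Noun"] == pytest.approx(1.0)
        # beta present in half the corpus but uninformative -> 0
        assert gr.scores["beta/Noun"] == pytest.approx(0.0, abs=1e-12)

    def test_unanimous_first_stays_first_after_fusion(self):
        corpus = two_class_corpus()
        M = build_master_feature_vector(corpus, rare_threshold=0)
        fused = emffs_rank_aggregation(M, corpus)
        assert fused.order[0] == "alpha/Noun"

    def test_fused_order_equals_hand_computed_mean_ranks(self, rng):
        corpus, words = random_corpus(rng, 14, 5, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        fused = emffs_rank_aggregation(M, corpus)
        constituents = [
            score_chi_square(M, corpus),
            score_information_gain(M, corpus),
            score_pearson(M, corpus),
            score_gain_ratio(M, corpus),
        ]
        mean_rank = {
            f: np.mean([c.order.index(f) + 1 for c in constituents]) for f in fused.order
        }
        expected = sorted(fused.order, key=lambda f: (mean_rank[f], f))
        assert list(fused.order) == expected


class TestSelectTopK:
    def test_prefix_nesting(self, rng):
        corpus, _ = random_corpus(rng, 15, 8, 3)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_information_gain(M, corpus)
        for j in range(1, len(M)):
            assert select_top_k(rank, j) == select_top_k(rank, j + 1)[:j]

    def test_all_returns_whole_vocabulary(self, rng):
        corpus, _ = random_corpus(rng, 10, 5, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_chi_square(M, corpus)
        assert select_top_k(rank, "all") == rank.order

    def test_clamps_oversized_k_with_warning(self, rng, caplog):
        corpus, _ = random_corpus(rng, 10, 5, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        rank = score_chi_square(M, corpus)
        assert select_top_k(rank, 10_000) == rank.order


class TestOracleEquivalence:
    """Every scorer matches an independent brute-force implementation."""

    @pytest.mark.parametrize("trial", range(25))
    def test_all_scorers_match_bruteforce(self, trial):
        rng = np.random.default_rng(1000 + trial)
        corpus, words = random_corpus(rng, int(rng.integers(8, 21)), int(rng.integers(3, 11)), int(rng.integers(2, 4)))
        M = build_master_feature_vector(corpus, rare_threshold=0)
        X, y = vectorize(corpus, [t.surface for t in M.vocabulary])
        names = M.rendered()
        ig = score_information_gain(M, corpus)
        chi = score_chi_square(M, corpus)
        pear = score_pearson(M, corpus)
        fms = score_fms(M, corpus)
        gr = score_gain_ratio(M, corpus)
        for j, name in enumerate(names):
            present = list(X[:, j] > 0)
            assert ig.scores[name] == pytest.approx(oracle_info_gain(present, y), abs=1e-9)
            assert chi.scores[name] == pytest.approx(oracle_chi_square(present, y), abs=1e-9)
            assert pear.scores[name] == pytest.approx(oracle_pearson(X[:, j], y), abs=1e-9)
            assert gr.scores[name] == pytest.approx(oracle_gain_ratio(present, y), abs=1e-9)
            expected_fms = oracle_fisher(X[:, j], y)
            if math.isinf(expected_fms):
                assert math.isinf(fms.scores[name])
            else:
                assert fms.scores[name] == pytest.approx(expected_fms, abs=1e-9)

    def test_scorers_invariant_to_report_order(self, rng):
        corpus, _ = random_corpus(rng, 12, 6, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        for scorer in (score_information_gain, score_chi_square, score_pearson, score_fms):
            fwd = scorer(M, corpus).scores
            rev = scorer(M, corpus[::-1]).scores
            assert fwd == pytest.approx(rev)  # order affects only float summation


class TestBowDataset:
    def test_counts_match_naive_recount(self, rng):
        corpus, words = random_corpus(rng, 10, 6, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        ds = build_bow_dataset(corpus, M)
        X, _ = vectorize(corpus, [t.surface for t in M.vocabulary])
        assert (ds.X == X).all()

    def test_subset_restricts_columns(self, rng):
        corpus, _ = random_corpus(rng, 10, 6, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        subset = M.rendered()[:3]
        ds = build_bow_dataset(corpus, M, subset)
        assert ds.attributes == subset
        assert ds.X.shape == (10, 3)

    def test_unknown_feature_rejected(self, rng):
        corpus, _ = random_corpus(rng, 10, 6, 2)
        M = build_master_feature_vector(corpus, rare_threshold=0)
        with pytest.raises(ValueError, match="outside master vocabulary"):
            build_bow_dataset(corpus, M, ["nonexistent/Noun"])
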