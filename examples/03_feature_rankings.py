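"""Rank vocabulary features with the automated filter schemes.

Each scheme scores every token of the master feature vector and returns a
strictly ranked list; top-k prefixes of those lists feed the classifiers.
"""

from autocod import (
    SyntheticCorpusConfig,
    build_master_feature_vector,
    emffs_rank_aggregation,
    generate_corpus,
    preprocess_corpus,
    score_chi_square,
    score_igfs,
    score_information_gain,
)

config = SyntheticCorpusConfig(seed=11).with_per_class_size(20)
reports, lexicons = generate_corpus(config)
corpus = preprocess_corpus(reports, dictionary=config.dictionary_words())
M = build_master_feature_vector(corpus)
print(f"master feature vector: {len(M)} tokens after rare-token pruning")

for ranking in (
    score_information_gain(M, corpus),
    score_chi_square(M, corpus),
    score_igfs(M, corpus),
    emffs_rank_aggregation(M, corpus),
):
    head = ", ".join(ranking.order[:5])
    print(f"{ranking.scheme:>10} top-5: {head}")
# Discriminative lexicon terms should dominate the top ranks; IGFS additionally
# interleaves classes so every cause of death is represented in a small top-k,
# and EMFFS fuses four rankings by mean rank.
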