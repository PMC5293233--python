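"""A restricted experiment grid: schemes x subset sizes x classifiers.

The full default grid is 6 schemes x 5 sizes x 5 classifiers = 150
cross-validated analyses; here a 2 x 2 x 2 slice keeps the run short.
Every cell shares the same stratified folds, so differences between cells
reflect the representations and learners, not the partitions.
"""

from autocod import SyntheticCorpusConfig, generate_corpus, preprocess_corpus, run_experiment_grid
from autocod.evaluate import grid_cells

print(f"default grid: {len(grid_cells())} analyses")

config = SyntheticCorpusConfig(seed=3).with_per_class_size(20)
reports, lexicons = generate_corpus(config)
corpus = preprocess_corpus(reports, dictionary=config.dictionary_words())

result = run_experiment_grid(
    corpus,
    lexicons,
    schemes=("expert", "info_gain"),
    sizes=(10, "all"),
    classifier_specs=("DT", "RF"),
    folds=5,
    seed=0,
)
table = result.to_frame()
wide = table[table.metric == "accuracy"].pivot_table(
    index=["scheme", "size"], columns="classifier", values="value"
)
print("\naccuracy by cell:")
print(wide.round(3))
# Each cell is the out-of-fold accuracy of one (scheme, subset size,
# classifier) combination under shared 5-fold stratified cross-validation.
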