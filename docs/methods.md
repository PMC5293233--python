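# Methods

This note documents the models and procedures `autocod` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Pipeline

### Preprocessing

Each autopsy report is a labelled bundle of free-text sections
(external examination, injury, internal examination, histopathology,
history); demographics are carried for bookkeeping but never enter any
feature representation (asserted by test).  Sections are concatenated in
that fixed order and passed through, in order:

1. **Spell correction.**  Every out-of-dictionary word is replaced by the
   nearest dictionary word within Levenshtein distance 2; ties break by
   smaller distance, then higher dictionary frequency, then
   alphabetically.  Words with no candidate in range pass through
   unchanged.  The dictionary is supplied by the caller (for synthetic
   corpora, the generator's complete emitted vocabulary).
2. **Lowercasing, sentence splitting, unigram tokenization.**  Hyphenated
   clinical terms ("gastro-intestinal") stay single tokens; punctuation
   and purely numeric tokens are dropped.
3. **Stopword removal** against a vendored ~170-word English closed-class
   list (replaceable by a plain-text file).
4. **Coarse lexical tagging** into Noun/Verb/Adjective/Adverb/Other by a
   deterministic rule tagger (closed exception lists, then suffix
   heuristics, default Noun).  A full statistical tagger would add a
   heavy dependency for no benefit at this granularity: the tag only
   disambiguates surface forms inside the master vocabulary, and the
   coarse tagset is stable across runs by construction.  Misclassified
   suffixes (e.g. a noun ending in *-ed*) cost nothing downstream
   because tags are ignored by the expert matcher and merely split a
   token into at most two vocabulary entries otherwise.

The **master feature vector** collects all distinct `surface/Tag` tokens
with exact corpus and document frequencies, prunes tokens occurring at
most `rare_threshold = 2` times corpus-wide ("once or twice"), and orders
them by descending corpus frequency with alphabetical tie-break.  Pruning
counts total occurrences by default; a `count_documents` flag switches to
document frequency, since either reading of "appeared once or twice in
the reports" is defensible.

### Expert-driven feature selection

Per class, a ranked lexicon of entries `{canonical, synonyms, rank}`;
ranks are unique and contiguous from 1 and no term may appear in two
entries of the same lexicon.  The weight of a report for a class is the
total occurrence count of tokens matching any canonical term or synonym
among the class's top-k entries:

- matching is on the surface form, ignoring the lexical tag (experts list
  words, not word/tag pairs);
- multi-word terms match as contiguous runs of the report's
  stopword-free token stream;
- `k` truncates lexicon depth; the dataset always has exactly one
  attribute per class.  This is the reading that reconciles subset-size
  experiments with the fixed attributes-equal-classes file layout; it is
  a reconstruction, flagged as such;
- a `binary` flag caps each entry's contribution at 1 (presence instead
  of frequency) as a sensitivity option; frequency counting is the
  default and the documented behaviour.

The weight is non-decreasing in k and additive over report parts; both
are property-tested, and values are tested against a naive scan oracle.

### Automated filter schemes

All schemes rank the full master vocabulary; top-k subsets are prefixes,
and ties always break alphabetically on the rendered token.  Information
gain, chi-square, gain ratio and odds ratio operate on document-level
presence/absence tables; Pearson and the Fisher–Markov criterion on
per-report occurrence counts — each formula's natural domain.

- **Information gain**: class entropy in bits minus expected entropy
  after splitting reports on feature presence, generalized from the
  two-class definition to C classes (`I = −Σ p_c log2 p_c`; a balanced
  binary split carries exactly 1 bit).  Base-2 logarithms throughout.
- **Chi-square**: `Σ (O−E)²/E` over the 2×C presence-by-class table,
  expected counts from marginal products; zero-expected cells contribute
  0.
- **Pearson**: the binary correlation definition is extended to C classes
  as the maximum over classes of |r| between the feature's count vector
  and the one-vs-rest class indicator; zero-variance features score 0
  rather than NaN.
- **Fisher–Markov selector, linear kernel (degree 1)**: under the linear
  kernel the criterion decomposes coordinate-wise, so each feature is
  scored by between-class scatter over pooled within-class scatter of
  its counts, with `gamma` (default 0) regularizing the denominator.  A
  feature separating classes with zero within-class scatter scores
  infinite (maximal); if every feature is degenerate the ordering falls
  back to between-class scatter.  The coordinate-wise reduction and the
  default `gamma` are reconstructions: the selector's original tuning is
  not recoverable here.
- **IGFS**: the published combination rule of the global metric
  (information gain) and the one-sided local metric (odds ratio) is
  under-specified, and is reconstructed as class-balanced round-robin:
  classes (alphabetical order) take turns contributing their
  highest-gain feature whose Haldane-smoothed (+0.5 per cell)
  one-vs-rest odds ratio exceeds 1, so every class is represented in any
  top-k prefix when possible; features positive for no class follow in
  global-gain order.
- **Gain ratio**: information gain over the split information (entropy of
  the presence/absence partition); zero split information scores 0.
- **EMFFS baseline**: mean-rank (Borda) fusion of the chi-square,
  information-gain, Pearson and gain-ratio rankings.

Every scorer is tested against an independent brute-force implementation
of the same formula on randomized small fixtures.

### Classification harness

Classifier internals are scikit-learn's; the harness fixes the protocol.
Stratified k-fold assignment is a function of (labels, folds, seed) only,
so every feature scheme is compared on identical partitions.  Defaults
(the original experiments' tool defaults are unknown; these are
documented, not claimed identical): multinomial NB on counts; linear SVM
(one-vs-rest, C = 1, margin scores accepted for rank AUC); KNN with k = 3
and Euclidean distance; decision tree with entropy splits; random forest
with 100 trees and √p features per split.  Folds reduce with a warning
when the smallest class has fewer instances than folds; a single-instance
class is an error.  Training wall-clock time is recorded but never
asserted (hardware-dependent).

### Evaluation

Macro precision and recall average per-class `TP/(TP+FP)` and
`TP/(TP+FN)` with equal class weights; a class with an empty denominator
contributes 0 (deterministic and conservative) with a warning.
F-measure_M is the weighted combination `(β²+1)PR/(β²P+R)` with β = 1 by
default.  Two accuracies are reported side by side: plain trace accuracy,
and the per-class average that also credits true negatives
(`accuracy_avg_paper`), which for more than two classes is inflated by
the TN term — property-tested as ≥ trace accuracy.  Per-class AUC is the
Hand–Till rank form `(S0 − n0(n0+1)/2)/(n0·n1)` with ascending mid-ranks
for ties (equivalently the tie-corrected Mann–Whitney statistic),
verified against brute-force pair counting.

The default experiment grid crosses 6 schemes (expert + 5 automated) ×
5 subset sizes (10, 20, 30, 40, all) × 5 classifiers = 150 analyses under
shared folds, streaming finished cells to JSON-lines so interrupted grids
resume; per-cell failures are recorded and the grid continues.  The
sample-size sweep regenerates the corpus at a range of per-class sizes
and traces the learning curve.

## Synthetic corpus generator

The generator defines the study conditions for all end-to-end tests.  Its
defaults are fixed once:

| parameter | default | rationale |
|---|---|---|
| classes / proportions | T07, S06, S38, S17 (260/2200 each); S28, S36 (250/2200); T71, T75, G40 (220/2200) | the nine accident-related causes of death and record distribution of the motivating hospital corpus |
| `reports_total` | 2200 | same |
| pool size per class | 30 ranked entries | matches the depth of published expert top-30 term lists |
| `synonym_group_size` | 3 | "abrasion/graze/trauma"-style interchangeable triples |
| `synonym_probability` | 0.5 | synonym use is common but not dominant in clinical prose |
| `background_vocab_size` / terms per report | 300 / 40 (Zipf-weighted) | shared accident vocabulary dominates report length |
| `discriminative_terms_per_report` | Poisson mean 8 | a handful of class-specific findings per report |
| `misspelling_probability` | 0.05 | one typo per ~20 words, single-character edits on dictionary words only, so correction recoverability is measurable |
| `lexicon_overlap` | 0.1 | a minority of each class's discriminative pool is confusable across classes |

Class counts use largest-remainder apportionment (exact and
deterministic; a `sample_counts` flag switches to multinomial draws).
Words are pseudo-words built from a fixed syllable inventory, which makes
corpora fully seed-reproducible and keeps single-character misspellings
mostly uniquely recoverable; realism of surface forms is explicitly not a
goal — the statistical structure is.

**What passing tests show, and don't.**  The generator reproduces the
structural obstacles the method targets (shared vocabulary, synonym
scatter, misspellings, class imbalance) but not real clinical language:
no grammar variation, no section-length heterogeneity, no abbreviation
conventions, no label noise.  End-to-end results on it demonstrate that
the pipeline's machinery behaves as designed — e.g. that aggregating
synonyms lifts the expert scheme above a bag of words — not that any
particular accuracy would be attained on hospital data.

## Numerical and procedural choices

- Entropies in bits; `0·log 0 = 0` by the standard limit.
- Chi-square zero-expected cells contribute 0.
- Odds-ratio smoothing: +0.5 added to all four cells (Haldane).
- All rankings strictly ordered: score descending, alphabetical
  tie-break; `select_top_k(r, j)` is always a prefix of
  `select_top_k(r, j+1)`, and oversized k clamps with a warning.
- Scorer invariance to report order holds to floating-point summation
  order (asserted to numerical precision, not bit-exact).
- The permutation-null check averages metrics over 8 label permutations:
  out-of-fold predictions of a classifier fitted to permuted labels carry
  a small pessimistic bias (observed per-permutation mean AUC
  0.466–0.507), so a single permutation is not a fair estimate of the
  null mean.
- Problem sizes in the test suite and acceptance script (e.g. 9 classes ×
  90 reports end-to-end, 1000 draws for the AUC null) are chosen to give
  stable statistics at desk scale; the full 2200-report default and the
  complete 150-cell grid run through the CLI.

## Known limitations

- The coarse rule tagger misassigns some suffixes; consequences are
  limited to vocabulary granularity (see above).
- The IGFS combination rule and the Fisher–Markov `gamma` are documented
  reconstructions, not verified re-implementations of their sources.
- Expert lexicon truncation by k is a reconstruction of how subset sizes
  interact with the attributes-equal-classes layout.
- ARFF support covers the numeric-attributes + nominal-class subset the
  pipeline emits (round-trip validated against `scipy.io.arff`), not the
  full format (no sparse, date, or string attributes).
- No statistical significance testing between grid cells, and no
  hyperparameter search: classifier defaults are fixed and documented.
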