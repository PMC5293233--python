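# autocod

Automatic multi-class ICD-10 cause-of-death classification for plaintext
autopsy reports, built around **expert-driven feature selection**.

## The problem

Pathologists assign each autopsy report a cause-of-death code from the WHO
ICD-10 system (e.g. S06 craniocerebral injury, T71 asphyxiation).  Doing
this from free text is slow, and automatic text classifiers struggle on
accident-related deaths for two reasons: the classes share most of their
vocabulary (every accident report mentions abrasions and lacerations), and
different pathologists describe the same finding with different words
("abrasion", "graze", "trauma").

`autocod` implements a classification pipeline addressing both problems
and the apparatus needed to study it:

- **Preprocessing** — spell correction (deterministic, edit distance ≤ 2),
  lowercasing, sentence/word tokenization, stopword removal, and coarse
  lexical tagging (`knee` → `knee/Noun`); the surviving tokens of the whole
  corpus, pruned of words occurring only once or twice, form the *master
  feature vector* `M`.
- **Expert-driven feature selection** — per class `σ` a ranked lexicon `E`
  of discriminative terms, each with a synonym group.  A report `m` is
  represented by one integer per class,

  `w_σ(m) = Σ_{entries e ∈ top-k(E_σ)} Σ_{t ∈ terms(e)} count(t, m)`,

  i.e. the frequency count of the report's tokens matching any term or
  synonym of the class's top-k entries.  The training set therefore has
  exactly as many attributes as classes.
- **Five automated filter schemes** for comparison — information gain,
  chi-square, Pearson correlation, Fisher–Markov selector (linear kernel),
  and IGFS (information gain globally, one-sided odds ratio locally) —
  plus gain ratio and the EMFFS mean-rank fusion baseline.
- **A classifier harness** — NB, linear SVM, KNN, decision tree, random
  forest (scikit-learn) under stratified 10-fold cross-validation with
  folds shared across all feature schemes.
- **Macro-averaged evaluation** — Precision_M, Recall_M, F-measure_M, two
  accuracy variants, and per-class Hand–Till rank AUC
  `(S0 − n0(n0+1)/2) / (n0·n1)`.
- **A synthetic corpus generator** — nine accident-related ICD-10 classes
  with an imbalanced distribution, synonym groups, shared background
  vocabulary and misspellings, so the entire pipeline is testable without
  access to confidential hospital data.

## Worked example

`examples/02_expert_vs_bow.py` generates a 810-report synthetic corpus
(9 classes × 90 reports), preprocesses it with spell correction, and
cross-validates a random forest on the expert class-score representation
against a bag-of-words baseline:

```
       expert:    9 attributes  macro-F=0.9951  accuracy=0.9951  mean AUC=1.0000
 bag-of-words: 1045 attributes  macro-F=0.9803  accuracy=0.9802  mean AUC=0.9995
```

The expert scheme condenses each report to nine term-match counts yet beats
the thousand-column bag of words, because synonym variants that dilute
individual token columns are aggregated into a single per-class count.

The other examples cover corpus generation (`01`), the automated ranking
schemes (`03`), the 150-cell experiment grid (`04`, run on a small slice),
and the sample-size learning curve (`05`).  A thin CLI wraps the same
library calls:

```bash
autocod simulate --seed 1 --out run/
autocod preprocess --corpus run/corpus.jsonl --dictionary run/dictionary.txt --out run/
autocod select --corpus run/corpus.jsonl --scheme expert --lexicons run/lexicons.json --out run/
autocod evaluate --dataset run/dataset.arff --classifier RF --out run/
autocod grid --corpus run/corpus.jsonl --lexicons run/lexicons.json --out run/grid
```

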