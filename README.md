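# triagesort

Machine-learning support for the *triage* step of biological literature
curation: screening a long list of retrieved PubMed abstracts to keep only
the few documents worth full manual curation.  The setting is fungal-enzyme
biocuration — abstracts annotated by a bio-entity text-mining system
(enzymes, fungi, kinetics sentences, ...) with Enzyme Commission registry
numbers — but the pipeline applies to any two-class triage corpus in the
supported record dialect.

Triage corpora are severely imbalanced: relevant ("positive") documents are
typically ~10% of the retrieved set, so off-the-shelf classifiers drift
toward rejecting everything while still looking accurate.  `triagesort`
addresses this with:

- **Annotation-span features.**  Five feature families over each abstract:
  F1 bio-entity annotation types (a fixed 22-type schema), F2 entity-span
  contents paired with their type (`ligninase|enzyme`), F3 bag-of-words over
  sentence-span contents paired with the sentence type, F4 EC numbers
  normalized to digit strings (`EC 1.14.99.-` → `11499`), F5 plain
  bag-of-words over title + abstract.  Four *feature settings* combine them:
  #1 = F1, #2 = F1+F4, #3 = F5, #4 = F1+F2+F3+F4.  Vocabularies are built
  from training documents only; tokens occurring fewer than 2 times in the
  training corpus or shorter than 3 characters are dropped.
- **Progressive under-sampling.**  The under-sampling factor (USF) removes
  randomly chosen negatives from the training pool so the negative share
  falls by USF percentage points: a 90/10 pool becomes 85/15 at USF 5%, ...
  50/50 at USF 40%.  The held-out test set always keeps the realistic
  imbalanced distribution (20.5% of the corpus, stratified).
- **Three learners** behind one train/predict contract: multinomial Naive
  Bayes with add-α smoothing (from scratch), a Logistic Model Tree — a
  decision tree whose leaves carry LogitBoost logistic regressions grown
  incrementally from the root, with the iteration count set by five-fold
  cross-validation (from scratch) — and a maximum-margin classifier whose
  kernel decision function is evaluated here with training delegated to an
  established convex solver.
- **Imbalance-aware evaluation** of the positive class: Precision, Recall,
  F-measure, F-β (β = 2, emphasizing recall — a missed relevant paper costs
  a curator more than a false candidate) and the Matthews Correlation
  Coefficient.  Accuracy is deliberately not reported.
- **The full grid.**  3 classifiers × 4 feature settings × 9 USF values =
  108 models, each cell independently seeded and reproducible, rendered as
  per-setting result tables.
- **A synthetic corpus generator** producing annotated two-class corpora
  with tunable imbalance and planted discriminative signal, so the whole
  pipeline is testable without any proprietary corpus.

## Worked example

```python
from triagesort import (
    ExperimentSpec, GeneratorSpec, generate_corpus, corpus_stats,
    render_report, run_grid,
)
from triagesort.experiments import frame_to_markdown

corpus = generate_corpus(
    GeneratorSpec(n_pos=75, n_neg=675, signal_strength=0.5, seed=42)
)
print(corpus_stats(corpus))

spec = ExperimentSpec(
    classifiers=("nb", "lmt", "svm"), settings=(2,), usfs=(0, 20, 40), seed=42
)
rows = run_grid(corpus, spec)
print(frame_to_markdown(render_report(rows)[2]))
```

prints

```
{'total': 750, 'class_counts': {'negative': 675, 'positive': 75},
 'class_percent': {'negative': 90.0, 'positive': 10.0},
 'with_abstract_text': 678, 'with_abstract_text_percent': 90.4}
```

| Under-sampling (USF) | Classifier | Precision | Recall | F-measure | MCC | F-2 |
| --- | --- | --- | --- | --- | --- | --- |
| Training set with USF 0% | Naive Bayes | 0.0 | 0.0 | 0.0 | 0.0 | 0.0 |
| Training set with USF 0% | LMT | 0.6 | 0.4 | 0.48 | 0.447 | 0.429 |
| Training set with USF 0% | SVM | 0.714 | 0.333 | 0.455 | 0.454 | 0.373 |
| Training set with USF 20% | Naive Bayes | 0.417 | 0.667 | 0.513 | 0.463 | 0.595 |
| Training set with USF 20% | LMT | 0.579 | 0.733 | 0.647 | 0.609 | 0.696 |
| Training set with USF 20% | SVM | 0.667 | 0.8 | 0.727 | 0.698 | 0.769 |
| Training set with USF 40% | Naive Bayes | 0.203 | 1.0 | 0.337 | 0.342 | 0.56 |
| Training set with USF 40% | LMT | 0.542 | 0.867 | 0.667 | 0.644 | 0.774 |
| Training set with USF 40% | SVM | 0.385 | 0.667 | 0.488 | 0.437 | 0.581 |

The generated corpus reproduces the 90/10 triage imbalance; positive-class
recall rises steeply with under-sampling for every learner (Naive Bayes
rejects every positive at USF 0% but recovers them all at USF 40%), at the
usual cost in precision — the trade-off F-2 is designed to arbitrate.

The same run from a shell:

```sh
triage-sort simulate --n-pos 75 --n-neg 675 --signal 0.5 --seed 42 --out corpus/
triage-sort run --corpus corpus/documents.xml --labels corpus/labels.tsv \
    --settings 2 --usf 0,20,40 --classifiers nb,lmt,svm --seed 42 --out results/
```

`triage-sort extract` exports document-feature count matrices (sparse ARFF
or SVMlight) with a JSON vocabulary sidecar; `triage-sort report` prints
corpus statistics.

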