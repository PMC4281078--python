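# Methods

## Problem and data model

The package classifies annotated PubMed abstracts into *positive* (retain
for full curation) and *negative* (reject) classes.  A document record
carries a PubMed id, an `ArticleTitle` and an `AbstractText` field, inline
bio-entity annotations, and `RegistryNumber` elements holding Enzyme
Commission (EC) identifiers.  Class labels travel separately as a
`pmid<TAB>class` TSV, the form in which triage corpora are typically
released (texts and curation decisions are distributed independently).

Annotations follow a fixed 22-type schema.  Each type has a span kind:
*entity* spans cover a word or short word group (Enzyme, Fungus, Gene,
Substrate, ...), *sentence* spans cover a whole sentence describing an
experimental property (Kinetics, pH, SubstrateSpecificity, ...).  Entity
spans may nest inside sentence spans.  Character offsets are 0-based and
half-open into the tag-stripped field text, so
`field[start:end] == covered_text` exactly; this convention is asserted by
the parser tests and round-trips through the writer byte-identically.
Records with an empty abstract are retained as instances — their features
come from the title and registry fields only.  Unknown annotation tags are
an error by default (catching schema drift early); a permissive flag drops
the tags and keeps their inner text.

## Preprocessing

Text is lowercased; markup is stripped (acting as a word boundary);
non-alphanumeric characters — ASCII punctuation and non-ASCII symbols alike
— are handled by a *hyphen policy*: `join` deletes them in place
("white-rot" → "whiterot"), `split` replaces them with a space ("white rot").
Both policies exist because annotation-content features use the joined form
while the plain bag-of-words uses the split form; both are idempotent
(property-tested).  Tokens are whitespace-split, then filtered: PubMed
stop-words (shipped as packaged data, replaceable by any one-word-per-line
file) and tokens shorter than 3 characters are discarded — very short
tokens inflate feature-space sparsity more than they discriminate.
Digits and alphanumeric tokens are kept; EC identifiers are handled by
their own feature family, so bags-of-words do not special-case them.

## Feature families and settings

- **F1** — one occurrence per annotation, keyed by entity type.  Keys use
  the schema capitalization (`SubstrateSpecificity`).
- **F2** — entity-span contents, cleaned with the join policy, keyed as
  `content|type` with the type lowercased (`ligninase|enzyme`).  Multi-word
  contents stay one key (`trametes versicolor|fungus`).
- **F3** — sentence-span contents as bags of words, each surviving token
  keyed as `token|sentencetype`.  Text covered by a nested entity span is
  kept as one whole token; the tokens between nested spans are cleaned with
  the join policy and filtered like any bag-of-words.
- **F4** — registry strings normalized to their concatenated digits
  (`EC 1.14.99.-` → `11499`).  Digit-free strings are skipped with a
  warning.
- **F5** — bag-of-words over the entire title and abstract, split policy,
  counts merged across fields.  Annotation span boundaries are treated as
  token boundaries (a space is injected at every span start/end before
  cleaning): annotators wrap whole words, and raw records do not always
  keep a space after a closing tag.

Settings: #1 = {F1}, #2 = {F1, F4}, #3 = {F5}, #4 = {F1, F2, F3, F4}.
Composition is a counted union, so per-family counts are conserved.

A `Vocabulary` is built from training documents only — never from test
data; a leakage test plants a sentinel feature in test documents and checks
every per-cell vocabulary of a full grid.  The occurrence filter ("at least
`min_count` = 2 occurrences in the training corpus") reads occurrence as
*total count*, not document frequency, and applies only to token-valued
features (the F3 token part and F5).  F1 types, F2 contents and F4 numbers
are exempt: the entity-type inventory is a fixed 22-entry schema, and a
frequency filter would otherwise silently shrink it.  Feature order is
lexicographic by (kind, key) for reproducible exports.  At test time,
out-of-vocabulary features are silently dropped (closed vocabulary).
Count matrices export to sparse ARFF and SVMlight with a JSON vocabulary
sidecar recording keys, kinds, filter parameters and a fingerprint of the
training corpus.

## Sampling

The held-out test set is 20.5% of the corpus by default, stratified: class
allocations use largest-remainder rounding, so each class's share matches
the corpus within one document; selection within a class is seeded uniform
sampling without replacement.

Under-sampling subtracts the factor (USF ∈ {0, 5, ..., 40}) in percentage
points from the training pool's *actual* negative share, clamped at 0.5
(balance); the retained negative count is `round(n_pos · p / (1 − p))`.
Positives are never removed and no document is duplicated.  Both operations
are pure functions of (corpus, seed, parameters).

## Classifiers

**Naive Bayes** is multinomial with add-α smoothing, α = 1 by default —
the natural event model for count vectors.  Scores are computed in log
space; with α = 0 a zero likelihood's log is replaced by a large negative
constant so prediction stays defined.  Ties break to the negative
(majority) class, as everywhere in the package.

**Logistic Model Tree.**  LogitBoost uses the classical base learner: one
weighted simple least-squares regression on a single attribute per
iteration, fitted to the working response z = (y − p)/(p(1−p)) with weights
p(1−p), z clipped at ±4 and weights floored, probabilities in the symmetric
parameterization p = 1/(1 + e^(−2F)).  One numerical choice beyond the
classical loop: each half-step is accepted only if it does not increase the
training negative log-likelihood; otherwise it is halved (up to three
times) and boosting stops early if still worse.  This makes the monotone
training-loss property unconditional.  The iteration count (≤ `max_iter`,
default 30) is chosen once by stratified five-fold cross-validation at the
root — the iteration with the lowest misclassification count summed over
folds — and reused at interior nodes, the classical heuristic.  Nodes are
split by information gain on the class labels with midpoint numeric
thresholds; children's boosting continues from the parent's accumulated
stump list, so each leaf's logistic function is built incrementally from
the root.  Splitting stops on purity, `min_node_size` (default 15), a gain
at or below `gain_threshold` (default 1e-4), or the depth cap (default 5).
No cost-complexity pruning is applied by default — a deviation from the
original model-tree formulation, which prunes; the incremental leaf models
already shrink toward the root model, and the gain threshold plus node-size
floor provide the regularization at the scales this package targets.
Prediction routes an instance to its unique leaf; the equivalent
sum-over-leaves form (indicator × leaf probability, the indicators
partitioning feature space) is also implemented and tested equal.

**Maximum-margin classifier.**  The decision function — the kernel sum over
support vectors plus bias — is evaluated by this package from the stored
support set; training delegates to scikit-learn's libsvm-based `SVC`, an
established solver for the convex margin-maximization problem, and tests
assert exact agreement between our decision values and the solver's.
Default kernel is linear with C = 1; RBF is selectable with the usual
`scale` gamma.  Sign of the decision value gives the class; zero falls to
negative.

All three learners share one train/predict contract (0 = negative,
1 = positive, width-checked), serialize to versioned JSON, and a
permuted-label test checks that each produces |MCC| < 0.15 on held-out data
when the training association is destroyed.

## Evaluation

Metrics are computed for the positive class from the standard confusion
matrix: Precision, Recall, F (harmonic mean), F-β with β = 2 (recall
weighted over precision — in triage a missed relevant document is the
costly error), and MCC.  Any 0/0 — no positive predictions, no positive
instances, a zero MCC denominator — is defined as 0 and logged.  Accuracy
is deliberately not reported: under a 90/10 imbalance the all-negative
classifier is 90% accurate and useless.  Tables round to 3 decimals; full
precision is kept in the flat CSV.

## Experiment grid

The full grid is 3 classifiers × 4 settings × 9 USF values = 108 cells.
The test split is computed once per (corpus, master seed) and shared by all
cells; each cell derives its own seed by a stable CRC32 hash of
(classifier, setting, usf), so any cell is reproducible in isolation.  A
failing cell is logged and skipped without aborting the run.  Reports group
by feature setting (or classifier), rows ordered by USF then classifier,
columns Precision / Recall / F-measure / MCC / F-2.

## Synthetic data generator

The generator's defaults emulate the qualitative profile of a real triage
corpus: 75 positive / 675 negative documents (10% positive), ~9% of records
with empty abstracts, annotations in both titles and abstracts, EC registry
numbers, and a Zipf-distributed (exponent 1.1) background vocabulary of 400
deterministic pseudo-words — realistic sparsity for the count matrix.
Titles run 4–8 words; abstracts 2–4 sentences of 8–14 words; sentence spans
wrap ~35% of sentences with entity spans nested inside.

Discriminative signal is planted: five enzyme-name entity contents, three
EC numbers and two content words appear in positive documents with
probability `background_rate + signal_strength · (1 − background_rate)`
and in negative documents at `background_rate` (0.15).  The default
`signal_strength` of 0.5 gives a *moderately* separable problem — planted
features in roughly 58% of positives versus 15% of negatives — chosen so
that classifiers are imperfect and the under-sampling trade-off is visible;
0 yields a null model (downstream MCC ≈ 0, tested) and 1 near-perfect
separability (held-out F → 1, tested as a monotone sweep).  With
`ensure_all_entity_types` (default), entity types rotate through documents
per class, so any corpus with ≥ 22 positives carries every schema type
among its positives alone — which is why setting-#1 vocabularies stay at
exactly 22 features across all under-sampling factors.

What the generator does *not* emulate: real linguistic structure (words are
syllable concatenations), annotator errors, correlated features, topic
drift, or duplicated abstracts.  Passing tests on synthetic corpora
therefore demonstrate that the pipeline's machinery — parsing, isolation of
training information, sampling arithmetic, learner contracts, the
under-sampling recall trend — behaves correctly, not that any particular
absolute score would be attained on a real curation corpus.

## Problem sizes in the test suite

The suite favors small, fully seeded instances: corpora of 100–1,000
documents, the full 108-cell grid on a 140-document corpus for the leakage
check, and the under-sampling trend measured over 10 seeds × 750-document
corpora on feature setting #2 (whose compact entity/EC vocabulary makes the
trend test sharp and fast).  These sizes are the package's own test-design
choice: they keep every invariant check exact while the whole suite runs in
seconds.

## Known limitations

- The LMT omits pruning and weight trimming; very deep trees are prevented
  by the depth cap rather than cost-complexity arguments.
- The ARFF reader accepts only the sparse-row subset this package writes.
- Vocabulary construction holds all training-corpus feature counts in
  memory; corpora orders of magnitude beyond the tested sizes would want a
  streaming count pass.
- Stop-word filtering applies a single list to all fields; no stemming or
  lemmatization is performed.
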