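# Methods

This note documents the models and procedures `phenopipe` implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Problem and data model

The unit of classification is a patient: an ordered list of free-text
clinical documents plus an optional gold label (AD / not AD). Corpora are
serialized as JSONL, one document per line, chosen for streamability and
diff-friendliness. Sentences are located by 0-based half-open character
offsets that always slice back to the sentence text; document order within a
patient is file order (no timestamps are modeled).

## Rule-based tagging

**Sentence splitting** is rule-based: terminal punctuation (`.!?`) followed
by whitespace ends a sentence unless the preceding word is on a small
abbreviation stop-list; blank lines also end sentences, because clinical
notes often lack terminal punctuation between paragraphs. Sentences cover
all non-whitespace text.

**Keyword matching.** Each of the 8 indicator categories has an editable
YAML lexicon of case-insensitive whole phrases (regular expressions via a
`re:` prefix). Word boundaries are enforced, so `dermatitis` does not fire
inside `neurodermatitis`. A sentence may match several categories (e.g.
"itchy rash" hits both eczema/rash and dry/itchy skin), and one keyword can
realize several categories ("atopic eczema" realizes both the direct-AD and
the eczema/rash category); per category, only the earliest occurrence in a
sentence is kept. The shipped lexicons are package defaults — keyword
inventories are institution-specific in practice and are data, not code.

**Assertion.** A minimal ConText-style algorithm assigns each match one of
four statuses. Triggers (also editable YAML) carry semantics (negation /
other experiencer / hypothetical), a direction (forward, backward,
bidirectional) and a scope, default 10 tokens, cut short by terminator
conjunctions ("but", "however", ...). A match takes the semantics of the
nearest covering trigger; distance ties resolve by precedence negation >
other experiencer > hypothetical; with no covering trigger the match is
affirmed. The precedence order and the hypothetical trigger inventory
(conditionals, "monitor for", risk phrasing) are this package's choices; the
algorithm family fixes neither.

## Embeddings

Backends implement a pure `(backend_id, text) → vector` contract with a
fixed output dimension. The default is a seeded feature-hashing embedder:
token unigrams and bigrams are hashed (salted BLAKE2b) to one of `dim`
(default 768) signed buckets and the signed counts are L2-normalized.
Sentences with disjoint vocabulary are orthogonal up to hash collisions,
which makes category vocabularies linearly separable — the property the
offline experiments rely on. A transformer backend (mean pooling over
final-layer hidden states, configurable to first-token pooling, 512-token
head truncation) is available when the optional `torch`/`transformers`
stack is installed; an unavailable backend raises an explicit capability
error rather than silently falling back. Pooling choice is a documented
divergence risk: embedding-based results depend on the backend, and token
counts in corpus statistics are likewise tokenizer-dependent by design.

## Sentence classifiers

Per category, a balanced dataset pairs affirmed in-category sentences with
an equal number of sentences drawn from other categories (sentences with no
keyword at all can be included via a flag, default off). The train/test
split is row-random under a seed; a patient-disjoint split is available
(`group_by_patient=True`) for leakage-sensitive analyses, but the default
keeps exact partition arithmetic.

The classifier is a two-layer perceptron, `dim → 100 → 2`, ReLU between the
layers, softmax on the output logits, trained for 10 epochs of mini-batch
SGD (batch 32) with learning rate 0.001 and momentum 0.9 on cross-entropy.
Initialization is seeded He-uniform; training is exactly reproducible under
a fixed seed and aborts on non-finite loss. These hyperparameters are fixed
pipeline defaults; no architecture search is in scope.

Convergence note: with unit-norm hashed features and this small learning
rate, the optimizer needs on the order of a thousand mini-batch updates to
dominate the random-initialization noise in the logits. The sentence-set
experiments therefore use 6,000 positive sentences per category (balanced,
80/20 split) — at that size every category's classifier exceeds 0.98
held-out accuracy within the 10-epoch budget across seeds, while a few
hundred samples per category leave it underfit. Template generation yields a
limited surface-form inventory, so train and test share strings: these
experiments measure separability and optimizer convergence, not
generalization to unseen clinical language.

## Patient vectors

Probability mode scores **all** sentences of a record — not only
lexicon-matched ones — through all 8 classifiers and max-pools per category.
This preserves a known failure mode: one confident false positive anywhere
in a long record propagates into the vector, and longer records have more
chances to produce one. Binary mode sets element *c* to 1 iff some sentence
carries an affirmed match in category *c*; negated, other-experiencer and
hypothetical matches contribute nothing. Both modes are order-invariant;
provenance records the arg-max sentence (earliest on ties) or the first
affirmed match. A patient with zero sentences is an error in probability
mode (rather than imputing a value) and an all-zero vector in binary mode.
Mean and top-k-mean aggregators exist behind configuration but are off by
default.

## Split protocol and evaluation

From a labeled cohort: floor(80%) of positives plus an equal number of
undersampled negatives form the balanced training set; the remaining
positives appear in both test sets — once with as many unused negatives
(balanced test), once with `round(n_pos · (1−p)/p)` further unused negatives
for target prevalence `p` = 0.30 (an explicit negative-count override exists
because published cohorts do not always follow a recoverable rounding rule).
Negatives never repeat across sets.

The classifier bank (logistic regression, SVM, decision tree, random
forest, KNN, XGBoost, AdaBoost) is tuned by stratified 5-fold CV over small
versioned grids (regularization strength, kernel, tree depth, estimator
count, k) on the training set only, refit on the full training set, and
combined by a stacking ensemble with a logistic-regression meta-learner.
Metrics are accuracy, precision, recall, F1, NPV and specificity from the
confusion matrix; zero-denominator metrics are reported as "undefined",
never coerced to 0 or 1.

A row-consistency auditor reconstructs the integer confusion matrix implied
by a published (precision, recall, class sizes) triple and recomputes all
six metrics; comparison allows half an ulp at the printed precision to
cover round-half-up vs round-half-even conventions. This both validates
internally consistent published rows to 4 decimals and flags inconsistent
ones (e.g. a balanced 28+28 row whose printed specificity contradicts its
own accuracy/precision/recall).

## Synthetic corpus

The generator emulates the structure the pipeline assumes, not clinical
language. Per patient: class drawn at the configured prevalence (default
0.30); planted indicators drawn per class (cases always get the mandatory
itchy-skin category plus ≥3 qualifying categories of {hay fever, atopic
allergies, eczema/rash, asthma}; a control whose keyword overlap
accidentally satisfies the rule is re-drawn); each planted indicator yields
1 + Poisson(intensity) affirmed template sentences, with per-category
intensities loosely proportional to the per-category sentence-set sizes the
sentence classifiers are built from. Confounder sentences reuse the same
keywords inside negating, other-experiencer and hypothetical templates at
configurable rates (defaults 0.15/0.10/0.10; `confounder_free()` switches
them off). Document and sentence counts are Poisson with class-specific
means (cases 23.44 docs × 16.77 sentences/doc, controls 7.99 × 24.25); at
least 70% of sentences are indicator-free filler. The per-class
sentences-per-doc pair is required to make both the per-patient and per-doc
averages come out right for both classes.

Ground truth records, per patient, the categories *realized* by the
affirmed sentences — computed by an independent keyword scan, not by the
tagger — so closed-loop tests can demand exact equality between binary
vectors and ground truth even when one keyword spans categories. Labels
always equal the UKWP rule applied to the realized indicators. The UKWP
mapping of the 8 categories onto the rule (category 5 mandatory; 2/3/4/7
qualifying; 1/6/8 non-criteria) is configurable; the generator only needs a
self-consistent rule.

What passing the synthetic experiments shows: the tagging, aggregation,
split and evaluation machinery is correct, deterministic and leak-free, and
the classifiers can recover a rule that is actually present in the
features. What it does not show: performance on real clinical notes, whose
vocabulary, misspellings, section structure, copy-forward duplication and
trigger diversity the templates do not model.

## Numerical and degenerate-input choices

Softmax is computed with max-subtraction (shift-invariant, overflow-safe);
forward-pass agreement with a dependency-free reference is ~1e-15.
Duplicate notes are preserved (no deduplication). Conflicting labels for
one patient are a validation error. Empty per-class statistics are NaN
("undefined" in rendered tables), never zero. All randomness flows from
explicit seeds (NumPy PCG64); fixed seeds give byte-identical corpora,
identical trained weights and identical reports.

## Problem sizes used in the shipped experiments

Closed-loop recovery: 400 patients at 30% prevalence, confounder-free.
Sentence classifiers: 6,000 positives per category, 80/20 split. Assertion
leakage: 1,000 sentences per (category × non-affirmed assertion) cell.
Oracle checks: 1,000 random inputs / confusion matrices.

## Known limitations

- Lexicons and triggers are small defaults, not a validated clinical
  inventory; recall on real notes depends entirely on their curation.
- The hashing backend carries no semantics: synonyms unseen in the lexicons
  are invisible to it, unlike contextual embeddings.
- Assertion handling is token-window-based; clause structure, scope-ending
  punctuation subtleties and machine-learned negation are out of scope.
- Long-document strategies (document-level transformers) and splitting the
  direct-mention category into family-history/affirmed/uncertain
  sub-features are out of scope.
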