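# phenopipe

**EHR phenotyping for atopic dermatitis (AD) cohort identification.**

Recruiting patients for AD studies is hard: there is no gold-standard lab
test, ICD billing codes are unreliable, and manual chart review is slow.
`phenopipe` implements a pipeline that classifies whether a patient's
clinical notes suggest AD, built around the UK Working Party (UKWP)
diagnostic criteria: an itchy skin condition plus three or more supporting
criteria (flexural involvement, asthma/hay fever history, dry skin, early
onset, visible flexural dermatitis).

The pipeline:

1. **Sentence tagging** — documents are split into offset-anchored
   sentences; each sentence is matched against keyword lexicons for 8 AD
   indicator categories (direct AD mention, hay fever, atopic allergies,
   eczema/rash, dry or itchy skin, non-asthma AD medications, asthma,
   asthma medications); each keyword match receives an assertion status
   (*affirmed*, *negated*, *other experiencer*, *hypothetical*) via a
   ConText-style algorithm of trigger phrases with directed,
   terminator-bounded token scopes.
2. **Patient vectors** — each patient becomes an 8-element vector, one
   element per indicator. In *binary* mode, element *c* = 1 iff at least one
   sentence affirms indicator *c*. In *probability* mode, a per-category
   multilayer perceptron (input→100→2 with ReLU and softmax, trained with
   momentum SGD on cross-entropy over sentence embeddings) scores every
   sentence, and element *c* = max over sentences of
   P(sentence affirms indicator *c*) — max pooling across the record.
3. **Patient classification** — a bank of standard classifiers (logistic
   regression, SVM, decision tree, random forest, KNN, XGBoost, AdaBoost,
   plus a stacking ensemble) is trained on the vectors with 5-fold
   cross-validated hyperparameter selection, on a balanced training set
   (80% of positives + equal undersampled negatives), and evaluated on a
   balanced test set and a 30%-prevalence test set with accuracy, precision,
   recall, F1, NPV and specificity.

Real clinical corpora are private, so the package ships a synthetic-corpus
generator that emulates the corpus structure the pipeline assumes (planted
indicator sentences in all four assertion contexts, class-specific document
and sentence counts, UKWP-consistent labels with ground truth). Every stage
is testable offline; a seeded feature-hashing sentence embedder is the
default backend, and a transformer backend can be plugged in where the
`transformers` stack is available.

## Worked example

```python
import phenopipe as pp

cfg = pp.PipelineConfig(out_dir="readme_run", mode="binary", seed=7,
                        generator={"n_patients": 200})
report_dir = pp.run_pipeline(cfg)
print((report_dir / "report_binary_balanced_test.tsv").read_text())
```

This synthesizes a 200-patient corpus at 30% AD prevalence, tags it, builds
binary patient vectors, splits it (here 44+44 train, 11+11 balanced test,
11+26 prevalence-matched test), trains the classifier bank and writes
per-model evaluation tables:

```
Model               Accuracy  Precision  Recall  F1      NPV     Specificity
Logistic Regression 1.0000    1.0000     1.0000  1.0000  1.0000  1.0000
SVM                 1.0000    1.0000     1.0000  1.0000  1.0000  1.0000
Decision Tree       0.9091    0.9091     0.9091  0.9091  0.9091  0.9091
...
Stacking Classifier 1.0000    1.0000     1.0000  1.0000  1.0000  1.0000
```

On this confounder-light synthetic corpus the task is nearly separable —
binary vectors recover the generator's ground-truth indicators exactly and
the label is a deterministic rule of them, so accuracies near 1.0 are the
expected behavior, not a claim about real notes. The first lines of
`vectors.tsv` show the per-patient features the models consume:

```
patient_id  v1  v2  v3  v4  v5  v6  v7  v8  mode
p001        0   0   0   1   0   1   0   0   binary
p002        0   0   0   0   0   0   0   0   binary
```

The same pipeline is available from the shell:

```sh
phenopipe generate --out corpus.jsonl --truth truth.tsv --seed 7
phenopipe tag --corpus corpus.jsonl --out tagged.jsonl
phenopipe build-vectors --corpus corpus.jsonl --mode binary --out vec.tsv
phenopipe split --corpus corpus.jsonl --out splits.json --seed 7
phenopipe train-phenotyper --vectors vec.tsv --corpus corpus.jsonl \
    --splits splits.json --out report/
```

plus `embed`, `train-sentence-classifiers`, `highlight` (chart-review
annotation stream) and `run` (the orchestrator).

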