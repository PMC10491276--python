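"""Patient-level aggregation of sentence evidence into 8-element vectors.

Probability mode (transformer/embedding experiments): every sentence in the
patient's record — lexicon-matched or not — is scored by all 8 sentence
classifiers and each vector element is the max probability over sentences
(max pooling).  Binary mode (rule-based ablation): element c is 1 iff at
least one sentence carries an affirmed keyword match in category c; negated,
other-experiencer and hypothetical mentions contribute nothing.

Element order is fixed to indicator categories 1..8:
1 direct AD mention, 2 hay fever, 3 atopic allergies, 4 eczema/rash,
5 dry/itchy skin, 6 non-asthma AD medications, 7 asthma, 8 asthma
medications.

Each element carries provenance: the (doc_id, sent_index) of the sentence
achieving the max (ties broken toward the earliest sentence) or of the first
affirmed match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import PatientRecord
from .embeddings import EmbeddingBackend
from .mlp import MLPModel, predict_proba
from .tagger import AFFIRMED, TaggedSentence, split_sentences

__all__ = ["PatientVector", "probability_vector", "binary_vector",
           "highlight_sentences"]

N_CATEGORIES = 8


@dataclass
class PatientVector:
    patient_id: str
    mode: str  # "probability" | "binary"
    values: np.ndarray  # shape (8,)
    provenance: list  # per element: (doc_id, sent_index) or None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_CATEGORIES,):
            raise ValueError("patient vector must have exactly 8 elements")
        if self.mode == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary vector elements must be 0 or 1")
        elif self.mode == "probability":
            if ((self.values < 0) | (self.values > 1)).any():
                raise ValueError("probabilities must lie in [0, 1]")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


def probability_vector(
    patient: PatientRecord,
    classifiers: dict[int, MLPModel],
    backend: EmbeddingBackend,
    embeddings_of=None,
) -> PatientVector:
    """Max-pooled per-category sentence probabilities for one patient.

    All sentences of all documents are embedded and scored by each of the 8
    classifiers; element c is the highest positive-class probability any
    sentence achieves under classifier c.  ``embeddings_of`` may override the
    backend call (e.g. with a cache).
    """
    if set(classifiers) != set(range(1, 9)):
        raise ValueError("classifiers must cover categories 1..8")
    sents = [s for doc in patient.documents for s in split_sentences(doc)]
    if not sents:
        raise ValueError(f"patient {patient.patient_id} has no sentences")
    texts = [s.text for s in sents]
    X = embeddings_of(texts) if embeddings_of is not None else backend.embed(texts)
    values = np.zeros(N_CATEGORIES)
    provenance: list = [None] * N_CATEGORIES
    for cat in range(1, 9):
        probs = predict_proba(classifiers[cat], X)
        best = int(np.argmax(probs))  # first max: earliest sentence wins ties
        values[cat - 1] = probs[best]
        provenance[cat - 1] = (sents[best].doc_id, sents[best].sent_index)
    return PatientVector(patient.patient_id, "probability", values, provenance)


def binary_vector(
    patient_id: str, tagged_sentences: list[TaggedSentence]
) -> PatientVector:
    """Affirmed-mention indicator vector for one patient.

    Element c is 1 iff at least one sentence has an affirmed match in
    category c; provenance is the first such sentence in document order.  A
    patient with no sentences gets the all-zero vector.
    """
    values = np.zeros(N_CATEGORIES)
    provenance: list = [None] * N_CATEGORIES
    for ts in tagged_sentences:
        for m in ts.matches:
            if m.assertion == AFFIRMED and values[m.category - 1] == 0:
                values[m.category - 1] = 1.0
                provenance[m.category - 1] = (ts.doc_id, ts.sentence.sent_index)
    return PatientVector(patient_id, "binary", values, provenance)


def highlight_sentences(
    patient: PatientRecord,
    tagged_sentences: list[TaggedSentence],
    classifiers: dict[int, MLPModel] | None = None,
    backend: EmbeddingBackend | None = None,
    threshold: float = 0.8,
) -> list[dict]:
    """Chart-review annotation stream: per sentence, its matched categories
    with assertions and (optionally) the 8 classifier probabilities that
    clear *threshold*, in document/offset order.

    With rule tags only, a sentence is listed when it carries at least one
    affirmed match; with classifiers, also when any category probability
    reaches the threshold.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if classifiers is not None and backend is None:
        raise ValueError("classifiers require an embedding backend")
    probs_by_sent = None
    if classifiers is not None:
        texts = [ts.text for ts in tagged_sentences]
        X = backend.embed(texts) if texts else np.empty((0, backend.dim))
        probs_by_sent = np.column_stack(
            [predict_proba(classifiers[c], X) for c in range(1, 9)]
        ) if texts else np.empty((0, 8))

    out = []
    order = sorted(
        range(len(tagged_sentences)),
        key=lambda i: (tagged_sentences[i].doc_id,
                       tagged_sentences[i].sentence.sent_index),
    )
    for rank, i in enumerate(order):
        ts = tagged_sentences[i]
        entry = {
            "patient_id": patient.patient_id,
            "doc_id": ts.doc_id,
            "sent_index": ts.sentence.sent_index,
            "span": [ts.sentence.char_start, ts.sentence.char_end],
            "text": ts.text,
            "categories": sorted(ts.categories()),
            "assertions": {m.category: m.assertion for m in ts.matches},
        }
        listed = bool(ts.categories(AFFIRMED))
        if probs_by_sent is not None:
            hot = {c + 1: float(p) for c, p in enumerate(probs_by_sent[i])
                   if p >= threshold}
            entry["probs"] = hot
            listed = listed or bool(hot)
        if listed:
            out.append(entry)
    return out
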