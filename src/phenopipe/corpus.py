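"""Corpus data model: clinical documents grouped by patient, JSONL I/O, and
descriptive corpus statistics.

A corpus is a collection of :class:`PatientRecord` objects, each holding the
patient's clinical documents (free text) and an optional gold phenotype label
(``True`` = atopic dermatitis).  Serialization is JSONL with one document per
line so corpora stream and diff cleanly::

    {"patient_id": "p1", "doc_id": "d1", "text": "...", "label": true}

The ``label`` key is written only for labeled patients and must agree across
all of a patient's lines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "ClinicalDocument",
    "PatientRecord",
    "Sentence",
    "CorpusStats",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "corpus_stats",
    "render_stats_table",
]


class CorpusError(ValueError):
    """Raised for malformed or inconsistent corpus files."""


@dataclass(frozen=True)
class ClinicalDocument:
    """One clinical note belonging to a patient."""

    doc_id: str
    patient_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusError(
                f"document {self.patient_id}/{self.doc_id} has empty text"
            )


@dataclass
class PatientRecord:
    """A patient's documents plus an optional gold phenotype label."""

    patient_id: str
    documents: list[ClinicalDocument] = field(default_factory=list)
    label: bool | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.patient_id != self.patient_id:
                raise CorpusError(
                    f"document {doc.doc_id} carries patient_id "
                    f"{doc.patient_id!r}, expected {self.patient_id!r}"
                )
            if doc.doc_id in seen:
                raise CorpusError(
                    f"duplicate doc_id {doc.doc_id!r} for patient "
                    f"{self.patient_id!r}"
                )
            seen.add(doc.doc_id)


@dataclass(frozen=True)
class Sentence:
    """A sentence located by 0-based half-open character offsets into its
    source document; ``text`` always equals the document slice."""

    patient_id: str
    doc_id: str
    sent_index: int
    text: str
    char_start: int
    char_end: int

    def validate_against(self, doc: ClinicalDocument) -> None:
        if not (0 <= self.char_start < self.char_end <= len(doc.text)):
            raise CorpusError(
                f"sentence offsets [{self.char_start}, {self.char_end}) out of "
                f"range for document {doc.doc_id} of length {len(doc.text)}"
            )
        if doc.text[self.char_start : self.char_end] != self.text:
            raise CorpusError(
                f"sentence text does not match document slice in {doc.doc_id}"
            )


def read_corpus(path: str | Path) -> list[PatientRecord]:
    """Read a JSONL corpus into patient records.

    Documents are grouped by ``patient_id``; within a patient, file order is
    preserved.  Patients are returned sorted by ``patient_id`` so that the
    result is independent of line interleaving.

    Raises
    ------
    CorpusError
        On malformed JSON (with line number), missing keys, or conflicting
        labels for one patient.
    """
    path = Path(path)
    order: dict[str, PatientRecord] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            try:
                patient_id = obj["patient_id"]
                doc_id = obj["doc_id"]
                text = obj["text"]
            except KeyError as exc:
                raise CorpusError(f"{path}:{lineno}: missing key {exc}") from exc
            label = obj.get("label")
            if label is not None and not isinstance(label, bool):
                raise CorpusError(f"{path}:{lineno}: label must be a JSON boolean")
            rec = order.get(patient_id)
            if rec is None:
                rec = PatientRecord(patient_id=patient_id, label=label)
                order[patient_id] = rec
            elif label is not None:
                if rec.label is not None and rec.label != label:
                    raise CorpusError(
                        f"{path}:{lineno}: conflicting labels for patient "
                        f"{patient_id!r}"
                    )
                rec.label = label
            if any(d.doc_id == doc_id for d in rec.documents):
                raise CorpusError(
                    f"{path}:{lineno}: duplicate doc_id {doc_id!r} for "
                    f"patient {patient_id!r}"
                )
            rec.documents.append(
                ClinicalDocument(doc_id=doc_id, patient_id=patient_id, text=text)
            )
    return [order[pid] for pid in sorted(order)]


def write_corpus(records: Iterable[PatientRecord], path: str | Path) -> Path:
    """Write records as JSONL (one document per line); round-trips through
    :func:`read_corpus`. Unlabeled patients get no ``label`` key."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            for doc in rec.documents:
                obj: dict = {
                    "patient_id": rec.patient_id,
                    "doc_id": doc.doc_id,
                    "text": doc.text,
                }
                if rec.label is not None:
                    obj["label"] = rec.label
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    return path


def whitespace_tokens(text: str) -> int:
    """Default token counter: whitespace-delimited tokens."""
    return len(text.split())


@dataclass
class CorpusStats:
    """Per-class corpus descriptives (documents, sentences, tokens).

    Statistics are arithmetic means; an empty class yields ``nan``
    ("undefined"), never zero.
    """

    avg_docs_per_patient: dict[str, float]
    avg_sentences_per_patient: dict[str, float]
    avg_tokens_per_patient: dict[str, float]
    avg_sentences_per_doc: dict[str, float]
    avg_tokens_per_doc: dict[str, float]
    avg_tokens_per_sentence: dict[str, float]
    tokens_per_sentence_by_category: dict[int, float]


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values) if values else math.nan


def corpus_stats(
    records: Sequence[PatientRecord],
    sentences: Sequence,
    tokenizer: Callable[[str], int] = whitespace_tokens,
    category_of=None,
) -> CorpusStats:
    """Compute per-class corpus descriptives.

    Parameters
    ----------
    records
        Labeled patient records; class is ``"AD"`` / ``"non-AD"`` by label
        (unlabeled patients are excluded from per-class rows).
    sentences
        Sentences (or tagged sentences) derived from the same records.  Any
        object with ``patient_id``, ``doc_id`` and ``text`` attributes works.
    tokenizer
        text -> token count; defaults to whitespace splitting.  Counts are
        backend-dependent by design (subword tokenizers count differently).
    category_of
        Optional callable mapping a sentence to an iterable of indicator
        category ids (1..8); enables the per-category token-mean rows.
    """
    label_of = {r.patient_id: r.label for r in records}
    classes = {"AD": True, "non-AD": False}

    sents_by_patient: dict[str, list] = {r.patient_id: [] for r in records}
    for s in sentences:
        if s.patient_id in sents_by_patient:
            sents_by_patient[s.patient_id].append(s)

    stats = CorpusStats({}, {}, {}, {}, {}, {}, {})
    for cls_name, cls_label in classes.items():
        pats = [r for r in records if label_of[r.patient_id] is cls_label]
        docs = [d for r in pats for d in r.documents]
        sents = [s for r in pats for s in sents_by_patient[r.patient_id]]
        doc_key = {(d.patient_id, d.doc_id) for d in docs}
        sent_tokens = {id(s): tokenizer(s.text) for s in sents}
        by_doc: dict[tuple[str, str], list] = {k: [] for k in doc_key}
        for s in sents:
            by_doc.setdefault((s.patient_id, s.doc_id), []).append(s)

        stats.avg_docs_per_patient[cls_name] = _mean([len(r.documents) for r in pats])
        stats.avg_sentences_per_patient[cls_name] = _mean(
            [len(sents_by_patient[r.patient_id]) for r in pats]
        )
        stats.avg_tokens_per_patient[cls_name] = _mean(
            [
                sum(sent_tokens[id(s)] for s in sents_by_patient[r.patient_id])
                for r in pats
            ]
        )
        stats.avg_sentences_per_doc[cls_name] = _mean(
            [len(by_doc[k]) for k in doc_key]
        )
        stats.avg_tokens_per_doc[cls_name] = _mean(
            [sum(sent_tokens[id(s)] for s in by_doc[k]) for k in doc_key]
        )
        stats.avg_tokens_per_sentence[cls_name] = _mean(
            [sent_tokens[id(s)] for s in sents]
        )

    if category_of is not None:
        per_cat: dict[int, list[int]] = {c: [] for c in range(1, 9)}
        for s in sentences:
            n_tok = tokenizer(s.text)
            for c in set(category_of(s)):
                per_cat[c].append(n_tok)
        for c in range(1, 9):
            stats.tokens_per_sentence_by_category[c] = _mean(per_cat[c])
    return stats


def render_stats_table(stats: CorpusStats) -> str:
    """Render the per-class and per-category statistics as TSV tables."""

    def fmt(x: float) -> str:
        return "undefined" if math.isnan(x) else f"{x:.2f}"

    lines = ["\tAD Patient\tNon-AD Patient"]
    rows = [
        ("Avg # docs (per patient)", stats.avg_docs_per_patient),
        ("Avg # sentences (per patient)", stats.avg_sentences_per_patient),
        ("Avg # tokens (per patient)", stats.avg_tokens_per_patient),
        ("Avg # sentences (per doc)", stats.avg_sentences_per_doc),
        ("Avg # tokens (per doc)", stats.avg_tokens_per_doc),
        ("Avg # tokens (per sentence)", stats.avg_tokens_per_sentence),
    ]
    for name, d in rows:
        lines.append(f"{name}\t{fmt(d['AD'])}\t{fmt(d['non-AD'])}")
    if stats.tokens_per_sentence_by_category:
        lines.append("")
        lines.append("\tMean # tokens per sentence")
        for c in range(1, 9):
            lines.append(f"Category {c}\t{fmt(stats.tokens_per_sentence_by_category[c])}")
    return "\n".join(lines) + "\n"
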