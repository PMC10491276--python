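"""Sentence splitting, indicator keyword matching and ConText-style assertion.

This is the rule-based stage of the pipeline: each document is split into
sentences, each sentence is scanned against the 8 indicator-category keyword
lexicons, and each keyword match is assigned an assertion status.  A mention
is *affirmed* unless a trigger phrase (e.g. "denies", "mother", "if") whose
directed token window covers the keyword marks it as negated, experienced by
someone other than the patient, or hypothetical — the ConText scheme of
trigger phrases with directed, terminator-bounded scopes.

Lexicons and triggers are data, not code: editable YAML files shipped as
package defaults (``data/lexicons.yaml``, ``data/context_triggers.yaml``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .corpus import ClinicalDocument, CorpusError, PatientRecord, Sentence

__all__ = [
    "AFFIRMED",
    "NEGATED",
    "OTHER_EXPERIENCER",
    "HYPOTHETICAL",
    "ASSERTIONS",
    "Lexicon",
    "ContextTrigger",
    "Match",
    "TaggedSentence",
    "load_lexicons",
    "load_triggers",
    "split_sentences",
    "match_categories",
    "assert_status",
    "tag_sentence",
    "tag_corpus",
]

AFFIRMED = "affirmed"
NEGATED = "negated"
OTHER_EXPERIENCER = "other_experiencer"
HYPOTHETICAL = "hypothetical"
ASSERTIONS = (AFFIRMED, NEGATED, OTHER_EXPERIENCER, HYPOTHETICAL)

# Precedence when several triggers cover a keyword at the same distance.
_PRECEDENCE = {NEGATED: 0, OTHER_EXPERIENCER: 1, HYPOTHETICAL: 2}
_SEMANTICS_TO_ASSERTION = {
    "negation": NEGATED,
    "other_experiencer": OTHER_EXPERIENCER,
    "hypothetical": HYPOTHETICAL,
}

_WORD_RE = re.compile(r"\w+(?:'\w+)?", re.UNICODE)


def _phrase_pattern(phrase: str) -> str:
    """Whole-phrase, case-insensitive pattern with word boundaries; internal
    whitespace matches any whitespace run."""
    parts = [re.escape(p) for p in phrase.split()]
    return r"\b" + r"\s+".join(parts) + r"\b"


@dataclass
class Lexicon:
    """Keyword inventory for one indicator category (1..8)."""

    category: int
    entries: list[str]
    _pattern: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.entries or any(e == "" for e in self.entries):
            raise ValueError(f"category {self.category}: empty lexicon entry")
        alts = []
        for e in self.entries:
            if e.startswith("re:"):
                alts.append(f"(?:{e[3:]})")
            else:
                alts.append(_phrase_pattern(e))
        self._pattern = re.compile("|".join(alts), re.IGNORECASE)

    def finditer(self, text: str):
        return self._pattern.finditer(text)


@dataclass(frozen=True)
class ContextTrigger:
    """One assertion trigger: phrase, semantics, directed scope in tokens."""

    phrase: str
    semantics: str  # negation | other_experiencer | hypothetical
    direction: str  # forward | backward | bidirectional
    scope: int = 10

    def __post_init__(self) -> None:
        if self.semantics not in _SEMANTICS_TO_ASSERTION:
            raise ValueError(f"unknown trigger semantics {self.semantics!r}")
        if self.direction not in ("forward", "backward", "bidirectional"):
            raise ValueError(f"unknown trigger direction {self.direction!r}")
        if self.scope < 1:
            raise ValueError("trigger scope must be >= 1")


@dataclass
class TriggerSet:
    triggers: list[ContextTrigger]
    terminators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._trigger_res = [
            (re.compile(_phrase_pattern(t.phrase), re.IGNORECASE), t)
            for t in self.triggers
        ]
        self._terminator_res = [
            re.compile(_phrase_pattern(t), re.IGNORECASE) for t in self.terminators
        ]


@dataclass(frozen=True)
class Match:
    """A keyword hit inside a sentence; span offsets are sentence-relative,
    0-based half-open."""

    category: int
    keyword: str
    start: int
    end: int
    assertion: str = AFFIRMED


@dataclass
class TaggedSentence:
    sentence: Sentence
    matches: list[Match]

    @property
    def patient_id(self) -> str:
        return self.sentence.patient_id

    @property
    def doc_id(self) -> str:
        return self.sentence.doc_id

    @property
    def text(self) -> str:
        return self.sentence.text

    def categories(self, assertion: str | None = None) -> set[int]:
        """Distinct matched categories, optionally filtered by assertion."""
        return {
            m.category
            for m in self.matches
            if assertion is None or m.assertion == assertion
        }


# ---------------------------------------------------------------------------
# YAML loading


def _data_text(name: str) -> str:
    return resources.files("phenopipe.data").joinpath(name).read_text("utf-8")


def load_lexicons(path: str | Path | None = None) -> dict[int, Lexicon]:
    """Load category→Lexicon from YAML; package defaults when *path* is None."""
    raw = (
        yaml.safe_load(Path(path).read_text("utf-8"))
        if path is not None
        else yaml.safe_load(_data_text("lexicons.yaml"))
    )
    lexicons = {int(c): Lexicon(int(c), list(entries)) for c, entries in raw.items()}
    if set(lexicons) != set(range(1, 9)):
        raise ValueError("lexicon file must define exactly categories 1..8")
    return lexicons


def load_triggers(path: str | Path | None = None) -> TriggerSet:
    """Load the ConText trigger inventory; package defaults when None."""
    raw = (
        yaml.safe_load(Path(path).read_text("utf-8"))
        if path is not None
        else yaml.safe_load(_data_text("context_triggers.yaml"))
    )
    triggers = [
        ContextTrigger(
            phrase=t["phrase"],
            semantics=t["semantics"],
            direction=t.get("direction", "forward"),
            scope=int(t.get("scope", 10)),
        )
        for t in raw["triggers"]
    ]
    return TriggerSet(triggers=triggers, terminators=list(raw.get("terminators", [])))


# ---------------------------------------------------------------------------
# Sentence splitting

_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st", "vs", "etc", "e.g", "i.e",
    "pt", "approx", "no",  # "no." as in "patient no. 5"
}

_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+|$)")
_PARA_RE = re.compile(r"\n[ \t]*\n")


def _is_abbreviation(text: str, punct_start: int) -> bool:
    # word immediately preceding the terminal punctuation
    m = re.search(r"(\w[\w.]*)$", text[:punct_start])
    if m is None:
        return False
    word = m.group(1).lower().rstrip(".")
    return word in _ABBREVIATIONS


def split_sentences(doc: ClinicalDocument) -> list[Sentence]:
    """Split a document into offset-anchored sentences.

    Boundaries are terminal punctuation (``.!?``) followed by whitespace —
    unless the preceding word is a known abbreviation — and blank lines
    (clinical notes often lack terminal punctuation between paragraphs).
    Sentences are whitespace-trimmed; offsets always slice back to the text.
    """
    text = doc.text
    cuts = {0, len(text)}
    for m in _BOUNDARY_RE.finditer(text):
        if not _is_abbreviation(text, m.start(1)):
            cuts.add(m.end(1))
    for m in _PARA_RE.finditer(text):
        cuts.add(m.start())
        cuts.add(m.end())
    bounds = sorted(cuts)

    sentences: list[Sentence] = []
    for a, b in zip(bounds, bounds[1:]):
        chunk = text[a:b]
        stripped = chunk.strip()
        if not stripped:
            continue
        start = a + (len(chunk) - len(chunk.lstrip()))
        end = start + len(stripped)
        sentences.append(
            Sentence(
                patient_id=doc.patient_id,
                doc_id=doc.doc_id,
                sent_index=len(sentences),
                text=stripped,
                char_start=start,
                char_end=end,
            )
        )
    return sentences


# ---------------------------------------------------------------------------
# Keyword matching

def match_categories(
    sentence: Sentence, lexicons: dict[int, Lexicon]
) -> list[Match]:
    """Scan a sentence against all category lexicons.

    Every category with at least one case-insensitive whole-phrase hit yields
    exactly one match (the earliest occurrence); overlapping hits in
    different categories are all reported.
    """
    out: list[Match] = []
    for cat in sorted(lexicons):
        first = None
        for m in lexicons[cat].finditer(sentence.text):
            if first is None or m.start() < first.start():
                first = m
        if first is not None:
            out.append(
                Match(
                    category=cat,
                    keyword=first.group(0),
                    start=first.start(),
                    end=first.end(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Assertion

def _token_spans(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def _span_to_token_range(
    spans: Sequence[tuple[int, int]], start: int, end: int
) -> tuple[int, int]:
    """Indices of tokens overlapping [start, end); (-1, -1) if none."""
    idx = [i for i, (a, b) in enumerate(spans) if a < end and b > start]
    return (idx[0], idx[-1]) if idx else (-1, -1)


def assert_status(
    sentence: Sentence, match: Match, triggers: TriggerSet
) -> str:
    """Assertion status of one keyword match.

    The nearest trigger whose directed token window (bounded by its scope and
    by terminator phrases) covers the keyword wins; on distance ties the
    precedence is negation > other_experiencer > hypothetical.  With no
    covering trigger, the match is affirmed.
    """
    text = sentence.text
    spans = _token_spans(text)
    kw_first, kw_last = _span_to_token_range(spans, match.start, match.end)
    if kw_first < 0:
        return AFFIRMED

    term_tokens: set[int] = set()
    for term_re in triggers._terminator_res:
        for m in term_re.finditer(text):
            i, j = _span_to_token_range(spans, m.start(), m.end())
            if i >= 0:
                term_tokens.update(range(i, j + 1))

    best: tuple[int, int] | None = None  # (distance, precedence)
    best_assertion = AFFIRMED
    for trig_re, trig in triggers._trigger_res:
        for m in trig_re.finditer(text):
            # trigger inside the keyword itself does not scope it
            if m.start() >= match.start and m.end() <= match.end:
                continue
            t_first, t_last = _span_to_token_range(spans, m.start(), m.end())
            if t_first < 0:
                continue
            covered = False
            distance = 0
            if trig.direction in ("forward", "bidirectional") and kw_first > t_last:
                distance = kw_first - t_last
                window = range(t_last + 1, min(t_last + trig.scope, len(spans) - 1) + 1)
                if kw_first in window and not any(
                    t in term_tokens for t in range(t_last + 1, kw_first)
                ):
                    covered = True
            if (
                not covered
                and trig.direction in ("backward", "bidirectional")
                and kw_last < t_first
            ):
                distance = t_first - kw_last
                window = range(max(t_first - trig.scope, 0), t_first)
                if kw_last in window and not any(
                    t in term_tokens for t in range(kw_last + 1, t_first)
                ):
                    covered = True
            if not covered:
                continue
            assertion = _SEMANTICS_TO_ASSERTION[trig.semantics]
            key = (distance, _PRECEDENCE[assertion])
            if best is None or key < best:
                best = key
                best_assertion = assertion
    return best_assertion


def tag_sentence(
    sentence: Sentence,
    lexicons: dict[int, Lexicon],
    triggers: TriggerSet,
) -> TaggedSentence:
    matches = [
        Match(m.category, m.keyword, m.start, m.end,
              assert_status(sentence, m, triggers))
        for m in match_categories(sentence, lexicons)
    ]
    return TaggedSentence(sentence=sentence, matches=matches)


def tag_corpus(
    records: Iterable[PatientRecord],
    lexicons: dict[int, Lexicon] | None = None,
    triggers: TriggerSet | None = None,
) -> dict[str, list[TaggedSentence]]:
    """Tag every sentence of every document, grouped by patient.

    Pure composition of :func:`split_sentences` → :func:`match_categories` →
    :func:`assert_status`; a sentence's tags never depend on other sentences.
    Sentences with no keyword hits are included (with empty ``matches``) so
    downstream stages can score *all* sentences.
    """
    lexicons = lexicons if lexicons is not None else load_lexicons()
    triggers = triggers if triggers is not None else load_triggers()
    out: dict[str, list[TaggedSentence]] = {}
    for rec in records:
        tagged: list[TaggedSentence] = []
        for doc in rec.documents:
            for sent in split_sentences(doc):
                sent.validate_against(doc)
                tagged.append(tag_sentence(sent, lexicons, triggers))
        out[rec.patient_id] = tagged
    return out
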