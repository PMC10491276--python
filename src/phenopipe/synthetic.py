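"""Synthetic labeled patient-note corpora with planted AD indicators.

The generator emulates the corpus structure the pipeline assumes, so every
downstream stage is testable without any real clinical data: each patient gets
a class-dependent number of documents and sentences; indicator mentions are
planted as template sentences built from the category keyword lexicons, in
affirmed, negated, other-experiencer and hypothetical contexts; the AD label
follows the UK Working Party rule (mandatory itchy-skin indicator plus at
least three qualifying indicators) applied to the affirmed indicators.

Ground truth records, per patient, the full set of categories *realized* by
the affirmed planted sentences.  Because keywords may belong to several
lexicons (e.g. "atopic eczema" realizes both the direct-AD category and the
eczema/rash category), realization is computed by an independent keyword scan
of each planted sentence, not assumed equal to the planted category.

Document/sentence counts per patient default to the corpus statistics the
pipeline was designed around: AD patients average ~23.4 documents of ~16.8
sentences, controls ~8.0 documents of ~24.3 sentences.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .corpus import ClinicalDocument, PatientRecord
from .tagger import (
    AFFIRMED,
    HYPOTHETICAL,
    NEGATED,
    OTHER_EXPERIENCER,
    Lexicon,
    load_lexicons,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "UKWPMapping",
    "ukwp_label",
    "plant_sentence",
    "generate_corpus",
    "write_truth_tsv",
    "read_truth_tsv",
]

CATEGORIES = tuple(range(1, 9))

# Sentence templates per assertion context.  Affirmed templates contain no
# trigger terms; the other templates use only in-inventory triggers.
TEMPLATES: dict[str, list[str]] = {
    AFFIRMED: [
        "Patient has {kw}.",
        "Patient reports {kw}.",
        "Patient presents with {kw} today.",
        "Exam notable for {kw}.",
        "Assessment: {kw}, continue current plan.",
        "Ongoing {kw} noted on exam.",
    ],
    NEGATED: [
        "No evidence of {kw}.",
        "Patient denies {kw}.",
        "Negative for {kw} at this visit.",
        "Denies any {kw}.",
        "{kw} was ruled out.",
    ],
    OTHER_EXPERIENCER: [
        "Mother has {kw}.",
        "Father was treated for {kw}.",
        "Family history of {kw}.",
        "Sister with {kw}.",
    ],
    HYPOTHETICAL: [
        "Return if {kw} develops.",
        "Monitor for {kw} at next visit.",
        "If {kw} occurs, start treatment.",
        "Patient is at risk for {kw}.",
    ],
}

FILLER_SENTENCES = [
    "Vital signs stable.",
    "Patient doing well overall.",
    "Medication list reviewed.",
    "Follow up in two weeks.",
    "Blood pressure 120 over 80.",
    "Reviewed lab results with patient.",
    "Patient ambulating independently.",
    "Plan discussed with care team.",
    "Sleep and appetite normal.",
    "Immunizations up to date.",
    "Routine screening completed.",
    "Patient tolerated the visit well.",
]


@dataclass(frozen=True)
class UKWPMapping:
    """Configurable mapping of the 8 indicator categories onto the UKWP rule:
    the mandatory itchy-skin criterion plus the categories that count toward
    the "3 or more" supporting criteria."""

    mandatory: int = 5
    qualifying: frozenset = frozenset({2, 3, 4, 7})
    min_qualifying: int = 3


def ukwp_label(indicators, mapping: UKWPMapping = UKWPMapping()) -> bool:
    """AD label from an 8-element indicator presence vector (index 0 = cat 1)."""
    present = {c for c in CATEGORIES if indicators[c - 1]}
    return (
        mapping.mandatory in present
        and len(present & mapping.qualifying) >= mapping.min_qualifying
    )


@dataclass
class GeneratorConfig:
    """Study conditions for corpus synthesis.

    ``case_plant_probs``/``control_plant_probs`` give, per category, the
    probability a patient of that class carries the indicator at all;
    ``intensity`` gives the mean number of *extra* affirmed sentences per
    planted indicator (each planted indicator yields ``1 + Poisson``
    sentences), loosely proportional to the per-category sentence-set sizes
    the pipeline's sentence classifiers are trained on.
    """

    n_patients: int = 400
    prevalence: float = 0.30
    case_plant_probs: dict = field(
        default_factory=lambda: {1: 0.70, 2: 0.80, 3: 0.35, 4: 0.85,
                                 5: 1.00, 6: 0.80, 7: 0.80, 8: 0.50}
    )
    control_plant_probs: dict = field(
        default_factory=lambda: {1: 0.03, 2: 0.25, 3: 0.10, 4: 0.35,
                                 5: 0.30, 6: 0.25, 7: 0.25, 8: 0.10}
    )
    intensity: dict = field(
        default_factory=lambda: {1: 1.5, 2: 0.6, 3: 0.3, 4: 4.0,
                                 5: 0.6, 6: 3.8, 7: 0.7, 8: 2.0}
    )
    negation_rate: float = 0.15
    other_experiencer_rate: float = 0.10
    hypothetical_rate: float = 0.10
    docs_per_patient: tuple = (23.44, 7.99)  # (case, control) Poisson means
    sentences_per_doc: tuple = (16.77, 24.25)
    filler_rate: float = 0.70
    ukwp: UKWPMapping = UKWPMapping()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for probs in (self.case_plant_probs, self.control_plant_probs):
            if set(probs) != set(CATEGORIES):
                raise ValueError("planting probabilities must cover categories 1..8")
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError("planting probabilities must lie in [0, 1]")
        for r in (self.negation_rate, self.other_experiencer_rate,
                  self.hypothetical_rate, self.filler_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_patients * self.prevalence < 1:
            warnings.warn("config implies zero positive patients in expectation")
        if self.n_patients * (1 - self.prevalence) < 1:
            warnings.warn("config implies zero control patients in expectation")

    def confounder_free(self) -> "GeneratorConfig":
        """Copy with all non-affirmed planting switched off."""
        return replace(
            self, negation_rate=0.0, other_experiencer_rate=0.0,
            hypothetical_rate=0.0,
        )


@dataclass
class GroundTruth:
    """Per-patient realized affirmed-indicator vectors and UKWP labels."""

    indicators: dict  # patient_id -> tuple of 8 bools
    labels: dict      # patient_id -> bool

    def indicator_matrix(self, patient_ids) -> np.ndarray:
        return np.array([self.indicators[p] for p in patient_ids], dtype=int)


class _KeywordScanner:
    """Independent whole-phrase keyword scan used for ground-truth
    bookkeeping (deliberately separate from the tagger's matcher)."""

    def __init__(self, lexicons: dict[int, Lexicon]):
        self._patterns: dict[int, list[re.Pattern]] = {}
        for cat, lex in lexicons.items():
            pats = []
            for entry in lex.entries:
                if entry.startswith("re:"):
                    pats.append(re.compile(entry[3:], re.IGNORECASE))
                else:
                    esc = r"\s+".join(re.escape(w) for w in entry.split())
                    pats.append(re.compile(rf"\b{esc}\b", re.IGNORECASE))
            self._patterns[cat] = pats

    def categories(self, text: str) -> set[int]:
        return {
            cat
            for cat, pats in self._patterns.items()
            if any(p.search(text) for p in pats)
        }


def plant_sentence(
    category: int,
    assertion: str,
    rng: np.random.Generator,
    lexicons: dict[int, Lexicon] | None = None,
) -> str:
    """One synthetic sentence containing exactly one keyword of *category*
    embedded in a template matching the requested assertion context."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if assertion not in TEMPLATES:
        raise ValueError(f"unknown assertion {assertion!r}")
    lexicons = lexicons if lexicons is not None else load_lexicons()
    entries = [e for e in lexicons[category].entries if not e.startswith("re:")]
    keyword = entries[rng.integers(len(entries))]
    template = TEMPLATES[assertion][rng.integers(len(TEMPLATES[assertion]))]
    text = template.format(kw=keyword)
    return text[0].upper() + text[1:]


def _sample_planted(
    probs: dict[int, float], is_case: bool, mapping: UKWPMapping,
    rng: np.random.Generator,
) -> set[int]:
    planted = {c for c in CATEGORIES if rng.random() < probs[c]}
    if is_case:
        planted.add(mapping.mandatory)
        missing = sorted(mapping.qualifying - planted)
        need = mapping.min_qualifying - len(planted & mapping.qualifying)
        if need > 0:
            extra = rng.choice(missing, size=need, replace=False)
            planted.update(int(c) for c in extra)
    return planted


def generate_corpus(
    config: GeneratorConfig,
    lexicons: dict[int, Lexicon] | None = None,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a labeled synthetic corpus plus its ground truth.

    Each patient's class is drawn at the configured prevalence; indicators are
    planted per class; the UKWP rule applied to the realized affirmed
    indicators always agrees with the drawn class (controls whose keyword
    overlap accidentally satisfies the rule are re-drawn).  Byte-identical
    output under a fixed seed.
    """
    lexicons = lexicons if lexicons is not None else load_lexicons()
    scanner = _KeywordScanner(lexicons)
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_patients))

    records: list[PatientRecord] = []
    indicators: dict[str, tuple] = {}
    labels: dict[str, bool] = {}

    for i in range(config.n_patients):
        pid = f"p{i + 1:0{width}d}"
        is_case = bool(rng.random() < config.prevalence)

        for _attempt in range(200):
            probs = config.case_plant_probs if is_case else config.control_plant_probs
            planted = _sample_planted(probs, is_case, config.ukwp, rng)
            affirmed_sents: list[str] = []
            for cat in sorted(planted):
                k = 1 + rng.poisson(config.intensity[cat])
                for _ in range(k):
                    affirmed_sents.append(
                        plant_sentence(cat, AFFIRMED, rng, lexicons)
                    )
            realized = set()
            for s in affirmed_sents:
                realized |= scanner.categories(s)
            truth_vec = tuple(c in realized for c in CATEGORIES)
            if ukwp_label(truth_vec, config.ukwp) == is_case:
                break
        else:
            raise RuntimeError(
                "could not realize a patient consistent with its class; "
                "check planting probabilities vs the UKWP mapping"
            )

        confounders: list[str] = []
        for cat in CATEGORIES:
            for assertion, rate in (
                (NEGATED, config.negation_rate),
                (OTHER_EXPERIENCER, config.other_experiencer_rate),
                (HYPOTHETICAL, config.hypothetical_rate),
            ):
                if rng.random() < rate:
                    confounders.append(plant_sentence(cat, assertion, rng, lexicons))

        cls = 0 if is_case else 1
        n_docs = max(1, int(rng.poisson(config.docs_per_patient[cls])))
        doc_sizes = [
            max(1, int(rng.poisson(config.sentences_per_doc[cls])))
            for _ in range(n_docs)
        ]
        total = sum(doc_sizes)
        specials = affirmed_sents + confounders
        n_filler = max(total - len(specials),
                       math.ceil(config.filler_rate * total))
        fillers = [
            FILLER_SENTENCES[rng.integers(len(FILLER_SENTENCES))]
            for _ in range(n_filler)
        ]
        sentences = specials + fillers
        order = rng.permutation(len(sentences))
        sentences = [sentences[j] for j in order]

        # distribute across documents following the drawn per-doc sizes,
        # scaled to the actual sentence count
        docs: list[ClinicalDocument] = []
        pos = 0
        for d, size in enumerate(doc_sizes):
            share = round(len(sentences) * size / total)
            chunk = sentences[pos : pos + max(1, share)]
            pos += len(chunk)
            if not chunk:
                break
            docs.append(
                ClinicalDocument(
                    doc_id=f"d{d + 1:03d}", patient_id=pid,
                    text=" ".join(chunk),
                )
            )
        if pos < len(sentences):
            rest = " ".join(sentences[pos:])
            last = docs[-1]
            docs[-1] = ClinicalDocument(
                doc_id=last.doc_id, patient_id=pid,
                text=last.text + " " + rest,
            )

        records.append(PatientRecord(patient_id=pid, documents=docs, label=is_case))
        indicators[pid] = truth_vec
        labels[pid] = is_case

    return records, GroundTruth(indicators=indicators, labels=labels)


def make_sentence_sets(
    n_per_category: int = 6000,
    test_fraction: float = 0.2,
    seed: int = 0,
    lexicons: dict[int, Lexicon] | None = None,
) -> dict[int, dict]:
    """Balanced, separable per-category sentence sets for classifier studies.

    For each category: ``n_per_category`` affirmed positive sentences and the
    same number of negatives drawn from affirmed sentences of the *other*
    categories (excluding any that realize the target category through
    keyword overlap).  Returns
    ``{category: {"train": (texts, labels), "test": (texts, labels)}}``.

    Template generation yields a limited string inventory per category, so
    train and test share surface forms; these sets measure separability and
    optimizer convergence, not generalization to unseen language.
    """
    lexicons = lexicons if lexicons is not None else load_lexicons()
    scanner = _KeywordScanner(lexicons)
    rng = np.random.default_rng(seed)
    out: dict[int, dict] = {}
    for cat in CATEGORIES:
        others = [c for c in CATEGORIES if c != cat]
        pos = [plant_sentence(cat, AFFIRMED, rng, lexicons)
               for _ in range(n_per_category)]
        neg: list[str] = []
        while len(neg) < n_per_category:
            c = others[rng.integers(len(others))]
            s = plant_sentence(c, AFFIRMED, rng, lexicons)
            if cat not in scanner.categories(s):
                neg.append(s)
        n_test = int(round(test_fraction * n_per_category))
        splits = {}
        for name, p_slice, n_slice in (
            ("test", pos[:n_test], neg[:n_test]),
            ("train", pos[n_test:], neg[n_test:]),
        ):
            texts = p_slice + n_slice
            labels = np.array([1] * len(p_slice) + [0] * len(n_slice))
            order = rng.permutation(len(texts))
            splits[name] = ([texts[i] for i in order], labels[order])
        out[cat] = splits
    return out


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("patient_id\t" + "\t".join(f"cat{c}" for c in CATEGORIES) + "\tlabel\n")
        for pid in sorted(truth.indicators):
            vec = truth.indicators[pid]
            fh.write(
                pid + "\t" + "\t".join(str(int(v)) for v in vec)
                + f"\t{int(truth.labels[pid])}\n"
            )
    return path


def read_truth_tsv(path: str | Path) -> GroundTruth:
    indicators: dict[str, tuple] = {}
    labels: dict[str, bool] = {}
    lines = Path(path).read_text("utf-8").splitlines()
    for line in lines[1:]:
        parts = line.split("\t")
        pid = parts[0]
        indicators[pid] = tuple(bool(int(x)) for x in parts[1:9])
        labels[pid] = bool(int(parts[9]))
    return GroundTruth(indicators=indicators, labels=labels)
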