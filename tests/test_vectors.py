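"""Patient vectors: max aggregation, binary affirmed indicators, highlighting."""

import numpy as np
import pytest

import phenopipe as pp
from phenopipe.corpus import ClinicalDocument
from phenopipe.mlp import MLPModel
from phenopipe.tagger import split_sentences
from phenopipe.vectors import binary_vector, highlight_sentences, probability_vector


def random_classifiers(rng, dim):
    return {
        c: MLPModel(W1=rng.normal(size=(dim, 6)), b1=rng.normal(size=6),
                    W2=rng.normal(size=(6, 2)), b2=rng.normal(size=2))
        for c in range(1, 9)
    }


def _record(texts, pid="p1"):
    docs = [ClinicalDocument(f"d{i}", pid, t) for i, t in enumerate(texts)]
    return pp.PatientRecord(pid, docs, label=None)


class TestProbabilityVector:
    def test_single_sentence_patient_equals_its_probabilities(self, backend):
        rng = np.random.default_rng(0)
        classifiers = random_classifiers(rng, backend.dim)
        rec = _record(["Patient has asthma"])
        pv = probability_vector(rec, classifiers, backend)
        emb = backend.embed(["Patient has asthma"])
        expected = [pp.predict_proba(classifiers[c], emb)[0] for c in range(1, 9)]
        assert pv.values == pytest.approx(expected)
        assert pv.provenance == [("d0", 0)] * 8

    def test_appending_a_sentence_never_decreases_elements(self, backend):
        rng = np.random.default_rng(1)
        classifiers = random_classifiers(rng, backend.dim)
        base = ["Patient has asthma.", "Plan reviewed."]
        v1 = probability_vector(_record(base), classifiers, backend).values
        v2 = probability_vector(_record(base + ["Denies rash."]),
                                classifiers, backend).values
        assert (v2 >= v1 - 1e-12).all()

    def test_equals_brute_force_double_loop(self, backend):
        rng = np.random.default_rng(2)
        classifiers = random_classifiers(rng, backend.dim)
        texts = ["Patient has asthma. Mother has eczema.",
                 "Dry skin noted. Follow up."]
        rec = _record(texts)
        pv = probability_vector(rec, classifiers, backend)
        sents = [s for d in rec.documents for s in split_sentences(d)]
        for c in range(1, 9):
            best = max(
                pp.predict_proba(classifiers[c], backend.embed([s.text]))[0]
                for s in sents
            )
            assert pv.values[c - 1] == pytest.approx(best)

    def test_scores_all_sentences_not_only_matched(self, backend):
        # a keyword-free sentence can still achieve an element's max
        rng = np.random.default_rng(3)
        classifiers = random_classifiers(rng, backend.dim)
        rec = _record(["Completely routine follow up visit."])
        pv = probability_vector(rec, classifiers, backend)
        assert pv.values.shape == (8,)  # scored despite zero keyword matches

    def test_order_permutation_invariant_values(self, backend):
        rng = np.random.default_rng(4)
        classifiers = random_classifiers(rng, backend.dim)
        texts = ["Patient has asthma.", "Dry skin noted.", "Plan reviewed."]
        v1 = probability_vector(_record(texts), classifiers, backend).values
        v2 = probability_vector(_record(texts[::-1]), classifiers, backend).values
        assert v1 == pytest.approx(v2)

    def test_zero_sentence_patient_rejected(self, backend):
        rng = np.random.default_rng(5)
        classifiers = random_classifiers(rng, backend.dim)
        rec = pp.PatientRecord("px", [ClinicalDocument("d0", "px", "   ")])
        with pytest.raises(ValueError, match="no sentences"):
            probability_vector(rec, classifiers, backend)


class TestBinaryVector:
    def test_denied_asthma_contributes_zero(self, lexicons, triggers):
        rec = _record(["Patient denies asthma."])
        tagged = pp.tag_corpus([rec], lexicons, triggers)["p1"]
        bv = binary_vector("p1", tagged)
        assert bv.values[6] == 0.0

    def test_affirmed_match_sets_element_with_provenance(self, lexicons, triggers):
        rec = _record(["Plan reviewed.", "Patient has asthma."])
        tagged = pp.tag_corpus([rec], lexicons, triggers)["p1"]
        bv = binary_vector("p1", tagged)
        assert bv.values[6] == 1.0
        assert bv.provenance[6] == ("d1", 0)

    def test_empty_patient_gives_all_zero(self):
        bv = binary_vector("p1", [])
        assert (bv.values == 0).all()

    def test_equals_generator_ground_truth(self, small_corpus, small_tagged):
        records, truth = small_corpus
        for rec in records:
            bv = binary_vector(rec.patient_id, small_tagged[rec.patient_id])
            assert np.array_equal(
                bv.values, np.array(truth.indicators[rec.patient_id], dtype=float)
            ), rec.patient_id

    def test_provenance_sentence_contains_keyword(self, small_corpus, small_tagged):
        records, _ = small_corpus
        for rec in records[:15]:
            tagged = small_tagged[rec.patient_id]
            bv = binary_vector(rec.patient_id, tagged)
            by_key = {(ts.doc_id, ts.sentence.sent_index): ts for ts in tagged}
            for c in range(8):
                if bv.values[c] == 1:
                    ts = by_key[bv.provenance[c]]
                    assert c + 1 in ts.categories(pp.AFFIRMED)

    def test_permutation_invariant(self, lexicons, triggers):
        texts = ["Patient has asthma.", "Mother has eczema.", "Dry skin noted."]
        t1 = pp.tag_corpus([_record(texts)], lexicons, triggers)["p1"]
        t2 = pp.tag_corpus([_record(texts[::-1])], lexicons, triggers)["p1"]
        assert np.array_equal(binary_vector("p1", t1).values,
                              binary_vector("p1", t2).values)


class TestHighlight:
    @pytest.fixture()
    def tagged_rec(self, lexicons, triggers):
        rec = _record(["Patient has asthma.", "Plan reviewed.",
                       "Patient denies rash."])
        return rec, pp.tag_corpus([rec], lexicons, triggers)["p1"]

    def test_rule_tags_only_lists_affirmed_matches(self, tagged_rec):
        rec, tagged = tagged_rec
        out = highlight_sentences(rec, tagged, threshold=1.0)
        assert [e["text"] for e in out] == ["Patient has asthma."]
        assert out[0]["assertions"] == {7: "affirmed"}

    def test_threshold_zero_lists_every_sentence(self, tagged_rec, backend):
        rec, tagged = tagged_rec
        rng = np.random.default_rng(6)
        out = highlight_sentences(rec, tagged,
                                  random_classifiers(rng, backend.dim),
                                  backend, threshold=0.0)
        assert len(out) == 3
        assert all(len(e["probs"]) == 8 for e in out)

    def test_invalid_threshold_rejected(self, tagged_rec):
        rec, tagged = tagged_rec
        with pytest.raises(ValueError, match="threshold"):
            highlight_sentences(rec, tagged, threshold=1.5)

    def test_planted_sentence_appears_with_its_category(self, small_corpus,
                                                        small_tagged):
        records, truth = small_corpus
        rec = next(r for r in records if truth.labels[r.patient_id])
        out = highlight_sentences(rec, small_tagged[rec.patient_id],
                                  threshold=1.0)
        listed = set().union(*(set(e["categories"]) for e in out))
        truth_cats = {c + 1 for c, v in
                      enumerate(truth.indicators[rec.patient_id]) if v}
        assert truth_cats <= listed
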