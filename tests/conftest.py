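import numpy as np
import pytest

import phenopipe as pp


@pytest.fixture(scope="session")
def lexicons():
    return pp.load_lexicons()


@pytest.fixture(scope="session")
def triggers():
    return pp.load_triggers()


@pytest.fixture(scope="session")
def backend():
    return pp.HashingBackend(dim=768, seed=0)


@pytest.fixture(scope="session")
def memo_embed(backend):
    """Memoized sentence embedder (template corpora repeat strings heavily)."""
    cache: dict[str, np.ndarray] = {}

    def embed(texts):
        out = np.empty((len(texts), backend.dim))
        for i, t in enumerate(texts):
            if t not in cache:
                cache[t] = backend.embed([t])[0]
            out[i] = cache[t]
        return out

    return embed


@pytest.fixture(scope="session")
def small_corpus():
    """Confounder-free synthetic corpus: 60 patients, fixed seed."""
    cfg = pp.GeneratorConfig(n_patients=60, seed=3).confounder_free()
    return pp.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_tagged(small_corpus):
    records, _ = small_corpus
    return pp.tag_corpus(records)


def make_sentence(text, patient_id="p", doc_id="d", sent_index=0):
    return pp.Sentence(
        patient_id=patient_id, doc_id=doc_id, sent_index=sent_index,
        text=text, char_start=0, char_end=len(text),
    )
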