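import numpy as np
import pytest

import dilitext as dt


@pytest.fixture(scope="session")
def toy_spec():
    return dt.GeneratorSpec(
        n_docs=200,
        positive_fraction=0.35,
        vocabulary_size=60,
        n_signal_terms=8,
        rate_ratio=4.0,
        mean_doc_length=120.0,
        n_phrases=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_data(toy_spec):
    """One strong-signal corpus shared across test modules."""
    dct, rec = dt.make_toy_dictionary(toy_spec)
    docs = dt.simulate_corpus(toy_spec, dct, rec)
    counts = dt.extract_corpus(docs, dct, rec)
    m = dt.build_count_matrix(counts)
    weighted = dt.tfidf_weight(m)
    labels = np.array([d.label for d in docs])
    return {
        "spec": toy_spec,
        "dictionary": dct,
        "recoding": rec,
        "docs": docs,
        "counts": m,
        "dtm": weighted,
        "labels": labels,
        "signal": set(dt.signal_terms(toy_spec, dct)),
    }


@pytest.fixture(scope="session")
def toy_model(toy_data):
    return dt.train_booster(
        toy_data["dtm"], toy_data["labels"], dt.BoosterConfig(seed=11)
    )


@pytest.fixture
def tiny_dictionary():
    return dt.TermDictionary(
        entries=frozenset(
            {"hepatitis", "jaundice", "hepatic failure", "hepatotoxicity"}
        ),
        name="tiny",
    )


@pytest.fixture
def tiny_recoding():
    return dt.RecodingMap(
        rules={
            "autoimmune hepatitis": "hepatitis",
            "chronic hepatitis b": "hepatitis",
            "aminotransferases": "aminotransferase",
        }
    )
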