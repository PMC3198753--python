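"""Shared fixtures: a small end-to-end synthetic run reused across modules."""

import numpy as np
import pytest
import scipy.sparse as sp

import concernminer as cm
from concernminer.text_prep import TermDocMatrix, Vocabulary


@pytest.fixture(scope="session")
def topic_model():
    return cm.default_topic_model()


@pytest.fixture(scope="session")
def small_run(topic_model):
    """A complete small pipeline run (seed 5): 800 background docs, 3,000
    participants, k=30 space, 12 clusters. Scaled for unit tests; the
    full-scale recovery run lives in the acceptance suite."""
    docs = cm.generate_background_docs(800, topic_model, seed=5)
    participants = cm.generate_participants(3000, seed=5)
    responses, truth = cm.generate_responses(participants, topic_model, 0.546, seed=5)
    patterns = cm.default_patterns()
    meaningful, meaningless = cm.split_responses(responses, patterns)
    corpus = list(docs) + [t for t in meaningful["text"]]
    vocab = cm.build_vocabulary(corpus)
    tdm = cm.build_term_doc_matrix(corpus, vocab)
    space = cm.build_space(tdm, 30)
    terms = cm.select_cluster_terms(
        [t for t in meaningful["text"]], min_freq=20, vocabulary=set(vocab.index)
    )
    dist = cm.build_distance_matrix(space, terms)
    clustering = cm.pam_cluster(dist, 12)
    table = cm.assign_responses(space, meaningful, clustering, terms.terms, 0.2)
    return {
        "model": topic_model,
        "docs": docs,
        "participants": participants,
        "responses": responses,
        "truth": truth,
        "patterns": patterns,
        "meaningful": meaningful,
        "meaningless": meaningless,
        "corpus": corpus,
        "vocab": vocab,
        "tdm": tdm,
        "space": space,
        "terms": terms,
        "dist": dist,
        "clustering": clustering,
        "assignments": table,
    }


def fake_tdm(array) -> TermDocMatrix:
    """Wrap an arbitrary numeric matrix as a raw-weighted TermDocMatrix with
    a synthetic vocabulary, for SVD tests on random matrices."""
    arr = np.asarray(array, dtype=float)
    vocab = Vocabulary(
        index={f"t{i:04d}": i for i in range(arr.shape[0])},
        frequency={f"t{i:04d}": 1 for i in range(arr.shape[0])},
    )
    m = sp.csr_matrix(arr)
    return TermDocMatrix(matrix=m, weighting="raw", vocab=vocab, raw=m)
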