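"""Shared fixtures: the default synthetic corpus and models fitted on it.

Session-scoped so the expensive Gibbs fits run once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from pasctopics import lda, preprocess
from pasctopics.synthetic_data import default_pasc_config, generate_corpus


@pytest.fixture(scope="session")
def default_corpus():
    """The default two-class synthetic corpus (73 PASC / 114 non-PASC)."""
    return generate_corpus(default_pasc_config(seed=1))


@pytest.fixture(scope="session")
def default_streams(default_corpus):
    corpus, _ = default_corpus
    return preprocess.preprocess_corpus(
        corpus.texts(), doc_ids=[d.doc_id for d in corpus]
    )


@pytest.fixture(scope="session")
def default_vocab(default_streams):
    return preprocess.build_vocabulary(default_streams)


@pytest.fixture(scope="session")
def default_bows(default_streams, default_vocab):
    return [preprocess.to_bag_of_words(s, default_vocab) for s in default_streams]


@pytest.fixture(scope="session")
def fitted_k3(default_bows, default_vocab):
    """LDA with the true topic count, fitted on the default corpus."""
    return lda.fit_lda(default_bows, default_vocab, k=3, n_iterations=800, seed=1)


def true_phi_in_vocab(truth, vocab) -> np.ndarray:
    """Ground-truth phi re-indexed into a fitted vocabulary's column order."""
    phi = np.zeros((truth.phi.shape[0], vocab.size))
    for j, w in enumerate(truth.vocabulary):
        if w in vocab.index:
            phi[:, vocab.index[w]] = truth.phi[:, j]
    return phi
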