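"""Collapsed-Gibbs LDA: degeneracies, oracles, scores and model selection."""

import numpy as np
import pytest

from pasctopics.lda import (
    LdaModel,
    ModelSelectionRecord,
    assignment_trace,
    choose_k_from_records,
    dominant_topic,
    fit_lda,
    log_perplexity,
    select_k,
    topic_keywords,
    umass_coherence,
)
from pasctopics.preprocess import TokenStream, build_vocabulary, to_bag_of_words

from .oracles import batch_means_se, enumerate_assignment_posterior


def corpus_from_token_lists(token_lists):
    streams = [
        TokenStream(doc_id=f"d{i}", tokens=tuple(toks))
        for i, toks in enumerate(token_lists)
    ]
    vocab = build_vocabulary(streams)
    return [to_bag_of_words(s, vocab) for s in streams], vocab


class TestFit:
    def test_single_topic_degeneracy(self):
        """k=1: every theta is [1] and phi is the smoothed word frequency."""
        bows, vocab = corpus_from_token_lists([["a", "b", "a"], ["b", "c"]])
        model = fit_lda(bows, vocab, k=1, eta=0.01, n_iterations=5, seed=0)
        assert np.allclose(model.theta, 1.0)
        counts = np.array([2, 2, 1])  # a, b, c occurrences
        expected = (counts + 0.01) / (counts.sum() + 3 * 0.01)
        assert np.allclose(model.phi[0], expected)

    def test_two_block_corpus_separates(self):
        """Docs over disjoint vocabularies get different dominant topics."""
        block1 = [["a", "b", "c", "d", "e"] * 3] * 10
        block2 = [["f", "g", "h", "i", "j"] * 3] * 10
        bows, vocab = corpus_from_token_lists(block1 + block2)
        model = fit_lda(bows, vocab, k=2, alpha=0.1, n_iterations=500, seed=0)
        dom = [dominant_topic(t) for t in model.theta]
        assert len(set(dom[:10])) == 1
        assert len(set(dom[10:])) == 1
        assert dom[0] != dom[10]

    def test_seed_determinism(self):
        bows, vocab = corpus_from_token_lists([["a", "b"], ["b", "c", "c"]])
        m1 = fit_lda(bows, vocab, k=2, n_iterations=50, seed=7)
        m2 = fit_lda(bows, vocab, k=2, n_iterations=50, seed=7)
        assert np.array_equal(m1.z, m2.z)
        assert np.array_equal(m1.phi, m2.phi)
        assert np.array_equal(m1.theta, m2.theta)

    def test_count_conservation(self, fitted_k3, default_bows):
        """Final z reproduces per-document and per-topic token totals."""
        model = fitted_k3
        doc_lengths = np.array([b.n_tokens for b in default_bows])
        n_dt = np.zeros((len(default_bows), model.k), dtype=int)
        pos = 0
        for d, L in enumerate(doc_lengths):
            for t in model.z[pos : pos + L]:
                n_dt[d, t] += 1
            pos += L
        assert pos == len(model.z)
        assert np.array_equal(n_dt.sum(axis=1), doc_lengths)
        assert n_dt.sum() == doc_lengths.sum()

    def test_empty_document_rejected(self):
        vocab = build_vocabulary([TokenStream("v", ("a", "b"))])
        streams = [TokenStream("d0", ("a", "b")), TokenStream("d1", ("z",))]
        bows = [to_bag_of_words(s, vocab) for s in streams]  # d1 is all OOV
        with pytest.raises(ValueError, match="d1"):
            fit_lda(bows, vocab, k=2, n_iterations=5, seed=0)

    def test_k_exceeding_tokens_warns(self):
        bows, vocab = corpus_from_token_lists([["a", "b"]])
        with pytest.warns(UserWarning, match="exceeds"):
            fit_lda(bows, vocab, k=10, n_iterations=5, seed=0)


class TestGibbsPosteriorOracle:
    def test_matches_exhaustive_enumeration(self):
        """Sampled assignment frequencies match the exact collapsed posterior.

        One 3-token document, k=2, V=4: all 8 assignment vectors are
        enumerated exactly; chain frequencies must agree within 3 standard
        errors (batch means, robust to autocorrelation).
        """
        streams = [TokenStream("d0", ("a", "b", "c"))]
        vocab = build_vocabulary([TokenStream("v", ("a", "b", "c", "d"))])
        bows = [to_bag_of_words(streams[0], vocab)]
        alpha, eta = 0.5, 0.01
        exact = enumerate_assignment_posterior([0, 1, 2], alpha, eta, k=2, V=4)

        trace = assignment_trace(
            bows, vocab, k=2, alpha=alpha, eta=eta,
            n_sweeps=21000, burn_in=1000, seed=3,
        )
        for z_vec, p_exact in exact.items():
            hits = (trace == np.array(z_vec)).all(axis=1)
            p_hat = hits.mean()
            se = max(batch_means_se(hits.astype(float)), 1e-4)
            assert abs(p_hat - p_exact) <= 3 * se, (z_vec, p_hat, p_exact, se)


class TestScores:
    def test_uniform_phi_perplexity(self):
        """With phi uniform over V=10 the mixture collapses to 1/V exactly."""
        V, k = 10, 3
        model = LdaModel(
            k=k, alpha=0.1, eta=0.01,
            phi=np.full((k, V), 1 / V),
            theta=np.array([[0.2, 0.3, 0.5]]),
            z=np.zeros(1, dtype=np.int32), seed=0, n_iterations=1,
        )
        bows, _ = corpus_from_token_lists([["a", "b", "c"]])
        assert log_perplexity(model, bows) == pytest.approx(-np.log2(10), abs=1e-12)

    def test_certain_word_perplexity_zero(self):
        phi = np.zeros((2, 3))
        phi[:, 0] = 1.0
        model = LdaModel(
            k=2, alpha=0.1, eta=0.01, phi=phi,
            theta=np.array([[0.4, 0.6]]),
            z=np.zeros(1, dtype=np.int32), seed=0, n_iterations=1,
        )
        bows, _ = corpus_from_token_lists([["a"]])
        assert log_perplexity(model, bows) == 0.0

    def test_hand_computed_mixture(self):
        """3-token document against a fully specified theta/phi."""
        phi = np.array([[0.5, 0.3, 0.1, 0.1], [0.1, 0.1, 0.4, 0.4]])
        theta = np.array([[0.25, 0.75]])
        model = LdaModel(
            k=2, alpha=0.1, eta=0.01, phi=phi, theta=theta,
            z=np.zeros(3, dtype=np.int32), seed=0, n_iterations=1,
        )
        vocab = build_vocabulary([TokenStream("v", ("a", "b", "c", "d"))])
        bows = [to_bag_of_words(TokenStream("d0", ("a", "c", "c")), vocab)]
        p_a = 0.25 * 0.5 + 0.75 * 0.1
        p_c = 0.25 * 0.1 + 0.75 * 0.4
        expected = (np.log2(p_a) + 2 * np.log2(p_c)) / 3
        assert log_perplexity(model, bows) == pytest.approx(expected, abs=1e-12)

    def test_out_of_vocabulary_index_rejected(self):
        model = LdaModel(
            k=1, alpha=0.1, eta=0.01, phi=np.array([[1.0]]),
            theta=np.array([[1.0]]), z=np.zeros(1, dtype=np.int32),
            seed=0, n_iterations=1,
        )
        from pasctopics.preprocess import BagOfWords

        with pytest.raises(ValueError, match="outside"):
            log_perplexity(model, [BagOfWords("d", ((5, 1),))])

    def _model_with_top_words(self, phi):
        phi = np.asarray(phi, dtype=float)
        return LdaModel(
            k=phi.shape[0], alpha=0.1, eta=0.01, phi=phi,
            theta=np.full((1, phi.shape[0]), 1 / phi.shape[0]),
            z=np.zeros(1, dtype=np.int32), seed=0, n_iterations=1,
        )

    def test_umass_hand_count(self):
        """Docs {a,b}, {a}, {b}; top words [a, b]: log((1+1)/2) = 0."""
        bows, _ = corpus_from_token_lists([["a", "b"], ["a"], ["b"]])
        model = self._model_with_top_words([[0.7, 0.3]])
        assert umass_coherence(model, bows, top_n=2) == pytest.approx(0.0, abs=1e-12)

    def test_umass_positive_when_perfectly_nested(self):
        """If every doc containing the top word also has the second, terms are > 0."""
        bows, _ = corpus_from_token_lists([["a", "b"], ["a", "b"], ["c"]])
        model = self._model_with_top_words([[0.6, 0.3, 0.1]])
        assert umass_coherence(model, bows, top_n=2) > 0

    def test_umass_identical_topics_identical_scores(self):
        bows, _ = corpus_from_token_lists([["a", "b", "c"], ["a", "c"]])
        phi = [[0.5, 0.3, 0.2], [0.5, 0.3, 0.2]]
        model = self._model_with_top_words(phi)
        one_topic = self._model_with_top_words(phi[:1])
        assert umass_coherence(model, bows) == pytest.approx(
            umass_coherence(one_topic, bows), abs=1e-12
        )


class TestKeywordsAndSelection:
    def test_k1_keywords_are_frequency_order(self):
        bows, vocab = corpus_from_token_lists(
            [["febbre", "febbre", "tosse"], ["febbre", "medico"]]
        )
        model = fit_lda(bows, vocab, k=1, n_iterations=5, seed=0)
        kws = topic_keywords(model, vocab)
        assert kws[0][0][0] == "febbre"

    def test_top_n_capped_at_vocabulary(self):
        bows, vocab = corpus_from_token_lists([["a", "b"]])
        model = fit_lda(bows, vocab, k=1, n_iterations=5, seed=0)
        assert len(topic_keywords(model, vocab, top_n=50)[0]) == 2

    def test_keyword_weights_non_increasing(self, fitted_k3, default_vocab):
        for pairs in topic_keywords(fitted_k3, default_vocab).values():
            weights = [w for _, w in pairs]
            assert weights == sorted(weights, reverse=True)
            assert len({t for t, _ in pairs}) == len(pairs)

    def test_singleton_grid(self):
        bows, vocab = corpus_from_token_lists([["a", "b", "a"], ["b", "c"]])
        records, chosen = select_k(bows, vocab, k_grid=[3], n_iterations=5, seed=0)
        assert chosen == 3 and len(records) == 1

    def test_published_sweep_values_choose_three(self):
        """The published coherence/perplexity sweep selects k=3."""
        records = [
            ModelSelectionRecord(3, 0.407, -7.248),
            ModelSelectionRecord(5, 0.332, -7.337),
            ModelSelectionRecord(7, 0.299, -7.398),
            ModelSelectionRecord(10, 0.346, -7.5239),
        ]
        assert choose_k_from_records(records) == 3

    def test_perplexity_breaks_near_ties(self):
        records = [
            ModelSelectionRecord(3, 0.400, -7.5),
            ModelSelectionRecord(5, 0.405, -7.0),  # within band, better perplexity
        ]
        assert choose_k_from_records(records) == 5

    def test_true_topic_count_wins_majority(self, default_bows, default_vocab):
        """Majority of seeds select the generative k=3 on default corpora."""
        from pasctopics.synthetic_data import default_pasc_config, generate_corpus
        from pasctopics.preprocess import build_vocabulary, preprocess_corpus, to_bag_of_words

        chosen = []
        for seed in range(1, 6):
            corpus, _ = generate_corpus(default_pasc_config(seed=seed))
            streams = preprocess_corpus(corpus.texts())
            vocab = build_vocabulary(streams)
            bows = [to_bag_of_words(s, vocab) for s in streams]
            _, k = select_k(bows, vocab, n_iterations=300, seed=seed)
            chosen.append(k)
        assert max(set(chosen), key=chosen.count) == 3


class TestDominantTopic:
    @pytest.mark.parametrize(
        "theta, expected",
        [([0.2, 0.7, 0.1], 1), ([0.5, 0.5], 0), ([1.0], 0)],
    )
    def test_argmax_with_tie_rule(self, theta, expected):
        assert dominant_topic(np.array(theta)) == expected


class TestModelInvariants:
    def test_rows_are_distributions(self, fitted_k3):
        assert np.allclose(fitted_k3.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(fitted_k3.theta.sum(axis=1), 1.0, atol=1e-9)
        assert (fitted_k3.phi > 0).all()
        assert (fitted_k3.theta > 0).all()
        assert fitted_k3.z.min() >= 0 and fitted_k3.z.max() < fitted_k3.k
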