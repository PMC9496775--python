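"""Embedding, reduction, HDBSCAN and class-based TF-IDF keywords."""

import math

import numpy as np
import pytest
from sklearn.cluster import HDBSCAN as SkHDBSCAN
from sklearn.metrics import adjusted_rand_score

from pasctopics._hdbscan import (
    core_distances,
    hdbscan_flat,
    mst_edges,
    mutual_reachability,
    pairwise_distances,
)
from pasctopics.embed_cluster import (
    ClusteringResult,
    assign_topics,
    class_tfidf_keywords,
    embed_documents,
    hdbscan_cluster,
    reduce_dimensions,
)
from pasctopics.preprocess import TokenStream

from .oracles import brute_force_mst_weight


def ts(*tokens, doc_id="d"):
    return TokenStream(doc_id=doc_id, tokens=tokens)


def blob_set(seed):
    """Two tight blobs plus distant outliers — the oracle comparison sets."""
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(15, 26, size=2)
    n_out = int(rng.integers(1, 4))
    return np.vstack(
        [
            rng.normal([0, 0], 0.1, (n1, 2)),
            rng.normal([10, 0], 0.1, (n2, 2)),
            rng.normal([25, 25], 0.5, (n_out, 2)),
        ]
    )


class TestEmbedding:
    def test_identical_documents_identical_rows(self):
        emb = embed_documents([ts("a", "b"), ts("a", "b"), ts("c")])
        assert np.array_equal(emb.matrix[0], emb.matrix[1])

    def test_rows_unit_norm(self):
        emb = embed_documents([ts("a", "b", "b"), ts("c", "d")])
        assert np.allclose(np.linalg.norm(emb.matrix, axis=1), 1.0)

    def test_disjoint_vocabularies_orthogonal(self):
        emb = embed_documents([ts("a", "b"), ts("c", "d")])
        assert emb.matrix[0] @ emb.matrix[1] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_embedder(self):
        with pytest.raises(KeyError, match="unknown embedder"):
            embed_documents([ts("a")], embedder="bert-download")


class TestReduction:
    def test_none_is_identity(self):
        emb = embed_documents([ts("a", "b"), ts("b", "c"), ts("c", "a")])
        assert reduce_dimensions(emb, 2, method="none") is emb

    def test_rank_one_data_exact(self):
        base = np.array([1.0, 2.0, 3.0])
        from pasctopics.embed_cluster import EmbeddingMatrix

        emb = EmbeddingMatrix(np.outer([1, 2, 3, 4], base), "x")
        red = reduce_dimensions(emb, 1, method="pca")
        # 1 component reconstructs rank-1 data exactly: variance fully kept
        centered = emb.matrix - emb.matrix.mean(axis=0)
        assert np.allclose(
            np.linalg.norm(red.matrix) ** 2, np.linalg.norm(centered) ** 2
        )

    def test_collinear_points_second_component_zero(self):
        from pasctopics.embed_cluster import EmbeddingMatrix

        direction = np.ones(10)
        pts = np.outer([0.0, 1.0, 2.0], direction)
        red = reduce_dimensions(EmbeddingMatrix(pts, "x"), 2, method="pca")
        assert np.allclose(red.matrix[:, 1], 0.0, atol=1e-9)

    def test_too_many_components(self):
        emb = embed_documents([ts("a"), ts("b")])
        with pytest.raises(ValueError, match="exceeds"):
            reduce_dimensions(emb, emb.d + 1)


class TestHdbscanPrimitives:
    def test_mutual_reachability_dominates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        D = pairwise_distances(X)
        core = core_distances(D, 5)
        M = mutual_reachability(D, core)
        off = ~np.eye(30, dtype=bool)
        assert (M[off] >= D[off] - 1e-12).all()
        assert (M >= core[:, None] - 1e-12)[off].all()
        assert (M >= core[None, :] - 1e-12)[off].all()

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_mst_weight_is_brute_force_minimum(self, n):
        rng = np.random.default_rng(n)
        X = rng.normal(size=(n, 2))
        D = pairwise_distances(X)
        edges = mst_edges(D)
        # it is a spanning tree ...
        seen = {0}
        for u, v, _ in edges:
            seen.update((int(u), int(v)))
        assert seen == set(range(n)) and len(edges) == n - 1
        # ... and no (n-1)-edge subset is lighter
        assert edges[:, 2].sum() == pytest.approx(brute_force_mst_weight(D), abs=1e-9)


class TestHdbscanClustering:
    def test_forced_noise_when_too_few_points(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="noise"):
            labels, probs = hdbscan_flat(rng.normal(size=(5, 2)), min_cluster_size=10)
        assert (labels == -1).all()
        assert (probs == 0).all()

    def test_two_blobs_one_outlier(self):
        """20+20 tight blobs and one far point: 2 clusters, 1 noise doc."""
        rng = np.random.default_rng(42)
        X = np.vstack(
            [
                rng.normal([0, 0], 0.1, (20, 2)),
                rng.normal([10, 0], 0.1, (20, 2)),
                [[50.0, 50.0]],
            ]
        )
        labels, probs = hdbscan_flat(X, min_cluster_size=5)
        assert set(labels) == {1, 2, -1}
        assert (labels == -1).sum() == 1
        assert labels[-1] == -1
        assert probs[-1] == 0.0
        assert probs[labels != -1].max() == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reference_implementation(self, seed):
        """Labels agree with sklearn's HDBSCAN up to renumbering (ARI = 1)."""
        X = blob_set(seed)
        mine, _ = hdbscan_flat(X, min_cluster_size=5)
        ref = SkHDBSCAN(min_cluster_size=5, min_samples=5, copy=True).fit_predict(X)
        assert adjusted_rand_score(mine, ref) == 1.0
        assert ((mine == -1) == (ref == -1)).all()

    def test_cluster_one_is_largest(self):
        X = blob_set(3)
        labels, _ = hdbscan_flat(X, min_cluster_size=5)
        sizes = {c: (labels == c).sum() for c in set(labels) - {-1}}
        assert sizes[1] == max(sizes.values())

    def test_deterministic_end_to_end(self):
        streams = [
            ts(*(["a", "b"] * 10), doc_id=f"x{i}") for i in range(12)
        ] + [ts(*(["c", "d"] * 10), doc_id=f"y{i}") for i in range(12)]
        runs = []
        for _ in range(2):
            emb = embed_documents(streams, seed=0)
            red = reduce_dimensions(emb, 2, seed=0)
            runs.append(hdbscan_cluster(red, min_cluster_size=5).labels)
        assert np.array_equal(runs[0], runs[1])


class TestClassTfidf:
    def test_hand_example(self):
        """Two clusters with A = 3 tokens/cluster average; hand arithmetic."""
        table = class_tfidf_keywords(
            {
                0: ["febbre", "febbre", "tosse"],
                1: ["paziente", "paziente", "tosse"],
            }
        )
        assert table.mean_cluster_tokens == pytest.approx(3.0)
        w = dict(table.keywords[0])
        assert w["febbre"] == pytest.approx(2 * math.log(1 + 3 / 2), abs=1e-12)
        assert w["tosse"] == pytest.approx(1 * math.log(1 + 3 / 2), abs=1e-12)
        assert table.keywords[0][0][0] == "febbre"

    def test_absent_term_not_listed(self):
        table = class_tfidf_keywords({0: ["a", "a"], 1: ["b"]})
        assert "b" not in dict(table.keywords[0])

    def test_single_cluster_well_defined(self):
        table = class_tfidf_keywords({0: ["a", "a", "b"]})
        w = dict(table.keywords[0])
        assert w["a"] == pytest.approx(2 * math.log(1 + 3 / 2), abs=1e-12)

    def test_noise_cluster_excluded(self):
        table = class_tfidf_keywords({-1: ["z"] * 100, 0: ["a"], 1: ["b"]})
        assert -1 not in table.keywords
        assert table.mean_cluster_tokens == pytest.approx(1.0)

    def test_count_scaling_preserves_rankings(self):
        base = {0: ["a"] * 3 + ["b"] * 2, 1: ["b"] * 4 + ["c"]}
        scaled = {c: toks * 5 for c, toks in base.items()}
        t1, t5 = class_tfidf_keywords(base), class_tfidf_keywords(scaled)
        for c in base:
            assert [t for t, _ in t1.keywords[c]] == [t for t, _ in t5.keywords[c]]

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            class_tfidf_keywords({0: []})


class TestAssignTopics:
    def test_identity_on_hard_labels(self):
        res = ClusteringResult(
            labels=np.array([1, 1, 2, -1]), strengths=np.array([1, 1, 1, 0.0])
        )
        assert assign_topics(res).tolist() == [1, 1, 2, -1]

    def test_all_noise(self):
        res = ClusteringResult(
            labels=np.array([-1, -1]), strengths=np.zeros(2)
        )
        assert assign_topics(res).tolist() == [-1, -1]
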