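"""The embedding/clustering topic track (BERTopic-style).

Four stages: embed documents into vectors, reduce dimensionality, cluster
densities with HDBSCAN (unassigned documents form the virtual "topic -1"),
and describe each cluster with class-based TF-IDF keywords.

The default embedder is deterministic L2-normalized TF-IDF over the corpus
vocabulary and the default reducer is PCA, so the whole track is exactly
reproducible offline; pre-trained sentence-transformer embeddings and UMAP
plug in through the adapter registries without code changes here.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import TfidfVectorizer

from . import _hdbscan
from .preprocess import TokenStream

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingMatrix",
    "ClusteringResult",
    "ClassTfidfTable",
    "TfidfDocumentEmbedder",
    "HDBSCAN",
    "register_embedder",
    "register_reducer",
    "embed_documents",
    "reduce_dimensions",
    "hdbscan_cluster",
    "class_tfidf_keywords",
    "assign_topics",
]


@dataclass
class EmbeddingMatrix:
    """D x d document embedding, one row per document in corpus order."""

    matrix: np.ndarray
    embedder_id: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_docs(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ClusteringResult:
    """Hard per-document labels (noise = -1, clusters 1..C by size)."""

    labels: np.ndarray
    strengths: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        assert (self.labels >= -1).all()
        assert np.all(self.strengths[self.labels == -1] == 0.0)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels[self.labels != -1], return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    @property
    def n_noise(self) -> int:
        return int((self.labels == -1).sum())


@dataclass
class ClassTfidfTable:
    """Per-cluster keyword lists from class-based TF-IDF."""

    keywords: dict[int, list[tuple[str, float]]]
    mean_cluster_tokens: float  # the normalizer A


class TfidfDocumentEmbedder(BaseEstimator, TransformerMixin):
    """L2-normalized TF-IDF document vectors over pre-tokenized streams.

    A deterministic, download-free stand-in for a sentence-embedding model:
    documents sharing vocabulary land close in cosine geometry, documents
    with disjoint vocabularies are orthogonal.
    """

    def __init__(self) -> None:
        self._vec = TfidfVectorizer(
            analyzer=lambda tokens: tokens, lowercase=False, norm="l2"
        )

    def fit(self, X: Sequence[Sequence[str]], y=None) -> "TfidfDocumentEmbedder":
        self._vec.fit(list(X))
        return self

    def transform(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        return self._vec.transform(list(X)).toarray()

    def fit_transform(self, X: Sequence[Sequence[str]], y=None) -> np.ndarray:
        return self._vec.fit_transform(list(X)).toarray()


class HDBSCAN(BaseEstimator, ClusterMixin):
    """Hierarchical density-based clustering with a noise label.

    In-package implementation (see :mod:`pasctopics._hdbscan`): mutual
    reachability distances, MST single linkage, condensed tree, and
    excess-of-mass cluster selection.  Unlike the sklearn estimator of the
    same name, clusters are numbered 1..C by decreasing size — the topic
    numbering used throughout this package — and noise is -1.

    Attributes
    ----------
    labels_ : ndarray (n_samples,)
    probabilities_ : ndarray (n_samples,)
        Membership strengths in [0, 1]; 0 for noise.
    """

    def __init__(
        self,
        min_cluster_size: int = 10,
        min_samples: int | None = None,
        metric: str = "euclidean",
    ):
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.metric = metric

    def fit(self, X, y=None) -> "HDBSCAN":
        labels, probs = _hdbscan.hdbscan_flat(
            np.asarray(X, dtype=np.float64),
            min_cluster_size=self.min_cluster_size,
            min_samples=self.min_samples,
            metric=self.metric,
        )
        self.labels_ = labels
        self.probabilities_ = probs
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


# ---------------------------------------------------------------- adapters

EmbedderFn = Callable[[Sequence[Sequence[str]], int], np.ndarray]
ReducerFn = Callable[[np.ndarray, int, int], np.ndarray]

_EMBEDDERS: dict[str, EmbedderFn] = {}
_REDUCERS: dict[str, ReducerFn] = {}


def register_embedder(name: str, fn: EmbedderFn) -> None:
    """Register an external embedding adapter (e.g. a sentence transformer)."""
    _EMBEDDERS[name] = fn


def register_reducer(name: str, fn: ReducerFn) -> None:
    """Register an external reduction adapter (e.g. UMAP)."""
    _REDUCERS[name] = fn


def _tfidf_embed(token_lists: Sequence[Sequence[str]], seed: int) -> np.ndarray:
    return TfidfDocumentEmbedder().fit_transform(token_lists)


register_embedder("tfidf", _tfidf_embed)


def embed_documents(
    streams: Sequence[TokenStream],
    embedder: str = "tfidf",
    seed: int = 0,
) -> EmbeddingMatrix:
    """Embed token streams with a registered embedder (default: TF-IDF)."""
    if not streams:
        raise ValueError("no documents to embed")
    if embedder not in _EMBEDDERS:
        raise KeyError(
            f"unknown embedder {embedder!r}; registered: {sorted(_EMBEDDERS)}"
        )
    token_lists = [list(s.tokens) for s in streams]
    matrix = _EMBEDDERS[embedder](token_lists, seed)
    return EmbeddingMatrix(matrix=matrix, embedder_id=embedder)


def reduce_dimensions(
    emb: EmbeddingMatrix,
    n_components: int = 5,
    method: str = "pca",
    seed: int = 0,
) -> EmbeddingMatrix:
    """Reduce embedding dimension.

    ``pca`` projects onto the leading principal directions (full SVD; the
    sign convention fixes each component's largest-magnitude loading
    positive, so results are deterministic).  ``none`` is the identity.
    Other names resolve through the reducer registry.
    """
    if method == "none":
        return emb
    if n_components > emb.d:
        raise ValueError(
            f"n_components={n_components} exceeds embedding dimension {emb.d}"
        )
    if method == "pca":
        k = min(n_components, emb.n_docs)
        reduced = PCA(n_components=k, svd_solver="full", random_state=seed).fit_transform(
            emb.matrix
        )
    elif method in _REDUCERS:
        reduced = _REDUCERS[method](emb.matrix, n_components, seed)
    else:
        raise KeyError(f"unknown reducer {method!r}; registered: {sorted(_REDUCERS)}")
    return EmbeddingMatrix(matrix=reduced, embedder_id=f"{emb.embedder_id}+{method}")


def hdbscan_cluster(
    emb: EmbeddingMatrix,
    min_cluster_size: int = 10,
    min_samples: int | None = None,
    metric: str = "euclidean",
) -> ClusteringResult:
    """Cluster the embedded documents; unassigned documents get label -1."""
    est = HDBSCAN(
        min_cluster_size=min_cluster_size, min_samples=min_samples, metric=metric
    ).fit(emb.matrix)
    n_clusters = len(set(est.labels_.tolist()) - {-1})
    logger.info(
        "hdbscan: %d clusters, %d noise documents of %d",
        n_clusters,
        int((est.labels_ == -1).sum()),
        emb.n_docs,
    )
    return ClusteringResult(labels=est.labels_, strengths=est.probabilities_)


def class_tfidf_keywords(
    streams_by_cluster: Mapping[int, Iterable[str]],
    top_n: int = 10,
) -> ClassTfidfTable:
    """Class-based TF-IDF keywords per cluster.

    Each cluster's documents are concatenated into one pseudo-document;
    a term's weight in cluster c is

        W(t, c) = tf(t, c) * log(1 + A / tf(t))

    with tf(t) the term's count across all clusters and A the mean token
    count per cluster.  The noise cluster (-1) is excluded from the
    computation entirely; zero-weight terms are dropped and ties are broken
    lexicographically.
    """
    cluster_counts: dict[int, Counter[str]] = {}
    for cluster, tokens in streams_by_cluster.items():
        if cluster == -1:
            continue
        counts = Counter(tokens)
        if not counts:
            raise ValueError(f"cluster {cluster} has no tokens")
        cluster_counts[cluster] = counts
    if not cluster_counts:
        raise ValueError("no non-noise clusters to extract keywords from")

    total_tf: Counter[str] = Counter()
    for counts in cluster_counts.values():
        total_tf.update(counts)
    A = sum(sum(c.values()) for c in cluster_counts.values()) / len(cluster_counts)

    keywords: dict[int, list[tuple[str, float]]] = {}
    for cluster, counts in cluster_counts.items():
        weighted = [
            (term, tf_tc * math.log(1.0 + A / total_tf[term]))
            for term, tf_tc in counts.items()
        ]
        weighted = [(t, w) for t, w in weighted if w > 0]
        weighted.sort(key=lambda tw: (-tw[1], tw[0]))
        keywords[cluster] = weighted[:top_n]
    return ClassTfidfTable(keywords=keywords, mean_cluster_tokens=A)


def assign_topics(clustering: ClusteringResult) -> np.ndarray:
    """Per-document topic ids: the hard cluster label (noise stays -1)."""
    return clustering.labels.copy()
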