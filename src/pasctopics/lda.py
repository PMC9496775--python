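"""Latent Dirichlet Allocation by collapsed Gibbs sampling.

Each document is a Dirichlet mixture theta over k latent topics and each
topic a distribution phi over the vocabulary; tokens are drawn by sampling
a topic z from theta and a word from phi_z.  Inference integrates theta and
phi out analytically and samples only the token-level assignments z from
their collapsed conditionals; point estimates are recovered from the final
count state with Dirichlet smoothing:

    phi[t, w]  = (n_tw + eta)   / (n_t + V * eta)
    theta[d, t] = (n_dt + alpha) / (N_d + k * alpha)

The module also provides the two intrinsic model-quality scores used to
choose k — per-word log2 likelihood ("log perplexity", more negative =
worse) and UMass topic coherence — and the sweep over k in {3, 5, 7, 10}.

:class:`GibbsLDA` is the sklearn-style estimator; :func:`fit_lda` and
friends are thin wrappers speaking the package's bag-of-words types.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._gibbs import gibbs_sweep
from .preprocess import BagOfWords, Vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "GibbsLDA",
    "LdaModel",
    "ModelSelectionRecord",
    "TopicKeywords",
    "bows_to_matrix",
    "fit_lda",
    "dominant_topic",
    "log_perplexity",
    "umass_coherence",
    "topic_keywords",
    "choose_k_from_records",
    "select_k",
    "assignment_trace",
    "save_model",
]


def bows_to_matrix(bows: list[BagOfWords], n_words: int) -> sp.csr_matrix:
    """Stack sparse bag-of-words documents into a CSR document-term matrix."""
    rows, cols, data = [], [], []
    for d, bow in enumerate(bows):
        for w, c in bow.entries:
            rows.append(d)
            cols.append(w)
            data.append(c)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(bows), n_words), dtype=np.int64
    )


def _expand_tokens(X: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Token-level (word index, doc index) arrays in corpus order.

    Tokens are laid out document by document, word indices ascending within
    a document, repeats adjacent — a fixed order so that chains are
    reproducible from the seed alone.
    """
    words, docs = [], []
    indptr, indices, data = X.indptr, X.indices, X.data
    for d in range(X.shape[0]):
        for j in range(indptr[d], indptr[d + 1]):
            words.extend([indices[j]] * int(data[j]))
            docs.extend([d] * int(data[j]))
    return (
        np.asarray(words, dtype=np.int32),
        np.asarray(docs, dtype=np.int32),
    )


class GibbsLDA(BaseEstimator, TransformerMixin):
    """LDA topic model fitted by collapsed Gibbs sampling.

    Parameters
    ----------
    n_topics : int
        Number of latent topics k.
    alpha : float or None
        Symmetric document-topic Dirichlet concentration; ``None`` means the
        common 1/k default.
    eta : float
        Symmetric topic-word smoothing.
    n_iterations : int
        Full Gibbs sweeps over all tokens; estimates come from the final
        state (no separate burn-in).
    random_state : int or None
        Seed; identical seed and input give a bit-identical chain.

    Attributes
    ----------
    components_ : ndarray of shape (n_topics, n_words)
        Smoothed per-topic word distributions (phi); rows sum to 1.
    doc_topic_ : ndarray of shape (n_docs, n_topics)
        Smoothed per-document topic mixtures (theta); rows sum to 1.
    z_ : ndarray of shape (n_tokens,)
        Final token-topic assignments in corpus order.
    """

    def __init__(
        self,
        n_topics: int = 3,
        alpha: float | None = None,
        eta: float = 0.01,
        n_iterations: int = 1000,
        random_state: int | None = None,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.eta = eta
        self.n_iterations = n_iterations
        self.random_state = random_state

    def _run_chain(
        self, X: sp.csr_matrix, collect_from: int | None = None
    ) -> list[np.ndarray] | None:
        """Run the Gibbs chain; optionally collect z after each sweep >= collect_from."""
        k = int(self.n_topics)
        if k < 1:
            raise ValueError("n_topics must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        alpha = 1.0 / k if self.alpha is None else float(self.alpha)
        eta = float(self.eta)
        X = sp.csr_matrix(X, dtype=np.int64)
        n_docs, n_words = X.shape
        doc_lengths = np.asarray(X.sum(axis=1)).ravel()
        if np.any(doc_lengths == 0):
            empty = np.flatnonzero(doc_lengths == 0)
            raise ValueError(f"empty documents at positions {empty.tolist()}")
        total_tokens = int(doc_lengths.sum())
        if k > total_tokens:
            warnings.warn(
                f"n_topics={k} exceeds the corpus token count {total_tokens}; "
                "most topics will stay empty",
                UserWarning,
                stacklevel=3,
            )

        words, docs = _expand_tokens(X)
        rng = np.random.default_rng(self.random_state)
        z = rng.integers(0, k, size=total_tokens).astype(np.int32)

        n_dt = np.zeros((n_docs, k), dtype=np.int64)
        n_tw = np.zeros((k, n_words), dtype=np.int64)
        np.add.at(n_dt, (docs, z), 1)
        np.add.at(n_tw, (z, words), 1)
        n_t = n_tw.sum(axis=1)
        cum = np.zeros(k, dtype=np.float64)

        trace: list[np.ndarray] | None = [] if collect_from is not None else None
        for sweep in range(self.n_iterations):
            uniforms = rng.random(total_tokens)
            gibbs_sweep(words, docs, z, n_dt, n_tw, n_t, alpha, eta, uniforms, cum)
            if trace is not None and sweep >= collect_from:
                trace.append(z.copy())

        self.alpha_ = alpha
        self.eta_ = eta
        self.n_words_ = n_words
        self.z_ = z
        self.token_doc_ = docs
        self.token_word_ = words
        self.components_ = (n_tw + eta) / (n_t + n_words * eta)[:, None]
        self.doc_topic_ = (n_dt + alpha) / (doc_lengths + k * alpha)[:, None]
        self._X_fingerprint = (X.shape, X.indptr.tobytes(), X.indices.tobytes(), X.data.tobytes())
        return trace

    def fit(self, X, y=None) -> "GibbsLDA":
        """Fit on a (n_docs, n_words) count matrix (sparse or dense)."""
        self._run_chain(X)
        return self

    def transform(self, X) -> np.ndarray:
        """Topic mixtures of the *training* corpus.

        Held-out inference is deliberately unsupported: the evaluation
        pipeline uses training-corpus mixtures only, so ``X`` must be the
        matrix the model was fitted on.
        """
        check_is_fitted(self, "doc_topic_")
        Xc = sp.csr_matrix(X, dtype=np.int64)
        fp = (Xc.shape, Xc.indptr.tobytes(), Xc.indices.tobytes(), Xc.data.tobytes())
        if fp != self._X_fingerprint:
            raise NotImplementedError(
                "GibbsLDA.transform supports only the training corpus; "
                "held-out inference is not implemented"
            )
        return self.doc_topic_


@dataclass
class LdaModel:
    """Fitted LDA state: hyperparameters, phi, theta and assignments."""

    k: int
    alpha: float
    eta: float
    phi: np.ndarray     # (k, V) rows sum to 1
    theta: np.ndarray   # (D, k) rows sum to 1
    z: np.ndarray       # (T,) token-level assignments
    seed: int | None
    n_iterations: int


@dataclass(frozen=True)
class ModelSelectionRecord:
    """One row of the k-selection sweep."""

    k: int
    coherence_score: float
    log_perplexity: float


#: topic id -> ordered (term, weight) list
TopicKeywords = dict[int, list[tuple[str, float]]]


def fit_lda(
    bows: list[BagOfWords],
    vocab: Vocabulary,
    k: int,
    alpha: float | None = None,
    eta: float = 0.01,
    n_iterations: int = 1000,
    seed: int | None = None,
) -> LdaModel:
    """Fit LDA on bag-of-words documents (wraps :class:`GibbsLDA`)."""
    for bow in bows:
        if bow.n_tokens == 0:
            raise ValueError(f"document {bow.doc_id!r} is empty after preprocessing")
    X = bows_to_matrix(bows, vocab.size)
    est = GibbsLDA(
        n_topics=k,
        alpha=alpha,
        eta=eta,
        n_iterations=n_iterations,
        random_state=seed,
    ).fit(X)
    return LdaModel(
        k=k,
        alpha=est.alpha_,
        eta=est.eta_,
        phi=est.components_,
        theta=est.doc_topic_,
        z=est.z_,
        seed=seed,
        n_iterations=n_iterations,
    )


def assignment_trace(
    bows: list[BagOfWords],
    vocab: Vocabulary,
    k: int,
    alpha: float | None = None,
    eta: float = 0.01,
    n_sweeps: int = 2000,
    burn_in: int = 200,
    seed: int | None = None,
) -> np.ndarray:
    """Post-burn-in token-assignment samples, one row per Gibbs sweep.

    Exposes the sampler's stationary distribution for posterior checks on
    small corpora (the chain visits assignment states with frequency
    proportional to the collapsed posterior).
    """
    X = bows_to_matrix(bows, vocab.size)
    est = GibbsLDA(
        n_topics=k,
        alpha=alpha,
        eta=eta,
        n_iterations=n_sweeps,
        random_state=seed,
    )
    trace = est._run_chain(X, collect_from=burn_in)
    return np.asarray(trace, dtype=np.int32)


def dominant_topic(theta_d: np.ndarray) -> int:
    """Index of the highest-probability topic; ties -> lowest index."""
    return int(np.argmax(theta_d))


def log_perplexity(model: LdaModel, bows: list[BagOfWords]) -> float:
    """Per-word log2 likelihood of the corpus under the fitted mixture.

    (1 / total tokens) * sum_d sum_w count * log2(sum_t theta[d,t] phi[t,w]);
    more negative = worse fit.
    """
    total = 0.0
    n_tokens = 0
    for d, bow in enumerate(bows):
        for w, c in bow.entries:
            if w >= model.phi.shape[1]:
                raise ValueError(
                    f"word index {w} outside vocabulary of size {model.phi.shape[1]}"
                )
            p = float(model.theta[d] @ model.phi[:, w])
            total += c * np.log2(p)
            n_tokens += c
    return total / n_tokens


def _doc_sets(bows: list[BagOfWords], n_words: int) -> list[set[int]]:
    return [{w for w, _ in bow.entries} for bow in bows]


def umass_coherence(
    model: LdaModel, bows: list[BagOfWords], top_n: int = 10
) -> float:
    """Mean UMass coherence over topics.

    Per topic, with top words w_1..w_n ordered by phi descending, the score
    is (2 / (n (n-1))) * sum_{i<j} log((D(w_i, w_j) + 1) / D(w_i)) where D
    counts document (co-)occurrences in ``bows`` and the conditioning word
    of each pair is the higher-ranked one.  Words absent from the corpus
    (possible only through smoothing) are skipped.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    V = model.phi.shape[1]
    doc_sets = _doc_sets(bows, V)
    doc_count = np.zeros(V, dtype=np.int64)
    for s in doc_sets:
        for w in s:
            doc_count[w] += 1

    scores = []
    for t in range(model.k):
        order = np.argsort(-model.phi[t], kind="stable")
        top = [int(w) for w in order if doc_count[w] > 0][:top_n]
        n = len(top)
        if n < 2:
            scores.append(0.0)
            continue
        acc = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                co = sum(1 for s in doc_sets if top[i] in s and top[j] in s)
                acc += np.log((co + 1) / doc_count[top[i]])
        scores.append(2.0 / (n * (n - 1)) * acc)
    return float(np.mean(scores))


def topic_keywords(
    model: LdaModel, vocab: Vocabulary, top_n: int = 10
) -> TopicKeywords:
    """Top-``top_n`` terms per topic by phi weight; ties lexicographic."""
    out: TopicKeywords = {}
    for t in range(model.k):
        pairs = sorted(
            ((vocab.token(w), float(model.phi[t, w])) for w in range(vocab.size)),
            key=lambda tw: (-tw[1], tw[0]),
        )
        out[t] = pairs[:top_n]
    return out


def choose_k_from_records(
    records: list[ModelSelectionRecord], coherence_tie_band: float = 0.01
) -> int:
    """The trade-off rule: best coherence, perplexity breaking near-ties.

    Among records whose coherence is within ``coherence_tie_band`` of the
    maximum, prefer the log-perplexity closest to 0, then the smaller k.
    """
    best_coh = max(r.coherence_score for r in records)
    candidates = [
        r for r in records if r.coherence_score >= best_coh - coherence_tie_band
    ]
    return min(candidates, key=lambda r: (-r.log_perplexity, r.k)).k


def select_k(
    bows: list[BagOfWords],
    vocab: Vocabulary,
    k_grid: list[int] = (3, 5, 7, 10),
    alpha: float | None = None,
    eta: float = 0.01,
    n_iterations: int = 1000,
    seed: int | None = None,
    coherence_tie_band: float = 0.01,
) -> tuple[list[ModelSelectionRecord], int]:
    """Sweep k over a grid and pick the best trade-off.

    Rule: maximize coherence; among candidates whose coherence is within
    ``coherence_tie_band`` of the best, prefer the log-perplexity closest
    to 0, then the smaller k.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    records = []
    for k in k_grid:
        model = fit_lda(
            bows, vocab, k, alpha=alpha, eta=eta, n_iterations=n_iterations, seed=seed
        )
        records.append(
            ModelSelectionRecord(
                k=k,
                coherence_score=umass_coherence(model, bows),
                log_perplexity=log_perplexity(model, bows),
            )
        )
    chosen = choose_k_from_records(records, coherence_tie_band)
    logger.info(
        "k sweep %s -> chosen k=%d",
        [(r.k, round(r.coherence_score, 4), round(r.log_perplexity, 4)) for r in records],
        chosen,
    )
    return records, chosen


def save_model(model: LdaModel, vocab: Vocabulary, path_prefix: str) -> dict[str, str]:
    """Serialize a fitted model: npz archive + human-readable keywords TSV."""
    import hashlib

    vocab_hash = hashlib.sha256("\x00".join(vocab.tokens).encode()).hexdigest()
    npz_path = f"{path_prefix}.npz"
    np.savez_compressed(
        npz_path,
        phi=model.phi,
        theta=model.theta,
        z=model.z,
        config=np.frombuffer(
            json.dumps(
                {
                    "k": model.k,
                    "alpha": model.alpha,
                    "eta": model.eta,
                    "seed": model.seed,
                    "n_iterations": model.n_iterations,
                    "vocab_sha256": vocab_hash,
                }
            ).encode(),
            dtype=np.uint8,
        ),
    )
    tsv_path = f"{path_prefix}_keywords.tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("topic\trank\tterm\tweight\n")
        for t, pairs in topic_keywords(model, vocab).items():
            for rank, (term, weight) in enumerate(pairs, start=1):
                fh.write(f"{t}\t{rank}\t{term}\t{weight:.6g}\n")
    return {"model": npz_path, "keywords": tsv_path}
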