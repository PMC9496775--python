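"""Synthetic two-class narrative corpora from the LDA generative process.

The generator runs the topic model forward: it draws per-topic word
distributions phi from block-boosted Dirichlets over a themed vocabulary,
then for every document draws a topic mixture theta from its class's
Dirichlet prior, a length from a shifted Poisson, and tokens by sampling a
topic and then a word.  The emulated corpus mirrors the PASC / non-PASC
narrative-medicine collection: 73 PASC documents averaging ~205 words
against 114 non-PASC documents averaging ~345 words, with PASC mixtures
concentrated on a symptom topic (fever, fatigue, tampon, smell, ...) and
non-PASC mixtures on a clinical-staff topic (patient, colleagues,
intensive_care, ...).  Full ground truth (phi, theta, z, labels) is
returned for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Corpus, Document, Label

__all__ = [
    "SYMPTOM_BLOCK",
    "CLINICAL_BLOCK",
    "GENERIC_BLOCK",
    "SyntheticConfig",
    "GroundTruth",
    "default_pasc_config",
    "generate_corpus",
    "parameter_recovery_score",
]

#: Symptom-themed vocabulary; the first eight entries are the symptom words
#: shared by the PASC-dominated topics of both topic-model tracks.
SYMPTOM_BLOCK: tuple[str, ...] = (
    "fever",
    "fatigue",
    "tiredness",
    "covid",
    "tampon",
    "smell",
    "symptom",
    "pain",
    "breath",
    "headache",
)

#: Clinical-staff-themed vocabulary characterizing non-PASC narratives.
CLINICAL_BLOCK: tuple[str, ...] = (
    "patient",
    "colleagues",
    "intensive_care",
    "doctor",
    "nurse",
    "hospital",
    "ward",
    "therapy",
    "shift",
    "emergency",
)

#: Topic-neutral filler head words shared by both classes.
GENERIC_BLOCK: tuple[str, ...] = (
    "day",
    "time",
    "home",
    "family",
    "life",
    "fear",
    "hope",
    "work",
    "world",
    "people",
    "thing",
    "moment",
    "heart",
    "story",
    "night",
    "week",
    "hand",
    "eye",
    "word",
    "silence",
)


def _tail(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i:03d}" for i in range(n))


#: Default topic vocabularies: named head words followed by synthetic tail
#: lemmas.  Word probabilities within a block decay Zipf-style, so each
#: topic has a few frequent characteristic words and a long tail of rare
#: ones — the frequency profile of real lemmatized narratives, and the
#: regime in which document co-occurrence statistics are informative.
DEFAULT_BLOCKS: tuple[tuple[str, ...], ...] = (
    SYMPTOM_BLOCK + _tail("sym", 40),
    CLINICAL_BLOCK + _tail("cli", 40),
    GENERIC_BLOCK + _tail("gen", 100),
)


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic corpus.

    Defaults emulate the real collection: class sizes 73/114, mean lengths
    205/345 words (shifted Poisson with a 21-word floor, the length of the
    real corpus's shortest document), three true topics (symptom, clinical,
    generic) over a block-partitioned vocabulary, and class topic priors
    concentrating PASC mass on the symptom topic and non-PASC mass on the
    clinical topic.  ``separation`` scales the Dirichlet boost a topic
    gives its own vocabulary block; higher values make topics closer to
    block-disjoint.
    """

    n_pasc: int = 73
    n_non_pasc: int = 114
    mean_length_pasc: float = 205.0
    mean_length_non_pasc: float = 345.0
    min_length: int = 21
    k_true: int = 3
    vocabulary_blocks: tuple[tuple[str, ...], ...] = DEFAULT_BLOCKS
    topic_word_concentration: float = 0.05
    block_boost: float = 1.0
    separation: float = 5.0
    zipf_exponent: float = 1.0
    class_topic_prior: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "PASC": (4.0, 0.5, 0.5),
            "non-PASC": (0.5, 4.0, 1.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [w for block in self.vocabulary_blocks for w in block]
        if len(set(flat)) != len(flat):
            raise ValueError("vocabulary blocks must be disjoint")
        for cls, prior in self.class_topic_prior.items():
            if len(prior) != self.k_true:
                raise ValueError(f"prior for {cls} has length {len(prior)} != k_true")
            if any(a <= 0 for a in prior):
                raise ValueError(f"prior for {cls} must be strictly positive")
        if min(self.mean_length_pasc, self.mean_length_non_pasc) < self.min_length:
            raise ValueError("mean lengths must be >= min_length")

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return tuple(w for block in self.vocabulary_blocks for w in block)


@dataclass
class GroundTruth:
    """Everything the generator knows that inference must recover."""

    phi: np.ndarray            # (k_true, V)
    theta: np.ndarray          # (D, k_true)
    z: list[np.ndarray]        # per-document token-topic assignments
    labels: list[Label]
    vocabulary: tuple[str, ...]


def default_pasc_config(seed: int = 0) -> SyntheticConfig:
    """The documented default study conditions with the given seed."""
    return SyntheticConfig(seed=seed)


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Run the generative topic model forward into a labeled corpus.

    Per topic t: phi_t ~ Dir(concentration + separation * block_boost on
    block t).  Per document: theta ~ Dir(class prior), length ~ min_length
    + Poisson(mean - min_length), and each token z ~ Mult(theta),
    w ~ Mult(phi_z).  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    vocab = config.vocabulary
    V = len(vocab)
    k = config.k_true

    # block-boosted topic-word Dirichlets with Zipf-decaying weight within
    # the block (normalized to mean 1 so `separation` keeps its scale);
    # topics beyond the number of blocks stay at the unboosted base
    phi = np.empty((k, V))
    offsets = np.cumsum([0] + [len(b) for b in config.vocabulary_blocks])
    for t in range(k):
        conc = np.full(V, config.topic_word_concentration)
        if t < len(config.vocabulary_blocks):
            size = offsets[t + 1] - offsets[t]
            zipf = 1.0 / np.arange(1, size + 1) ** config.zipf_exponent
            zipf *= size / zipf.sum()
            conc[offsets[t] : offsets[t + 1]] += (
                config.block_boost * config.separation * zipf
            )
        phi[t] = rng.dirichlet(conc)

    plan = [(Label.PASC, config.n_pasc, config.mean_length_pasc)] + [
        (Label.NON_PASC, config.n_non_pasc, config.mean_length_non_pasc)
    ]
    documents: list[Document] = []
    thetas: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    labels: list[Label] = []
    for label, n_docs, mean_len in plan:
        prior = np.asarray(config.class_topic_prior[label.value])
        for i in range(n_docs):
            theta = rng.dirichlet(prior)
            length = config.min_length + rng.poisson(mean_len - config.min_length)
            z = rng.choice(k, size=length, p=theta)
            w_idx = np.empty(length, dtype=np.int64)
            for t in np.unique(z):
                mask = z == t
                w_idx[mask] = rng.choice(V, size=int(mask.sum()), p=phi[t])
            words = [vocab[w] for w in w_idx]
            documents.append(
                Document(
                    doc_id=f"{'pasc' if label is Label.PASC else 'nonpasc'}{i:04d}",
                    raw_text=" ".join(words),
                    label=label,
                    source="synthetic",
                )
            )
            thetas.append(theta)
            zs.append(np.asarray(z, dtype=np.int32))
            labels.append(label)

    truth = GroundTruth(
        phi=phi,
        theta=np.vstack(thetas),
        z=zs,
        labels=labels,
        vocabulary=vocab,
    )
    return Corpus(documents), truth


def parameter_recovery_score(true_phi: np.ndarray, est_phi: np.ndarray) -> float:
    """Mean cosine similarity after greedy one-to-one topic matching.

    Estimated topics are matched to true topics greedily by descending
    cosine similarity (absorbing label switching); the score is the mean
    similarity of the matched pairs, in [0, 1] for non-negative rows.
    """
    true_phi = np.asarray(true_phi, dtype=np.float64)
    est_phi = np.asarray(est_phi, dtype=np.float64)
    if true_phi.shape != est_phi.shape:
        raise ValueError(f"shape mismatch: {true_phi.shape} vs {est_phi.shape}")
    tn = true_phi / np.linalg.norm(true_phi, axis=1, keepdims=True)
    en = est_phi / np.linalg.norm(est_phi, axis=1, keepdims=True)
    sim = tn @ en.T
    k = sim.shape[0]
    free_true = set(range(k))
    free_est = set(range(k))
    matched = []
    for _ in range(k):
        best = max(
            ((i, j) for i in free_true for j in free_est),
            key=lambda ij: sim[ij],
        )
        matched.append(float(sim[best]))
        free_true.discard(best[0])
        free_est.discard(best[1])
    return float(np.mean(matched))
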