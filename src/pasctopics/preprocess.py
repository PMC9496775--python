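"""Text cleaning, tokenization and bag-of-words construction.

The cleaning pipeline is deliberately small and deterministic: lowercase,
strip URLs, replace punctuation and special characters with spaces, collapse
separators, and optionally drop digits-only tokens.  Lemmatization is a
pluggable token->lemma mapping (default: identity) so that corpora built
from pre-lemmatized vocabularies pass through unchanged, while a real
morphological analyzer can be adapted in for raw Italian text.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "CleaningConfig",
    "TokenStream",
    "Vocabulary",
    "BagOfWords",
    "clean_text",
    "tokenize",
    "remove_stopwords",
    "lemmatize",
    "build_vocabulary",
    "to_bag_of_words",
    "term_frequency_table",
    "load_stopwords",
    "preprocess_corpus",
]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_DIGITS_ONLY_RE = re.compile(r"^\d+$")


@dataclass(frozen=True)
class CleaningConfig:
    """Flags controlling :func:`clean_text`.

    keep_hyphens
        Keep ``-`` inside tokens instead of treating it as a separator.
    remove_digits
        Drop tokens consisting only of digits.
    url_removal
        Strip ``http(s)://...`` and ``www...`` spans before anything else.
    """

    keep_hyphens: bool = False
    remove_digits: bool = True
    url_removal: bool = True


@dataclass(frozen=True)
class TokenStream:
    """Ordered lowercase tokens of one document."""

    doc_id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


def clean_text(raw: str, config: CleaningConfig = CleaningConfig()) -> str:
    """Normalize raw text to a lowercase, space-separated string.

    Order: lowercase -> URL removal -> punctuation/special-character
    replacement with space -> separator collapse -> digits-only token
    removal.  Idempotent: applying it twice equals applying it once.
    """
    text = raw.lower()
    if config.url_removal:
        text = _URL_RE.sub(" ", text)
    # word characters (unicode letters, digits, underscore) survive;
    # underscore is kept so compound tokens like "intensive_care" stay whole
    if config.keep_hyphens:
        text = re.sub(r"[^\w\-]", " ", text)
        text = re.sub(r"(?<!\w)-|-(?!\w)", " ", text)  # bare hyphens are separators
    else:
        text = re.sub(r"[^\w]", " ", text)
    tokens = text.split()
    if config.remove_digits:
        tokens = [t for t in tokens if not _DIGITS_ONLY_RE.match(t)]
    return " ".join(tokens)


def tokenize(cleaned: str, doc_id: str = "") -> TokenStream:
    """Split an already-cleaned string on whitespace, discarding empties."""
    return TokenStream(doc_id=doc_id, tokens=tuple(cleaned.split()))


def remove_stopwords(stream: TokenStream, stopwords: frozenset[str] | set[str]) -> TokenStream:
    """Drop stopword tokens, preserving the order of survivors."""
    return TokenStream(
        doc_id=stream.doc_id,
        tokens=tuple(t for t in stream.tokens if t not in stopwords),
    )


def lemmatize(
    stream: TokenStream,
    lemmatizer: Mapping[str, str] | Callable[[str], str] | None = None,
) -> TokenStream:
    """Map each token to its lemma; unknown tokens pass through unchanged.

    ``lemmatizer`` may be a dict-like mapping or a callable; ``None`` is the
    identity.  Output is always lowercase and length-preserving.
    """
    if lemmatizer is None:
        return stream
    if callable(lemmatizer) and not isinstance(lemmatizer, Mapping):
        out = tuple(lemmatizer(t).lower() for t in stream.tokens)
    else:
        out = tuple(lemmatizer.get(t, t).lower() for t in stream.tokens)
    return TokenStream(doc_id=stream.doc_id, tokens=out)


@dataclass(frozen=True)
class Vocabulary:
    """Token <-> index bijection with per-token document frequencies.

    Indices are contiguous ``0..V-1``, assigned in first-occurrence order
    over the streams the vocabulary was built from.
    """

    index: dict[str, int]
    doc_freq: dict[str, int]
    n_docs: int
    _tokens: tuple[str, ...] = field(repr=False, default=())

    @property
    def size(self) -> int:
        return len(self.index)

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def token(self, idx: int) -> str:
        return self._tokens[idx]

    @property
    def tokens(self) -> tuple[str, ...]:
        return self._tokens


@dataclass(frozen=True)
class BagOfWords:
    """Sparse (token index, occurrence count) document representation."""

    doc_id: str
    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.entries]
        assert idx == sorted(set(idx)), "entries must be sorted by unique index"
        assert all(c >= 1 for _, c in self.entries)

    @property
    def n_tokens(self) -> int:
        return sum(c for _, c in self.entries)


def build_vocabulary(
    streams: Sequence[TokenStream],
    min_df: int = 1,
    max_df_fraction: float = 1.0,
) -> Vocabulary:
    """Build a token dictionary from token streams.

    Tokens with document frequency below ``min_df`` or above
    ``max_df_fraction * n_docs`` are excluded.  Raises ``ValueError`` if
    nothing survives.
    """
    n_docs = len(streams)
    df: Counter[str] = Counter()
    first_seen: dict[str, None] = {}
    for stream in streams:
        seen = set()
        for t in stream.tokens:
            if t not in first_seen:
                first_seen[t] = None
            seen.add(t)
        df.update(seen)
    max_df = max_df_fraction * n_docs
    kept = [t for t in first_seen if min_df <= df[t] <= max_df]
    if not kept:
        raise ValueError(
            f"vocabulary is empty after filtering (min_df={min_df}, "
            f"max_df_fraction={max_df_fraction})"
        )
    index = {t: i for i, t in enumerate(kept)}
    return Vocabulary(
        index=index,
        doc_freq={t: df[t] for t in kept},
        n_docs=n_docs,
        _tokens=tuple(kept),
    )


def to_bag_of_words(stream: TokenStream, vocab: Vocabulary) -> BagOfWords:
    """Count in-vocabulary tokens; out-of-vocabulary tokens are dropped."""
    counts: Counter[int] = Counter(
        vocab.index[t] for t in stream.tokens if t in vocab.index
    )
    return BagOfWords(
        doc_id=stream.doc_id,
        entries=tuple(sorted(counts.items())),
    )


def term_frequency_table(
    streams: Iterable[TokenStream], top_n: int
) -> list[tuple[str, int]]:
    """Corpus-wide term counts, descending; ties broken lexicographically.

    This is the table a word cloud is drawn from.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts: Counter[str] = Counter()
    for stream in streams:
        counts.update(stream.tokens)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:top_n]


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword file: UTF-8, one token per line, ``#`` comments."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.add(line.lower())
    return frozenset(words)


def preprocess_corpus(
    texts: Sequence[str],
    doc_ids: Sequence[str] | None = None,
    config: CleaningConfig = CleaningConfig(),
    stopwords: frozenset[str] | set[str] = frozenset(),
    lemmatizer: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[TokenStream]:
    """Clean -> tokenize -> stopword-filter -> lemmatize every document."""
    if doc_ids is None:
        doc_ids = [f"doc{i:05d}" for i in range(len(texts))]
    streams = []
    for doc_id, text in zip(doc_ids, texts):
        stream = tokenize(clean_text(text, config), doc_id=doc_id)
        stream = remove_stopwords(stream, stopwords)
        streams.append(lemmatize(stream, lemmatizer))
    return streams
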