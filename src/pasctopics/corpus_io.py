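"""Labeled-corpus I/O and descriptive statistics.

A corpus is an ordered collection of free-text illness narratives, each
tagged with a class label (PASC — post-acute sequelae of COVID-19 — or
non-PASC).  Corpora are exchanged as UTF-8 CSV files with a header row;
``doc_id`` and ``source`` columns are optional on input and generated when
absent.  Document order is treated as opaque and preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "Document",
    "Corpus",
    "CorpusSummary",
    "LoadReport",
    "read_corpus_csv",
    "write_corpus_csv",
    "corpus_summary",
]


class Label(str, Enum):
    """Document class tag."""

    PASC = "PASC"
    NON_PASC = "non-PASC"
    UNLABELED = "unlabeled"


#: Case-insensitive mapping from raw CSV label strings to :class:`Label`.
DEFAULT_LABEL_MAP: dict[str, Label] = {
    "pasc": Label.PASC,
    "non-pasc": Label.NON_PASC,
    "non_pasc": Label.NON_PASC,
    "nonpasc": Label.NON_PASC,
    "unlabeled": Label.UNLABELED,
}


@dataclass(frozen=True)
class Document:
    """One narrative: raw text plus class label and provenance."""

    doc_id: str
    raw_text: str
    label: Label = Label.UNLABELED
    source: str = ""

    def __post_init__(self) -> None:
        if not self.raw_text.strip():
            raise ValueError(f"document {self.doc_id!r}: raw_text is empty")


@dataclass
class Corpus:
    """An ordered list of :class:`Document` with unique ids."""

    documents: list[Document]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate doc_ids in corpus: {dupes}")

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    def label_counts(self) -> dict[Label, int]:
        counts: dict[Label, int] = {}
        for d in self.documents:
            counts[d.label] = counts.get(d.label, 0) + 1
        return counts

    def texts(self) -> list[str]:
        return [d.raw_text for d in self.documents]

    def labels(self) -> list[Label]:
        return [d.label for d in self.documents]

    def __len__(self) -> int:
        return self.n_docs

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]


@dataclass(frozen=True)
class LoadReport:
    """What happened while reading a corpus file."""

    rows_read: int
    rows_dropped: int
    dropped_row_indices: tuple[int, ...]
    class_counts: dict[Label, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ClassStats:
    """Word-count summary for one group of documents."""

    n_docs: int
    min: float
    max: float
    mean: float
    iqr: float

    def __post_init__(self) -> None:
        assert self.min <= self.mean <= self.max
        assert self.iqr >= 0


@dataclass(frozen=True)
class CorpusSummary:
    """Per-class and overall words-per-document statistics."""

    overall: ClassStats
    per_class: dict[Label, ClassStats]


def _whitespace_count(text: str) -> int:
    return len(text.split())


def read_corpus_csv(
    path: str | Path,
    text_column: str = "text",
    label_column: str = "label",
    label_map: dict[str, Label] | None = None,
) -> tuple[Corpus, LoadReport]:
    """Read a labeled corpus from a CSV file.

    One :class:`Document` per row, original row order preserved.  Rows whose
    text is empty after whitespace stripping are dropped and counted in the
    returned :class:`LoadReport`.  Labels are matched case-insensitively
    against ``label_map`` (default: PASC / non-PASC / unlabeled).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    KeyError
        If a named column is missing (the message names the column).
    ValueError
        If a label value is unmappable (the message lists offending rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (text_column, label_column):
        if col not in frame.columns:
            raise KeyError(f"corpus CSV {path} is missing column {col!r}")
    mapping = {k.lower(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}

    bad_rows = [
        i
        for i, raw in enumerate(frame[label_column])
        if str(raw).strip().lower() not in mapping
    ]
    if bad_rows:
        raise ValueError(
            f"unmappable label values in rows {bad_rows[:20]} of {path}; "
            f"expected one of {sorted(mapping)} (case-insensitive)"
        )

    texts = frame[text_column].tolist()
    raw_labels = frame[label_column].tolist()
    ids = frame["doc_id"].tolist() if "doc_id" in frame.columns else None
    sources = frame["source"].tolist() if "source" in frame.columns else None
    documents: list[Document] = []
    dropped: list[int] = []
    for i, (text, raw_label) in enumerate(zip(texts, raw_labels)):
        if not str(text).strip():
            dropped.append(i)
            continue
        documents.append(
            Document(
                doc_id=str(ids[i]) if ids is not None else f"doc{i:05d}",
                raw_text=str(text),
                label=mapping[str(raw_label).strip().lower()],
                source=str(sources[i]) if sources is not None else str(path),
            )
        )
    corpus = Corpus(documents)
    report = LoadReport(
        rows_read=len(frame),
        rows_dropped=len(dropped),
        dropped_row_indices=tuple(dropped),
        class_counts=corpus.label_counts(),
    )
    logger.info(
        "read %d rows from %s: kept %d, dropped %d empty; class counts %s",
        report.rows_read,
        path,
        corpus.n_docs,
        report.rows_dropped,
        {k.value: v for k, v in report.class_counts.items()},
    )
    return corpus, report


def write_corpus_csv(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus to CSV (header ``doc_id,text,label,source``).

    Round-trips exactly through :func:`read_corpus_csv` (standard CSV
    quoting handles embedded commas, quotes and newlines).
    """
    if corpus.n_docs == 0:
        raise ValueError("refusing to write an empty corpus")
    frame = pd.DataFrame(
        {
            "doc_id": [d.doc_id for d in corpus],
            "text": [d.raw_text for d in corpus],
            "label": [d.label.value for d in corpus],
            "source": [d.source for d in corpus],
        }
    )
    frame.to_csv(path, index=False)


def _stats(counts: Sequence[int]) -> ClassStats:
    arr = np.asarray(counts, dtype=float)
    q75, q25 = np.percentile(arr, [75, 25])
    return ClassStats(
        n_docs=len(arr),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        iqr=float(q75 - q25),
    )


def corpus_summary(
    corpus: Corpus,
    tokenizer: Callable[[str], int] = _whitespace_count,
) -> CorpusSummary:
    """Words-per-document statistics, overall and per class.

    ``tokenizer`` maps a raw text to its word count; the default counts
    whitespace-separated tokens of the raw (pre-cleaning) text.  Pass a
    post-cleaning counter to summarize the processed corpus instead.
    """
    if corpus.n_docs == 0:
        raise ValueError("corpus_summary of an empty corpus")
    counts = [tokenizer(d.raw_text) for d in corpus]
    per_class: dict[Label, ClassStats] = {}
    for lab in Label:
        sub = [c for c, d in zip(counts, corpus) if d.label is lab]
        if sub:
            per_class[lab] = _stats(sub)
    return CorpusSummary(overall=_stats(counts), per_class=per_class)
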