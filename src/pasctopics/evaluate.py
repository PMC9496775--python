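"""Semi-supervised evaluation of unsupervised topics against class labels.

Topics are discovered without labels; afterwards the topic holding the most
PASC documents is declared the predicted Positive class and the topic
holding the most non-PASC documents the predicted Negative class.  Accuracy
is then (TP + TN) / N over the whole corpus — documents in other topics,
including the HDBSCAN noise topic -1, count in the denominator but are
credited to neither class.  The grouped fraction of a class is the share of
its documents landing in its single best topic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .corpus_io import Label

__all__ = [
    "ContingencyTable",
    "EvaluationReport",
    "contingency_table",
    "map_topics_to_classes",
    "semi_supervised_accuracy",
    "grouped_fraction",
    "distribution_report",
    "pct",
]


def pct(x: float) -> float:
    """A fraction as a percentage rounded half-up to 2 decimals (0.861 -> 86.10)."""
    return float(Decimal(x * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Topic x class document counts.

    ``counts[topic] = (n_pasc, n_non_pasc)``; topics ascending, so the
    noise topic -1 comes first when present.
    """

    counts: dict[int, tuple[int, int]]
    n_total: int

    @property
    def topics(self) -> list[int]:
        return sorted(self.counts)

    @property
    def non_noise_topics(self) -> list[int]:
        return [t for t in self.topics if t != -1]

    def class_total(self, label: Label) -> int:
        i = 0 if label is Label.PASC else 1
        return sum(c[i] for c in self.counts.values())


@dataclass(frozen=True)
class EvaluationReport:
    """Mapped-topic classification metrics."""

    positive_topic: int
    negative_topic: int
    true_positive: int
    true_negative: int
    n_total: int
    accuracy: float
    grouped_fraction_pasc: float
    grouped_fraction_non_pasc: float
    n_unassigned_pasc: int = 0
    n_unassigned_non_pasc: int = 0

    def __post_init__(self) -> None:
        assert abs(self.accuracy * self.n_total - (self.true_positive + self.true_negative)) < 1e-9


def _as_label(x) -> Label:
    if isinstance(x, Label):
        return x
    return Label(str(x)) if str(x) in (l.value for l in Label) else Label[str(x)]


def contingency_table(
    topic_assignments: Sequence[int], labels: Sequence[Label | str]
) -> ContingencyTable:
    """Count documents by (topic, class)."""
    if len(topic_assignments) != len(labels):
        raise ValueError(
            f"{len(topic_assignments)} assignments vs {len(labels)} labels"
        )
    if len(labels) == 0:
        raise ValueError("empty inputs")
    counts: dict[int, list[int]] = {}
    for topic, label in zip(topic_assignments, labels):
        lab = _as_label(label)
        cell = counts.setdefault(int(topic), [0, 0])
        cell[0 if lab is Label.PASC else 1] += 1
    return ContingencyTable(
        counts={t: (c[0], c[1]) for t, c in sorted(counts.items())},
        n_total=len(labels),
    )


def map_topics_to_classes(table: ContingencyTable) -> tuple[int, int]:
    """Majority mapping of topics onto (Positive, Negative) classes.

    Positive = the non-noise topic with the most PASC documents; Negative =
    the non-noise topic with the most non-PASC documents.  Ties break to
    the lower topic id.  If both rules pick the same topic, Positive keeps
    it and Negative falls to the best remaining topic.  The noise topic -1
    is never eligible.
    """
    eligible = table.non_noise_topics
    if len(eligible) < 2:
        raise ValueError(
            f"degenerate mapping: need >= 2 non-noise topics, have {eligible}"
        )
    positive = min(eligible, key=lambda t: (-table.counts[t][0], t))
    negative = min(eligible, key=lambda t: (-table.counts[t][1], t))
    if negative == positive:
        remaining = [t for t in eligible if t != positive]
        negative = min(remaining, key=lambda t: (-table.counts[t][1], t))
    return positive, negative


def grouped_fraction(table: ContingencyTable, label: Label) -> float:
    """Largest share of a class gathered by any single non-noise topic."""
    total = table.class_total(label)
    if total == 0:
        raise ValueError(f"no documents of class {label.value}")
    i = 0 if label is Label.PASC else 1
    return max(table.counts[t][i] for t in table.non_noise_topics) / total


def semi_supervised_accuracy(
    table: ContingencyTable, mapping: tuple[int, int] | None = None
) -> EvaluationReport:
    """Accuracy (TP + TN) / N under the majority topic-to-class mapping."""
    if mapping is None:
        mapping = map_topics_to_classes(table)
    positive, negative = mapping
    for t in (positive, negative):
        if t not in table.counts or t == -1:
            raise ValueError(f"mapped topic {t} not usable in table")
    tp = table.counts[positive][0]
    tn = table.counts[negative][1]
    noise = table.counts.get(-1, (0, 0))
    return EvaluationReport(
        positive_topic=positive,
        negative_topic=negative,
        true_positive=tp,
        true_negative=tn,
        n_total=table.n_total,
        accuracy=(tp + tn) / table.n_total,
        grouped_fraction_pasc=grouped_fraction(table, Label.PASC),
        grouped_fraction_non_pasc=grouped_fraction(table, Label.NON_PASC),
        n_unassigned_pasc=noise[0],
        n_unassigned_non_pasc=noise[1],
    )


def distribution_report(
    table: ContingencyTable,
    keywords: dict[int, list[tuple[str, float]]] | None = None,
) -> list[dict]:
    """Machine-readable (topic, class, count, keywords) rows for plotting.

    ``keywords`` maps topic id to its (term, weight) list (from LDA topic
    keywords or class-based TF-IDF); topics without an entry — such as the
    noise topic — get an empty list.
    """
    keywords = keywords or {}
    rows = []
    for topic in table.topics:
        n_pasc, n_non = table.counts[topic]
        for label, count in ((Label.PASC, n_pasc), (Label.NON_PASC, n_non)):
            rows.append(
                {
                    "topic": topic,
                    "class": label.value,
                    "count": count,
                    "keywords": [t for t, _ in keywords.get(topic, [])][:10],
                }
            )
    assert sum(r["count"] for r in rows) == table.n_total
    return rows
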