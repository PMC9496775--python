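"""End-to-end orchestration of the two topic-model tracks.

generate-or-load corpus -> preprocess -> LDA track and/or clustering track
-> semi-supervised evaluation -> reports.  One global seed is split into
fixed per-stage seeds, so adding or skipping a stage never perturbs the
randomness of the others, and identical config + seed gives byte-identical
metrics output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import corpus_io, embed_cluster, evaluate, lda, preprocess, synthetic_data
from .corpus_io import Corpus, Label

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compare_tracks"]

# fixed stage indices for seed splitting; append-only so that adding a
# stage never changes earlier stages' seeds
_STAGE_IDS = {"synthetic": 0, "lda": 1, "cluster": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Flat declarative pipeline configuration; CLI flags override keys."""

    input: str = "synthetic"          # "synthetic" or a corpus CSV path
    track: str = "both"               # lda | cluster | both
    seed: int = 0
    outdir: str = "runs/out"
    # preprocessing
    stopwords: str | None = None
    keep_hyphens: bool = False
    remove_digits: bool = True
    url_removal: bool = True
    # synthetic generator
    separation: float = 5.0
    # LDA track
    k: int | None = None              # fixed k; None -> sweep k_grid
    k_grid: list[int] = field(default_factory=lambda: [3, 5, 7, 10])
    alpha: float | None = None
    eta: float = 0.01
    n_iterations: int = 1000
    # clustering track
    embedder: str = "tfidf"
    reducer: str = "pca"
    n_components: int = 5
    min_cluster_size: int = 10
    min_samples: int | None = None
    metric: str = "euclidean"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def corpus_fingerprint(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for d in corpus:
        h.update(d.raw_text.encode())
        h.update(d.label.value.encode())
    return h.hexdigest()[:16]


def _report_to_metrics(report: evaluate.EvaluationReport) -> dict:
    return {
        "positive_topic": report.positive_topic,
        "negative_topic": report.negative_topic,
        "true_positive": report.true_positive,
        "true_negative": report.true_negative,
        "accuracy": round(report.accuracy, 6),
        "accuracy_pct": evaluate.pct(report.accuracy),
        "grouped_fraction_pasc_pct": evaluate.pct(report.grouped_fraction_pasc),
        "grouped_fraction_non_pasc_pct": evaluate.pct(report.grouped_fraction_non_pasc),
        "n_unassigned": report.n_unassigned_pasc + report.n_unassigned_non_pasc,
    }


def _write_contingency_tsv(table: evaluate.ContingencyTable, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("topic\tclass\tdocument_count\n")
        for topic in table.topics:
            n_pasc, n_non = table.counts[topic]
            fh.write(f"{topic}\t{Label.NON_PASC.value}\t{n_non}\n")
            fh.write(f"{topic}\t{Label.PASC.value}\t{n_pasc}\n")


def _write_keywords_tsv(keywords: dict[int, list[tuple[str, float]]], path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("topic\trank\tterm\tweight\n")
        for topic in sorted(keywords):
            for rank, (term, weight) in enumerate(keywords[topic], start=1):
                fh.write(f"{topic}\t{rank}\t{term}\t{weight:.6g}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured tracks; return a manifest of outputs and metrics."""
    if config.track not in ("lda", "cluster", "both"):
        raise ValueError(f"unknown track {config.track!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("pasctopics")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper()))
    manifest: dict[str, Any] = {"outputs": {}, "metrics": {}}
    try:
        # ------------------------------------------------ corpus
        if config.input == "synthetic":
            syn = synthetic_data.SyntheticConfig(
                separation=config.separation, seed=stage_seed(config.seed, "synthetic")
            )
            corpus, _truth = synthetic_data.generate_corpus(syn)
            corpus_path = outdir / "corpus.csv"
            corpus_io.write_corpus_csv(corpus, corpus_path)
            manifest["outputs"]["corpus"] = str(corpus_path)
        else:
            corpus, _ = corpus_io.read_corpus_csv(config.input)
        fingerprint = corpus_fingerprint(corpus)
        logger.info("corpus: %d docs, fingerprint %s", corpus.n_docs, fingerprint)

        # ------------------------------------------------ preprocess
        stopwords = (
            preprocess.load_stopwords(config.stopwords)
            if config.stopwords
            else frozenset()
        )
        cleaning = preprocess.CleaningConfig(
            keep_hyphens=config.keep_hyphens,
            remove_digits=config.remove_digits,
            url_removal=config.url_removal,
        )
        streams = preprocess.preprocess_corpus(
            corpus.texts(),
            doc_ids=[d.doc_id for d in corpus],
            config=cleaning,
            stopwords=stopwords,
        )
        labels = corpus.labels()

        # ------------------------------------------------ LDA track
        if config.track in ("lda", "both"):
            vocab = preprocess.build_vocabulary(streams)
            bows = [preprocess.to_bag_of_words(s, vocab) for s in streams]
            seed = stage_seed(config.seed, "lda")
            if config.k is None:
                records, chosen_k = lda.select_k(
                    bows,
                    vocab,
                    k_grid=config.k_grid,
                    alpha=config.alpha,
                    eta=config.eta,
                    n_iterations=config.n_iterations,
                    seed=seed,
                )
                manifest["metrics"]["lda_model_selection"] = [
                    asdict(r) for r in records
                ]
            else:
                chosen_k = config.k
            model = lda.fit_lda(
                bows,
                vocab,
                chosen_k,
                alpha=config.alpha,
                eta=config.eta,
                n_iterations=config.n_iterations,
                seed=seed,
            )
            logger.info("lda: fitted k=%d (seed %d)", chosen_k, seed)
            # 1-based topic ids, matching the reporting convention
            assignments = [lda.dominant_topic(theta_d) + 1 for theta_d in model.theta]
            table = evaluate.contingency_table(assignments, labels)
            report = evaluate.semi_supervised_accuracy(table)
            keywords = {
                t + 1: kws for t, kws in lda.topic_keywords(model, vocab).items()
            }
            _write_contingency_tsv(table, outdir / "lda_contingency.tsv")
            _write_keywords_tsv(keywords, outdir / "lda_keywords.tsv")
            paths = lda.save_model(model, vocab, str(outdir / "lda_model"))
            manifest["outputs"].update(
                {
                    "lda_contingency": str(outdir / "lda_contingency.tsv"),
                    "lda_keywords": str(outdir / "lda_keywords.tsv"),
                    **{f"lda_{k}": v for k, v in paths.items()},
                }
            )
            manifest["metrics"]["lda"] = {
                "k": chosen_k,
                "corpus_fingerprint": fingerprint,
                **_report_to_metrics(report),
            }
            manifest["metrics"]["lda"]["log_perplexity"] = round(
                lda.log_perplexity(model, bows), 6
            )
            manifest["metrics"]["lda"]["coherence"] = round(
                lda.umass_coherence(model, bows), 6
            )

        # ------------------------------------------------ clustering track
        if config.track in ("cluster", "both"):
            seed = stage_seed(config.seed, "cluster")
            emb = embed_cluster.embed_documents(
                streams, embedder=config.embedder, seed=seed
            )
            reduced = embed_cluster.reduce_dimensions(
                emb, n_components=config.n_components, method=config.reducer, seed=seed
            )
            clustering = embed_cluster.hdbscan_cluster(
                reduced,
                min_cluster_size=config.min_cluster_size,
                min_samples=config.min_samples,
                metric=config.metric,
            )
            assignments = embed_cluster.assign_topics(clustering)
            streams_by_cluster: dict[int, list[str]] = {}
            for s, c in zip(streams, assignments):
                streams_by_cluster.setdefault(int(c), []).extend(s.tokens)
            ctab = embed_cluster.class_tfidf_keywords(streams_by_cluster)
            table = evaluate.contingency_table(assignments.tolist(), labels)
            report = evaluate.semi_supervised_accuracy(table)
            _write_contingency_tsv(table, outdir / "cluster_contingency.tsv")
            _write_keywords_tsv(ctab.keywords, outdir / "cluster_keywords.tsv")
            manifest["outputs"].update(
                {
                    "cluster_contingency": str(outdir / "cluster_contingency.tsv"),
                    "cluster_keywords": str(outdir / "cluster_keywords.tsv"),
                }
            )
            manifest["metrics"]["cluster"] = {
                "n_clusters": len(clustering.cluster_sizes),
                "n_noise": clustering.n_noise,
                "corpus_fingerprint": fingerprint,
                **_report_to_metrics(report),
            }

        if config.track == "both":
            manifest["metrics"]["comparison"] = compare_tracks(
                manifest["metrics"]["lda"], manifest["metrics"]["cluster"]
            )

        metrics_path = outdir / "metrics.json"
        metrics_path.write_text(
            json.dumps(manifest["metrics"], indent=2, sort_keys=True) + "\n"
        )
        manifest["outputs"]["metrics"] = str(metrics_path)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()


def compare_tracks(metrics_lda: dict, metrics_cluster: dict) -> dict:
    """Side-by-side comparison of the two tracks on the same corpus."""
    if metrics_lda.get("corpus_fingerprint") != metrics_cluster.get(
        "corpus_fingerprint"
    ):
        raise ValueError("metrics come from different corpora")
    acc_l, acc_c = metrics_lda["accuracy"], metrics_cluster["accuracy"]
    if acc_c > acc_l:
        better = "cluster"
    elif acc_l > acc_c:
        better = "lda"
    else:
        better = "tie"
    return {
        "lda_accuracy_pct": metrics_lda["accuracy_pct"],
        "cluster_accuracy_pct": metrics_cluster["accuracy_pct"],
        "lda_grouped_fraction_pasc_pct": metrics_lda["grouped_fraction_pasc_pct"],
        "cluster_grouped_fraction_pasc_pct": metrics_cluster[
            "grouped_fraction_pasc_pct"
        ],
        "better_track": better,
    }
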