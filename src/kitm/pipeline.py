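"""End-to-end pipeline: preprocess -> domains -> encode -> expand ->
train -> evaluate, with a reproducible run manifest.

The manifest records input hashes, the seed, per-stage record counts and
library versions, so any silent change to inputs or intermediates is
detectable; the only non-reproducible field is the timestamp.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
import os
import time
from dataclasses import asdict

import numpy as np

from . import __version__
from .concept_encoding import encode_tokens, encoded_to_record
from .config import RunConfig
from .corpus_model import Corpus, read_corpus
from .knowledge_base import KnowledgeBase, load_rrf_kb, load_toy_kb
from .knowledge_expansion import expand_text, expanded_to_record
from .metrics import metric_report
from .model import build_dataset, top_terms, train_cvb0, training_perplexity
from .text_pipeline import (
    apply_label_filters,
    apply_term_filters,
    tokenize_corpus,
)

logger = logging.getLogger(__name__)


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_jsonl(path: str, records) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(record, sort_keys=True, ensure_ascii=False) + "\n")
            n += 1
    return n


def load_kb_from_config(config: RunConfig) -> KnowledgeBase:
    if config.kb_format == "toy":
        return load_toy_kb(config.kb_path)
    if config.kb_format == "rrf":
        return load_rrf_kb(config.kb_path, config.rel_path)
    raise ValueError(f"unknown kb format {config.kb_format!r}")


def classify_posts(
    corpus: Corpus, topic_map: dict[str, str]
) -> dict[str, list]:
    """Partition posts by the topic their labels map to.

    A post goes into the bucket of the lexicographically first topic among
    its mapped labels; posts with no mapped label land in
    ``"unclassified"``.  Buckets form an exact partition of the corpus.
    """
    buckets: dict[str, list] = {}
    for post in corpus:
        topics = sorted(
            {topic_map[label] for label in post.labels if label in topic_map}
        )
        bucket = topics[0] if topics else "unclassified"
        buckets.setdefault(bucket, []).append(post)
    return buckets


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``<out_dir>/run_manifest.json``).  Any stage failure aborts with the
    stage name attached."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "kitm_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {
            "corpus": {"path": config.corpus_path, "sha256": _sha256(config.corpus_path)},
            "kb": {"path": config.kb_path, "sha256": _sha256(config.kb_path)},
        },
        "stages": {},
        "outputs": {},
    }

    stage = "read_corpus"
    try:
        corpus = read_corpus(
            config.corpus_path, format=config.corpus_format, field_map=config.field_map
        )
        manifest["stages"][stage] = {"n_posts": len(corpus)}

        stage = "load_kb"
        kb = load_kb_from_config(config)
        manifest["stages"][stage] = {
            "n_concepts": len(kb.concepts),
            "n_relations": len(kb.relations),
        }

        stage = "preprocess"
        raw_docs = tokenize_corpus(corpus)
        tokenized = apply_term_filters(raw_docs, config.pipeline)
        manifest["stages"][stage] = {
            "n_docs_in": len(raw_docs),
            "n_docs_surviving": len(tokenized.docs),
            "n_docs_dropped": len(tokenized.dropped_docs),
            "vocabulary_size": len(tokenized.vocabulary),
            "stoplist_size": len(tokenized.stoplist),
        }
        tokenized_path = os.path.join(config.out_dir, "tokenized.jsonl")
        _write_jsonl(
            tokenized_path,
            ({"id": doc_id, "tokens": tokens} for doc_id, tokens in tokenized.docs),
        )

        stage = "labels"
        label_stream = apply_label_filters(corpus, config.pipeline, kb=kb)
        manifest["stages"][stage] = {
            "n_labeled_docs": len(label_stream.doc_labels),
            "n_excluded_docs": len(label_stream.excluded_docs),
            "n_labels": len(label_stream.label_df),
        }
        _write_jsonl(
            os.path.join(config.out_dir, "labels.jsonl"),
            (
                {"id": doc_id, "labels": sorted(labels)}
                for doc_id, labels in label_stream.doc_labels
            ),
        )

        stage = "encode"
        encoded_filtered = [
            encode_tokens(tokens, kb, label_stream.domain_map, post_id=doc_id)
            for doc_id, tokens in tokenized.docs
        ]
        manifest["stages"][stage] = {
            "n_docs": len(encoded_filtered),
            "n_concept_terms": sum(e.n_concepts for e in encoded_filtered),
        }
        _write_jsonl(
            os.path.join(config.out_dir, "encoded.jsonl"),
            (encoded_to_record(e) for e in encoded_filtered),
        )

        stage = "expand"
        expanded = [
            expand_text(e, kb, config.m, scope=config.expansion_scope)
            for e in encoded_filtered
        ]
        manifest["stages"][stage] = {
            "m": config.m,
            "n_latent_terms": sum(
                len(codes) for e in expanded for codes in e.latent_terms.values()
            ),
        }
        _write_jsonl(
            os.path.join(config.out_dir, "expanded.jsonl"),
            (expanded_to_record(e) for e in expanded),
        )

        stage = "train"
        label_map = dict(label_stream.doc_labels)
        dataset = build_dataset(
            [(e.post_id, e.expanded_tokens) for e in expanded], label_map
        )
        if dataset.n_docs == 0:
            manifest["stages"][stage] = {"n_docs": 0, "skipped": True}
            logger.warning("train: no documents survived filtering; stage skipped")
        else:
            model = train_cvb0(
                dataset,
                alpha=config.alpha,
                beta=config.beta,
                n_iterations=config.iterations,
                seed=config.seed,
            )
            model_path = os.path.join(config.out_dir, "model.json")
            with open(model_path, "w", encoding="utf-8") as fh:
                fh.write(model.to_json())
            manifest["stages"][stage] = {
                "n_docs": dataset.n_docs,
                "n_topics": model.n_topics,
                "vocabulary_size": dataset.n_terms,
                "training_perplexity": training_perplexity(model, dataset),
            }
            manifest["outputs"]["top_terms"] = top_terms(model, config.top_terms)

        stage = "evaluate"
        # metrics are computed on the full (unfiltered) token stream of
        # every post, so per-post knowledge rates stay meaningful even for
        # posts the length filters drop
        report_path = os.path.join(config.out_dir, "report.csv")
        ms = list(config.lkr_ms)
        with open(report_path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["post_id", "ekr"]
                + [f"lkr_m{m}" for m in ms]
                + ["kcr", "n_raw", "n_k", "n_unique", "k_d", "n_s", "n"]
            )
            for doc_id, tokens in raw_docs:
                encoded = encode_tokens(tokens, kb, label_stream.domain_map, post_id=doc_id)
                report = metric_report(
                    encoded,
                    kb,
                    ms=ms,
                    lkr_mode=config.lkr_mode,
                    scope=config.expansion_scope,
                    kcr_hop_radius=config.kcr_hop_radius,
                )
                writer.writerow(
                    [report.post_id, f"{report.ekr:.6f}"]
                    + [
                        "nan" if math.isnan(report.lkr_by_m[m]) else f"{report.lkr_by_m[m]:.6f}"
                        for m in ms
                    ]
                    + [
                        f"{report.kcr:.6f}",
                        report.counts["n_raw"],
                        report.counts["n_k"],
                        report.counts["n_unique"],
                        report.counts["k_d"],
                        report.counts["n_s"],
                        report.counts["n"],
                    ]
                )
        manifest["stages"][stage] = {"n_reports": len(raw_docs)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name in ("tokenized.jsonl", "labels.jsonl", "encoded.jsonl",
                 "expanded.jsonl", "model.json", "report.csv"):
        path = os.path.join(config.out_dir, name)
        if os.path.exists(path):
            manifest["outputs"][name] = _sha256(path)

    manifest_path = os.path.join(config.out_dir, "run_manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
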