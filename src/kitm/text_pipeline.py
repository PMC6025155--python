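"""Tokenizer and filter chain producing the term and label streams.

The chain is deliberately rigid and ordered: tokenize on space and
punctuation, lowercase, keep only word/number tokens; then (in this order)
minimum term length, minimum document frequency, dynamic stoplist of the
most document-frequent terms, minimum document length.  Permuting the
filters changes the output, so the order is pinned by regression tests.
"""

from __future__ import annotations

import logging
import unicodedata
from collections import Counter
from dataclasses import dataclass, field

from .corpus_model import Corpus
from .knowledge_base import KnowledgeBase, normalize_term

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Filter thresholds; defaults are the published chain's values
    (>=3 chars, <4 docs, 30-term stoplist, >=5 terms per doc,
    <10-doc labels)."""

    min_term_length: int = 3
    term_min_doc_count: int = 4
    label_min_doc_count: int = 10
    stoplist_size: int = 30
    doc_min_length: int = 5

    def __post_init__(self) -> None:
        for name in (
            "min_term_length",
            "term_min_doc_count",
            "label_min_doc_count",
            "stoplist_size",
            "doc_min_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TokenizedCorpus:
    docs: list[tuple[str, list[str]]]
    vocabulary: dict[str, int]  # term -> document frequency
    dropped_docs: list[str] = field(default_factory=list)
    stoplist: list[str] = field(default_factory=list)


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace and punctuation/symbols, keep only
    tokens made of letters and digits.  Total function; '' -> []."""
    chars = []
    for ch in text.lower():
        cat = unicodedata.category(ch)
        if cat.startswith("P") or cat.startswith("S") or ch.isspace():
            chars.append(" ")
        else:
            chars.append(ch)
    return [tok for tok in "".join(chars).split() if tok.isalnum()]


def _doc_frequencies(docs: list[tuple[str, list[str]]]) -> Counter:
    df: Counter = Counter()
    for _id, tokens in docs:
        df.update(set(tokens))
    return df


def apply_term_filters(
    docs: list[tuple[str, list[str]]], config: PipelineConfig | None = None
) -> TokenizedCorpus:
    """Apply the term filter chain in its fixed order.

    1. drop tokens shorter than ``min_term_length`` characters;
    2. drop terms appearing in fewer than ``term_min_doc_count`` docs;
    3. drop the ``stoplist_size`` most document-frequent surviving terms
       (ties broken lexicographically, most frequent first);
    4. drop docs left with fewer than ``doc_min_length`` terms
       (recorded in ``dropped_docs``).

    ``vocabulary`` maps each surviving term to its document frequency over
    the surviving docs.
    """
    config = config or PipelineConfig()
    current = [
        (doc_id, [t for t in tokens if len(t) >= config.min_term_length])
        for doc_id, tokens in docs
    ]

    df = _doc_frequencies(current)
    keep = {t for t, n in df.items() if n >= config.term_min_doc_count}
    current = [
        (doc_id, [t for t in tokens if t in keep]) for doc_id, tokens in current
    ]

    df = _doc_frequencies(current)
    ranked = sorted(df.items(), key=lambda kv: (-kv[1], kv[0]))
    stoplist = [t for t, _n in ranked[: config.stoplist_size]]
    stopset = set(stoplist)
    current = [
        (doc_id, [t for t in tokens if t not in stopset])
        for doc_id, tokens in current
    ]

    surviving = [
        (doc_id, tokens)
        for doc_id, tokens in current
        if len(tokens) >= config.doc_min_length
    ]
    dropped = [
        doc_id
        for doc_id, tokens in current
        if len(tokens) < config.doc_min_length
    ]
    if dropped:
        logger.debug("term filters dropped %d short docs: %s", len(dropped), dropped)
    vocabulary = dict(_doc_frequencies(surviving))
    return TokenizedCorpus(
        docs=surviving,
        vocabulary=vocabulary,
        dropped_docs=dropped,
        stoplist=stoplist,
    )


@dataclass
class LabelStream:
    """Per-post surviving label sets plus bookkeeping."""

    doc_labels: list[tuple[str, set[str]]]
    label_df: dict[str, int]
    excluded_docs: list[str] = field(default_factory=list)
    domain_map: dict[str, set[str]] = field(default_factory=dict)


def apply_label_filters(
    posts: Corpus,
    config: PipelineConfig | None = None,
    kb: KnowledgeBase | None = None,
    domains: list[str] | None = None,
) -> LabelStream:
    """Tokenize label fields on whitespace, run domain discovery against
    the KB (when given), and drop labels carried by fewer than
    ``label_min_doc_count`` documents.

    Posts left with no labels are excluded from the labeled dataset and
    logged.  Labels are normalized to the same canonical form the KB term
    index uses, so discovery and counting agree.
    """
    from .concept_encoding import discover_domains  # local: avoids cycle

    config = config or PipelineConfig()
    raw_labels: list[tuple[str, list[str]]] = []
    all_label_tokens: set[str] = set()
    for post in posts:
        tokens: list[str] = []
        for label_field in sorted(post.labels):
            tokens.extend(normalize_term(t) for t in label_field.split())
        tokens = [t for t in tokens if t]
        raw_labels.append((post.id, tokens))
        all_label_tokens.update(tokens)

    domain_map: dict[str, set[str]] = {}
    if kb is not None:
        domain_map = discover_domains(sorted(all_label_tokens), kb, domains)

    df: Counter = Counter()
    for _id, tokens in raw_labels:
        df.update(set(tokens))
    keep = {t for t, n in df.items() if n >= config.label_min_doc_count}

    doc_labels: list[tuple[str, set[str]]] = []
    excluded: list[str] = []
    for doc_id, tokens in raw_labels:
        surviving = {t for t in tokens if t in keep}
        if surviving:
            doc_labels.append((doc_id, surviving))
        else:
            excluded.append(doc_id)
    if excluded:
        logger.warning(
            "label filter excluded %d posts with no surviving labels", len(excluded)
        )
    return LabelStream(
        doc_labels=doc_labels,
        label_df={t: df[t] for t in sorted(keep)},
        excluded_docs=excluded,
        domain_map=domain_map,
    )


def tokenize_corpus(posts: Corpus, use_caption_fallback: bool = True) -> list[tuple[str, list[str]]]:
    """Tokenize each post's narrative body (falling back to the caption
    when the body is empty)."""
    docs = []
    for post in posts:
        text = post.text if post.text else (post.caption if use_caption_fallback else "")
        docs.append((post.id, tokenize(text)))
    return docs
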